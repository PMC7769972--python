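"""Synthetic axial CT phantoms with known paraspinal composition.

A phantom is two elliptical "paraspinal" compartments flanking a bright
vertebral disc on a uniform fat-like background.  Compartment pixels are
assigned ground-truth labels (fatty / lean / bone) by exact counts realising
the requested fatty muscle fraction, then HU values are drawn per label from
truncated normals whose supports are chosen so that, after rounding to
integer HU, every pixel classifies as its own label.  The measurement
pipeline therefore recovers the true FMF exactly — the closed loop that the
metric tests rely on.  An untruncated mode produces boundary-crossing noise
for robustness checks, where recovery is only approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .imaging_io import CompartmentMask, CTSlice
from .muscle_metrics import AttenuationThresholds

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "phantom_suite",
]

# Sampling supports per label, in unrounded HU.  Rounding half away from zero
# maps [-29, 29.49] into the fatty window [-29, 29] and [29.5, 100.49] into the
# lean window [30, 100].
_FATTY_SUPPORT = (-29.0, 29.49)
_LEAN_SUPPORT = (29.5, 100.49)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse; centre and semi-axes in mm."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float


def _default_geometry() -> tuple[Ellipse, ...]:
    # two 30x20 mm ellipses flanking the midline on a 128x128 mm grid
    return (
        Ellipse(74.0, 40.0, 10.0, 15.0),
        Ellipse(74.0, 88.0, 10.0, 15.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build one phantom deterministically."""

    target_fmf: float = 44.0  # percent
    grid_size: int = 128
    spacing: float = 1.0  # mm, isotropic
    ellipses: tuple[Ellipse, ...] = field(default_factory=_default_geometry)
    lean_hu_mean: float = 45.0
    lean_hu_sd: float = 12.0
    fatty_hu_mean: float = 5.0
    fatty_hu_sd: float = 12.0
    background_hu: float = -100.0
    vertebra_hu: float = 700.0
    vertebra_radius: float = 7.5  # mm; 0 disables the disc
    bone_fraction: float = 0.0  # fraction of compartment pixels set > 100 HU
    bone_hu: float = 400.0
    truncate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fmf <= 100.0):
            raise ValueError("target_fmf must be in [0, 100]")
        if self.fatty_hu_sd < 0 or self.lean_hu_sd < 0:
            raise ValueError("HU standard deviations must be nonnegative")
        if not (0.0 <= self.bone_fraction < 1.0):
            raise ValueError("bone_fraction must be in [0, 1)")
        half = self.grid_size * self.spacing
        for e in self.ellipses:
            if (
                e.center_row - e.semi_row < 0
                or e.center_row + e.semi_row > half
                or e.center_col - e.semi_col < 0
                or e.center_col + e.semi_col > half
            ):
                raise ValueError("ellipse extends outside the grid")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth composition of a phantom's compartment."""

    true_fatty_pixels: int
    true_lean_pixels: int
    true_bone_pixels: int
    true_fmf: float  # percent = 100 * fatty / (fatty + lean)
    label_map: np.ndarray  # 0 outside, 1 bone, 2 fatty, 3 lean


def _ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    n = spec.grid_size
    rows = (np.arange(n) + 0.5) * spec.spacing
    cols = (np.arange(n) + 0.5) * spec.spacing
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    mask = np.zeros((n, n), dtype=bool)
    for e in spec.ellipses:
        mask |= ((rr - e.center_row) / e.semi_row) ** 2 + (
            (cc - e.center_col) / e.semi_col
        ) ** 2 <= 1.0
    return mask


def _sample_hu(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    support: tuple[float, float],
    truncate: bool,
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, np.clip(mean, *support) if truncate else mean)
    if not truncate:
        return rng.normal(mean, sd, size=n)
    lo, hi = support
    if sd > hi - lo:
        raise ValueError(
            f"sd {sd} too large for truncation interval [{lo}, {hi}]"
        )
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTSlice, CompartmentMask, PhantomTruth]:
    """Build one phantom; deterministic for a fixed spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    compartment = _ellipse_mask(spec)
    n_total = int(compartment.sum())
    if n_total == 0:
        raise ValueError("compartment geometry produced an empty mask")

    n_bone = int(round(spec.bone_fraction * n_total))
    n_soft = n_total - n_bone
    n_fatty = int(round(spec.target_fmf / 100.0 * n_soft))
    n_lean = n_soft - n_fatty

    order = rng.permutation(n_total)
    rows, cols = np.nonzero(compartment)
    rows, cols = rows[order], cols[order]

    label_map = np.zeros((spec.grid_size, spec.grid_size), dtype=np.uint8)
    label_map[rows[:n_bone], cols[:n_bone]] = 1
    label_map[rows[n_bone : n_bone + n_fatty], cols[n_bone : n_bone + n_fatty]] = 2
    label_map[rows[n_bone + n_fatty :], cols[n_bone + n_fatty :]] = 3

    pixels = np.full((spec.grid_size, spec.grid_size), spec.background_hu, dtype=float)
    if spec.vertebra_radius > 0:
        n = spec.grid_size
        coords = (np.arange(n) + 0.5) * spec.spacing
        rr, cc = np.meshgrid(coords, coords, indexing="ij")
        centre = spec.grid_size * spec.spacing / 2.0
        disc = (rr - centre) ** 2 + (cc - centre) ** 2 <= spec.vertebra_radius**2
        pixels[disc & ~compartment] = spec.vertebra_hu

    pixels[label_map == 1] = spec.bone_hu
    pixels[label_map == 2] = _sample_hu(
        rng, n_fatty, spec.fatty_hu_mean, spec.fatty_hu_sd, _FATTY_SUPPORT, spec.truncate
    )
    pixels[label_map == 3] = _sample_hu(
        rng, n_lean, spec.lean_hu_mean, spec.lean_hu_sd, _LEAN_SUPPORT, spec.truncate
    )

    ct = CTSlice(
        pixels,
        spec.spacing,
        spec.spacing,
        source_id=f"phantom(fmf={spec.target_fmf},seed={spec.seed})",
    )
    mask = CompartmentMask(compartment, source_id=ct.source_id)
    truth = PhantomTruth(
        true_fatty_pixels=n_fatty,
        true_lean_pixels=n_lean,
        true_bone_pixels=n_bone,
        true_fmf=100.0 * n_fatty / n_soft if n_soft else float("nan"),
        label_map=label_map,
    )
    return ct, mask, truth


def phantom_suite(
    fmf_grid: list[float], seed: int = 0, **overrides
) -> list[tuple[CTSlice, CompartmentMask, PhantomTruth]]:
    """One phantom per requested true FMF, with per-item derived seeds."""
    base = PhantomSpec(seed=seed, **overrides)
    return [
        generate_phantom(replace(base, target_fmf=float(f), seed=seed + i))
        for i, f in enumerate(fmf_grid)
    ]
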