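"""Densitometric muscle-quality metrics from a single axial CT slice.

Within the bilateral paraspinal compartment, skeletal muscle tissue is
identified by the attenuation window -29..100 HU and split at 29/30 HU into
fatty (-29..29 HU, myosteatotic) and lean (30..100 HU) muscle.  The fatty
muscle fraction (FMF) is the fatty area as a percentage of the total muscle
area; being a ratio it needs no anthropometric normalisation.  Also derived:
compartment area, mean muscle attenuation and, given body height, the
skeletal muscle index (SMI, cm^2/m^2).

The published thresholds are integers, which leaves real-valued HU in
(29, 30) unclassified; pixels are therefore rounded to the nearest integer
(half away from zero) before classification, closing the gap while keeping
the integer windows verbatim.  Mean attenuation is computed on the unrounded
values (it is a mean, not a class).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .imaging_io import CompartmentMask, CTSlice

__all__ = [
    "AttenuationThresholds",
    "PixelLabel",
    "PixelClassification",
    "MuscleMeasurements",
    "UndefinedFMFError",
    "classify_pixels",
    "area_cm2",
    "measure",
    "binarize_fmf",
    "round_half_away",
]


class UndefinedFMFError(ValueError):
    """No muscle pixels in the compartment; FMF has no value."""


@dataclass(frozen=True)
class AttenuationThresholds:
    """Integer HU windows defining muscle and its fatty/lean split.

    muscle_low..fatty_high is fatty muscle, (fatty_high, muscle_high] lean;
    anything outside [muscle_low, muscle_high] in the compartment is
    non-muscle (fat below, bone/contrast above).
    """

    muscle_low: float = -29.0
    fatty_high: float = 29.0
    muscle_high: float = 100.0

    def __post_init__(self) -> None:
        if not (self.muscle_low <= self.fatty_high < self.muscle_high):
            raise ValueError("require muscle_low <= fatty_high < muscle_high")


class PixelLabel(enum.IntEnum):
    OUTSIDE = 0
    NON_MUSCLE = 1  # in compartment but outside the muscle window
    FATTY = 2
    LEAN = 3


@dataclass(frozen=True)
class PixelClassification:
    """Per-pixel labels over the full slice grid (:class:`PixelLabel` codes)."""

    labels: np.ndarray

    def count(self, label: PixelLabel) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass(frozen=True)
class MuscleMeasurements:
    """All per-subject imaging metrics, areas in cm^2."""

    compartment_area: float
    muscle_area: float
    fatty_area: float
    lean_area: float
    fmf: float  # percent
    mean_attenuation: float  # HU, over muscle pixels, unrounded values
    smi: float | None = None  # cm^2/m^2, requires height

    def to_dict(self) -> dict:
        return {
            "compartment_area_cm2": self.compartment_area,
            "muscle_area_cm2": self.muscle_area,
            "fatty_area_cm2": self.fatty_area,
            "lean_area_cm2": self.lean_area,
            "fmf_percent": self.fmf,
            "mean_attenuation_hu": self.mean_attenuation,
            "smi_cm2_m2": self.smi,
        }


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, halves away from zero (29.5 -> 30, -29.5 -> -30)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def classify_pixels(
    ct: CTSlice,
    mask: CompartmentMask,
    thresholds: AttenuationThresholds = AttenuationThresholds(),
) -> PixelClassification:
    """Label every pixel of the slice by compartment membership and HU window."""
    mask.validate_against(ct)
    hu = round_half_away(ct.pixels)
    labels = np.full(ct.shape, PixelLabel.OUTSIDE, dtype=np.uint8)
    inside = mask.mask
    labels[inside] = PixelLabel.NON_MUSCLE
    fatty = inside & (hu >= thresholds.muscle_low) & (hu <= thresholds.fatty_high)
    lean = inside & (hu > thresholds.fatty_high) & (hu <= thresholds.muscle_high)
    labels[fatty] = PixelLabel.FATTY
    labels[lean] = PixelLabel.LEAN
    return PixelClassification(labels)


def area_cm2(pixel_count: int, ct: CTSlice) -> float:
    """Pixel count times pixel surface area, mm^2 converted to cm^2."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be nonnegative")
    return pixel_count * ct.pixel_area_mm2 / 100.0


def measure(
    ct: CTSlice,
    mask: CompartmentMask,
    thresholds: AttenuationThresholds = AttenuationThresholds(),
    height_m: float | None = None,
) -> MuscleMeasurements:
    """Compute all muscle metrics for one subject.

    Raises :class:`UndefinedFMFError` when the compartment contains no pixel
    in the muscle window (FMF is a ratio with zero denominator).
    """
    cls = classify_pixels(ct, mask, thresholds)
    n_fatty = cls.count(PixelLabel.FATTY)
    n_lean = cls.count(PixelLabel.LEAN)
    n_compartment = mask.n_pixels
    n_muscle = n_fatty + n_lean
    if n_muscle == 0:
        raise UndefinedFMFError("no pixels in the muscle attenuation window")
    muscle_sel = (cls.labels == PixelLabel.FATTY) | (cls.labels == PixelLabel.LEAN)
    mean_att = float(ct.pixels[muscle_sel].mean())
    muscle_area = area_cm2(n_muscle, ct)
    if height_m is not None:
        if height_m <= 0:
            raise ValueError("height_m must be positive")
        smi = muscle_area / height_m**2
    else:
        smi = None
    return MuscleMeasurements(
        compartment_area=area_cm2(n_compartment, ct),
        muscle_area=muscle_area,
        fatty_area=area_cm2(n_fatty, ct),
        lean_area=area_cm2(n_lean, ct),
        fmf=100.0 * n_fatty / n_muscle,
        mean_attenuation=mean_att,
        smi=smi,
    )


def binarize_fmf(fmf: float, cutoff: float = 44.0) -> str:
    """Dichotomise FMF at the cutoff: 'high' iff fmf > cutoff (strict), else 'low'."""
    if not (0.0 <= fmf <= 100.0):
        raise ValueError("fmf must be a percentage in [0, 100]")
    return "high" if fmf > cutoff else "low"
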