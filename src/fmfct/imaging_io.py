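"""Reading and writing calibrated CT slices and compartment masks.

A measurement is only meaningful on a slice whose pixel values are true
Hounsfield units and whose pixel spacing is known, so both are mandatory:
files missing rescale or spacing metadata are rejected rather than silently
assumed to be 1 mm / already calibrated.

Supported formats: single-frame DICOM (.dcm) and NIfTI-1 (.nii/.nii.gz) for
slices; PNG (8/16-bit) or NIfTI for masks.  Axial orientation is taken as
stored; there is no reorientation logic (single-slice workflow).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image

__all__ = [
    "CTSlice",
    "CompartmentMask",
    "ImagingIOError",
    "MissingMetadataError",
    "ShapeMismatchError",
    "EmptyMaskError",
    "load_ct_slice",
    "write_ct_slice",
    "load_mask",
    "write_mask",
]


class ImagingIOError(ValueError):
    """Base class for imaging I/O contract violations."""


class MissingMetadataError(ImagingIOError):
    """Rescale or spacing metadata absent; HU calibration impossible."""


class ShapeMismatchError(ImagingIOError):
    """Mask grid does not match its reference slice."""


class EmptyMaskError(ImagingIOError):
    """Mask contains no foreground pixel; no measurement is possible."""


@dataclass(frozen=True)
class CTSlice:
    """A calibrated 2-D axial CT attenuation map.

    Parameters
    ----------
    pixels
        2-D array of attenuation values in Hounsfield units (real-valued
        after rescale).
    spacing_row, spacing_col
        Pixel edge lengths in millimetres (> 0).
    source_id
        Free-text provenance string.
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ImagingIOError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ImagingIOError("attenuation values must be finite")
        if not (self.spacing_row > 0 and self.spacing_col > 0):
            raise ImagingIOError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_row * self.spacing_col


@dataclass(frozen=True)
class CompartmentMask:
    """Binary region marking the bilateral paraspinal compartment."""

    mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise ImagingIOError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def validate_against(self, reference: CTSlice) -> None:
        """Raise if shape differs from `reference` or the mask is empty."""
        if self.shape != reference.shape:
            raise ShapeMismatchError(
                f"mask shape {self.shape} != slice shape {reference.shape}"
            )
        if self.n_pixels == 0:
            raise EmptyMaskError("compartment mask has no foreground pixels")


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _load_dicom_slice(path: str) -> CTSlice:
    ds = pydicom.dcmread(path)
    if "PixelSpacing" not in ds:
        raise MissingMetadataError(f"{path}: DICOM lacks PixelSpacing")
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        raise MissingMetadataError(
            f"{path}: DICOM lacks RescaleSlope/RescaleIntercept; cannot calibrate HU"
        )
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ImagingIOError(f"{path}: expected a single-frame DICOM, got shape {arr.shape}")
    hu = arr.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    spacing_row, spacing_col = (float(v) for v in ds.PixelSpacing)
    return CTSlice(hu, spacing_row, spacing_col, source_id=os.fspath(path))


def _load_nifti_plane(path: str, slice_index: int | None) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(path)
    data = img.get_fdata()  # applies scl_slope / scl_inter
    zooms = img.header.get_zooms()
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim == 2:
        if slice_index not in (None, 0):
            raise ImagingIOError(f"{path}: 2-D image, slice_index {slice_index} out of range")
        plane = data
    elif data.ndim == 3:
        if slice_index is None:
            raise ImagingIOError(f"{path}: 3-D volume requires slice_index")
        if not (0 <= slice_index < data.shape[2]):
            raise ImagingIOError(
                f"{path}: slice_index {slice_index} out of range for {data.shape[2]} axial planes"
            )
        plane = data[:, :, slice_index]
    else:
        raise ImagingIOError(f"{path}: unsupported dimensionality {data.ndim}")
    spacing = (float(zooms[0]), float(zooms[1]))
    if not (spacing[0] > 0 and spacing[1] > 0):
        raise MissingMetadataError(f"{path}: non-positive pixdim; spacing metadata invalid")
    return plane, spacing


def load_ct_slice(path: str | os.PathLike, slice_index: int | None = None) -> CTSlice:
    """Load a calibrated axial CT slice from DICOM or NIfTI.

    Pixel values are returned in HU: DICOM rescale slope/intercept or NIfTI
    scl_slope/scl_inter are applied.  ``slice_index`` selects the axial plane
    of a NIfTI volume (third axis) and is ignored for single-frame DICOM.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        plane, (sr, sc) = _load_nifti_plane(path, slice_index)
        return CTSlice(plane, sr, sc, source_id=path)
    if path.endswith(".dcm"):
        return _load_dicom_slice(path)
    # fall back on content sniffing for extension-less DICOM
    try:
        return _load_dicom_slice(path)
    except pydicom.errors.InvalidDicomError as exc:  # pragma: no cover - defensive
        raise ImagingIOError(f"{path}: unsupported image format") from exc


def write_ct_slice(ct: CTSlice, path: str | os.PathLike) -> None:
    """Write a CTSlice as a 2-D NIfTI with spacing in the header zooms."""
    affine = np.diag([ct.spacing_row, ct.spacing_col, 1.0, 1.0])
    img = nib.Nifti1Image(ct.pixels.astype(np.float32), affine)
    img.header.set_zooms((ct.spacing_row, ct.spacing_col))
    nib.save(img, os.fspath(path))


def load_mask(path: str | os.PathLike, reference: CTSlice) -> CompartmentMask:
    """Load a compartment mask (PNG or NIfTI); any nonzero stored value is inside.

    The mask grid must match ``reference``; an all-zero mask raises
    :class:`EmptyMaskError` (distinct from :class:`ShapeMismatchError`).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ImagingIOError(f"{path}: mask must be a single 2-D plane")
    else:
        with Image.open(path) as im:
            arr = np.array(im)
        if arr.ndim == 3:  # collapse colour channels
            arr = arr.any(axis=2)
    mask = CompartmentMask(arr != 0, source_id=path)
    mask.validate_against(reference)
    return mask


def write_mask(mask: CompartmentMask, path: str | os.PathLike) -> None:
    """Write a mask as NIfTI (uint8) or PNG depending on extension."""
    path = os.fspath(path)
    data = mask.mask.astype(np.uint8)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(data, np.eye(4)), path)
    else:
        Image.fromarray(data * 255).save(path)
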