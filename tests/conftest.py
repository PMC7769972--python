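import numpy as np
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from fmfct.imaging_io import CompartmentMask, CTSlice


def make_dicom(
    path,
    stored: np.ndarray,
    spacing=(0.8, 0.8),
    slope=1.0,
    intercept=-1024.0,
    omit=(),
):
    """Write a minimal single-frame CT DICOM with the given stored values."""
    stored = np.asarray(stored, dtype=np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if "PixelSpacing" not in omit:
        ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
    if "Rescale" not in omit:
        ds.RescaleSlope = str(slope)
        ds.RescaleIntercept = str(intercept)
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def uniform_slice(values: np.ndarray, spacing=(1.0, 1.0)) -> CTSlice:
    return CTSlice(np.asarray(values, float), spacing[0], spacing[1], "test")


def full_mask(ct: CTSlice) -> CompartmentMask:
    return CompartmentMask(np.ones(ct.shape, bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20201228)
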