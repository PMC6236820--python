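"""DICOM RT-DOSE reading (and writing, for fixtures).

Voxel values are stored pixel data times ``DoseGridScaling``, in Gy.  Grid
geometry comes from ImagePositionPatient, PixelSpacing and
GridFrameOffsetVector; only the axis-aligned identity orientation
(1,0,0,0,1,0) with uniformly spaced frames is supported in v1.  The DICOM
frame/row/column array order is transposed to this package's (x, y, z) order.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from ..errors import MalformedDoseError, UnsupportedOrientationError
from ..geometry import DoseGrid, VoxelGrid

__all__ = ["read_rtdose", "write_rtdose"]

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def read_rtdose(source, prescription: float) -> DoseGrid:
    """Read an RT-DOSE file (or an open pydicom Dataset) into a DoseGrid."""
    ds = source if isinstance(source, Dataset) else pydicom.dcmread(str(source))
    if "DoseGridScaling" not in ds:
        raise MalformedDoseError("RT-DOSE is missing DoseGridScaling")
    orientation = tuple(float(v) for v in ds.ImageOrientationPatient)
    if not np.allclose(orientation, _IDENTITY_ORIENTATION, atol=1e-6):
        raise UnsupportedOrientationError(
            f"only axis-aligned identity orientation is supported, got {orientation}"
        )
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size < 2:
        raise MalformedDoseError("GridFrameOffsetVector must have >= 2 frames")
    dz = np.diff(offsets)
    if not np.allclose(dz, dz[0], atol=1e-6) or dz[0] <= 0:
        raise UnsupportedOrientationError("frames must be uniformly spaced, ascending")
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array  # (frames, rows, cols) = (z, y, x)
    values = arr.transpose(2, 1, 0).astype(float) * scaling
    grid = VoxelGrid(
        origin=origin,
        spacing=(col_spacing, row_spacing, float(dz[0])),
        dims=values.shape,
    )
    return DoseGrid(grid=grid, values=values, prescription=prescription)


def write_rtdose(dose: DoseGrid, path) -> None:
    """Write a DoseGrid as a minimal axis-aligned RT-DOSE file.

    Values are quantised to 32-bit integers with ``DoseGridScaling`` chosen
    from the dose maximum; the round trip is lossless to that stored
    precision (≈ max / 2³²).
    """
    max_dose = float(dose.values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    stored = np.round(dose.values / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImageOrientationPatient = list(_IDENTITY_ORIENTATION)
    ds.ImagePositionPatient = [f"{v:.6f}" for v in dose.grid.origin]
    ds.PixelSpacing = [f"{dose.grid.spacing[1]:.6f}", f"{dose.grid.spacing[0]:.6f}"]
    nz = dose.grid.dims[2]
    ds.GridFrameOffsetVector = [
        f"{i * dose.grid.spacing[2]:.6f}" for i in range(nz)
    ]
    ds.NumberOfFrames = nz
    ds.Rows = dose.grid.dims[1]
    ds.Columns = dose.grid.dims[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseGridScaling = f"{scaling:.10e}"
    ds.PixelData = stored.transpose(2, 1, 0).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
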