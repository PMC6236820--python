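"""NIfTI import/export for masks and dose grids.

The affine is restricted to axis-aligned scaling plus translation (v1 scope):
``affine = diag(spacing) + origin``, mapping 0-based voxel indices to
patient-space mm at voxel centers.  Masks are stored as uint8 {0, 1}; dose as
float32 with the prescription recorded in the header ``descrip`` field
(``rx=<value>Gy``) and recoverable on read.
"""

from __future__ import annotations

import re

import nibabel as nib
import numpy as np

from ..errors import InvalidMaskError, UnsupportedOrientationError
from ..geometry import BinaryMask, DoseGrid, VoxelGrid

__all__ = ["read_mask", "write_mask", "read_dose", "write_dose"]


def _affine_for(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _grid_from(img: nib.Nifti1Image) -> VoxelGrid:
    affine = img.affine
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    diag = np.diag(affine[:3, :3])
    if np.any(np.abs(off_diag) > 1e-6) or np.any(diag <= 0):
        raise UnsupportedOrientationError(
            "only axis-aligned NIfTI affines with positive spacing are supported"
        )
    return VoxelGrid(
        origin=tuple(affine[:3, 3]),
        spacing=tuple(diag),
        dims=img.shape[:3],
    )


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine_for(mask.grid))
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.isin(data, (0, 1)).all():
        raise InvalidMaskError(f"{path}: mask values must be 0 or 1")
    return BinaryMask(grid=_grid_from(img), data=data.astype(bool))


def write_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine_for(dose.grid))
    img.header["descrip"] = f"rx={dose.prescription:g}Gy".encode()
    nib.save(img, str(path))


def read_dose(path, prescription: float | None = None) -> DoseGrid:
    """Read a dose volume; the prescription comes from the header ``descrip``
    field unless overridden by the argument."""
    img = nib.load(str(path))
    if prescription is None:
        descrip = bytes(img.header["descrip"]).decode(errors="ignore")
        match = re.search(r"rx=([0-9.]+)Gy", descrip)
        if match is None:
            raise ValueError(
                f"{path}: no prescription in header; pass prescription= explicitly"
            )
        prescription = float(match.group(1))
    values = np.asarray(img.dataobj, dtype=float)
    return DoseGrid(grid=_grid_from(img), values=values, prescription=prescription)
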