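"""DICOM RT-STRUCT contour rasterization.

Each selected ROI is rasterized slice-wise onto a caller-supplied voxel grid:
a voxel is set iff its **center** lies inside the contour polygon on the
nearest slice, with the even-odd rule, so nested contours (holes) XOR out.
Only CLOSED_PLANAR contours with constant z per contour are supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset

from ..errors import StructureNotFoundError, UnsupportedGeometryError
from ..geometry import BinaryMask, VoxelGrid

__all__ = ["StructureNameMap", "read_rtstruct", "make_rtstruct_dataset"]


def _default_patterns() -> dict[str, list[str]]:
    # Placeholder clinical naming conventions; override per institution.
    return {
        "ptv": [r"^ptv.*"],
        "lung_left": [r"^lung[_ ]?l(eft)?$", r"^left[_ ]?lung$"],
        "lung_right": [r"^lung[_ ]?r(ight)?$", r"^right[_ ]?lung$"],
    }


@dataclass
class StructureNameMap:
    """Case-insensitive regex patterns mapping clinical ROI names to roles."""

    patterns: dict[str, list[str]] = field(default_factory=_default_patterns)

    def resolve(self, role: str, roi_names: list[str]) -> str:
        if role not in self.patterns:
            raise StructureNotFoundError(f"role {role!r} not in name map")
        matches = [
            name
            for name in roi_names
            if any(re.fullmatch(p, name, re.IGNORECASE) for p in self.patterns[role])
        ]
        if not matches:
            raise StructureNotFoundError(
                f"no ROI matches role {role!r} among {roi_names}"
            )
        if len(matches) > 1:
            raise StructureNotFoundError(
                f"role {role!r} is ambiguous: matches {matches}"
            )
        return matches[0]


def _contours_by_roi(ds: Dataset) -> dict[str, list[np.ndarray]]:
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.StructureSetROISequence
    }
    out: dict[str, list[np.ndarray]] = {}
    for roi in ds.ROIContourSequence:
        name = names[int(roi.ReferencedROINumber)]
        contours = out.setdefault(name, [])
        for contour in getattr(roi, "ContourSequence", []):
            gtype = str(getattr(contour, "ContourGeometricType", "CLOSED_PLANAR"))
            if gtype != "CLOSED_PLANAR":
                raise UnsupportedGeometryError(
                    f"ROI {name!r}: unsupported contour type {gtype}"
                )
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if not np.allclose(pts[:, 2], pts[0, 2], atol=1e-6):
                raise UnsupportedGeometryError(
                    f"ROI {name!r}: non-planar contour (z varies within a contour)"
                )
            contours.append(pts)
    return out


def _rasterize(contours: list[np.ndarray], grid: VoxelGrid) -> np.ndarray:
    occ = np.zeros(grid.dims, dtype=bool)
    xs = grid.axis_coordinates(0)
    ys = grid.axis_coordinates(1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.stack([xx.ravel(), yy.ravel()], axis=-1)
    for pts in contours:
        z = float(pts[0, 2])
        k = int(round((z - grid.origin[2]) / grid.spacing[2]))
        if not 0 <= k < grid.dims[2]:
            continue
        # contains_points treats the vertex list as an implicitly closed polygon
        path = MplPath(pts[:, :2])
        inside = path.contains_points(centers).reshape(len(xs), len(ys))
        # even-odd rule: nested contours (holes) toggle occupancy
        occ[:, :, k] ^= inside
    return occ


def read_rtstruct(
    source,
    grid: VoxelGrid,
    name_map: StructureNameMap | None = None,
    roles: list[str] | None = None,
) -> dict[str, BinaryMask]:
    """Rasterize the requested roles of an RT-STRUCT onto ``grid``.

    ``source`` may be a path or an open pydicom Dataset.  Returns a mapping
    role → BinaryMask for each requested role (default: every role in the
    name map that resolves).
    """
    ds = source if isinstance(source, Dataset) else pydicom.dcmread(str(source))
    name_map = name_map or StructureNameMap()
    by_roi = _contours_by_roi(ds)
    roi_names = list(by_roi)
    out: dict[str, BinaryMask] = {}
    for role in roles if roles is not None else list(name_map.patterns):
        name = name_map.resolve(role, roi_names)
        occ = _rasterize(by_roi[name], grid)
        out[role] = BinaryMask(grid=grid, data=occ)
    return out


_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def make_rtstruct_dataset(
    structures: dict[str, list[tuple[float, np.ndarray]]],
) -> Dataset:
    """Build a minimal synthetic RT-STRUCT Dataset (fixture/testing helper).

    ``structures`` maps ROI name → list of (slice z in mm, (N, 2) array of
    in-plane xy vertices in mm).  The result round-trips through
    :func:`read_rtstruct`; it is not a clinically complete structure set.
    """
    ds = Dataset()
    ds.SOPClassUID = _RTSTRUCT_SOP_CLASS
    ds.Modality = "RTSTRUCT"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, contours) in enumerate(structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        ds.StructureSetROISequence.append(roi)
        roi_contour = Dataset()
        roi_contour.ReferencedROINumber = number
        roi_contour.ContourSequence = []
        for z, xy in contours:
            xy = np.asarray(xy, dtype=float)
            contour = Dataset()
            contour.ContourGeometricType = "CLOSED_PLANAR"
            contour.NumberOfContourPoints = len(xy)
            data: list[float] = []
            for x, y in xy:
                data.extend([float(x), float(y), float(z)])
            contour.ContourData = [f"{v:.6f}" for v in data]
            roi_contour.ContourSequence.append(contour)
        ds.ROIContourSequence.append(roi_contour)
    return ds
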