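"""Signed distance transforms, isotropic margin expansion and overlap volumes.

The margin expansion used throughout the package is *geometric*: a voxel
belongs to ``PTV + m`` iff its center lies within ``m`` millimetres of the
nearest PTV voxel center, with anisotropic spacing honoured.  Expansion is
implemented by thresholding the signed Euclidean distance map of the original
mask at ``m`` (never by iterated morphological dilation), so nesting and
composition identities hold by construction and negative margins erode.

Tie rule: voxels whose signed distance equals ``m`` exactly are included
(``<=`` threshold), which makes ``expand(mask, 0)`` the identity.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateMaskError,
    EmptyOrganError,
    GridMismatchError,
    InsufficientPaddingError,
)
from .geometry import BinaryMask, SignedDistanceMap, VoxelGrid

__all__ = [
    "signed_distance_map",
    "expand_mask",
    "pad_mask",
    "fractional_volume",
    "v_of_m_curve",
]


def signed_distance_map(mask: BinaryMask) -> SignedDistanceMap:
    """Signed Euclidean distance (mm) to the nearest opposite-class voxel center.

    Negative inside the mask, positive outside; exact anisotropic EDT via
    :func:`scipy.ndimage.distance_transform_edt`.

    Raises
    ------
    DegenerateMaskError
        If the mask is all-true or all-false (no surface exists).
    """
    occ = mask.data
    if not occ.any() or occ.all():
        raise DegenerateMaskError("mask must be nonempty and not fill the grid")
    spacing = mask.grid.spacing
    # distance_transform_edt gives, for each nonzero voxel, the distance to the
    # nearest zero voxel -- i.e. to the nearest opposite-class center.
    outside = ndimage.distance_transform_edt(~occ, sampling=spacing)
    inside = ndimage.distance_transform_edt(occ, sampling=spacing)
    return SignedDistanceMap(grid=mask.grid, values=outside - inside)


def pad_mask(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Return the mask on a grid enlarged by ``ceil(margin/spacing) + 1`` false
    voxels per side, so a subsequent expansion by ``margin_mm`` cannot clip."""
    if margin_mm <= 0:
        return BinaryMask(grid=mask.grid, data=mask.data.copy())
    pads = tuple(
        int(math.ceil(margin_mm / s)) + 1 for s in mask.grid.spacing
    )
    data = np.pad(mask.data, tuple((p, p) for p in pads), constant_values=False)
    origin = tuple(
        o - p * s for o, p, s in zip(mask.grid.origin, pads, mask.grid.spacing)
    )
    grid = VoxelGrid(origin=origin, spacing=mask.grid.spacing, dims=data.shape)
    return BinaryMask(grid=grid, data=data)


def _touches_boundary(occ: np.ndarray) -> bool:
    return bool(
        occ[0, :, :].any() or occ[-1, :, :].any()
        or occ[:, 0, :].any() or occ[:, -1, :].any()
        or occ[:, :, 0].any() or occ[:, :, -1].any()
    )


def expand_mask(
    mask: BinaryMask,
    margin_mm: float,
    *,
    sdm: SignedDistanceMap | None = None,
) -> BinaryMask:
    """Isotropically expand (``margin_mm > 0``) or erode (``< 0``) a mask.

    Result occupancy is ``{signed distance <= margin_mm}``; ``margin_mm = 0``
    returns the input occupancy bit-exactly.  A precomputed ``sdm`` of the same
    mask may be passed to amortise the transform across margins.

    Raises
    ------
    InsufficientPaddingError
        If a positive expansion reaches the outermost voxel layer of the grid
        (it would be silently clipped; pad with :func:`pad_mask` first).
    """
    if margin_mm == 0:
        return BinaryMask(grid=mask.grid, data=mask.data.copy())
    if sdm is None:
        sdm = signed_distance_map(mask)
    elif not mask.grid.approx_equal(sdm.grid):
        raise GridMismatchError("sdm was computed on a different grid")
    out = sdm.values <= margin_mm
    if margin_mm > 0 and _touches_boundary(out & ~mask.data):
        raise InsufficientPaddingError(
            f"expansion by {margin_mm} mm reaches the grid boundary; "
            "pad the grid before expanding"
        )
    return BinaryMask(grid=mask.grid, data=out)


def fractional_volume(expansion: BinaryMask, organ: BinaryMask) -> float:
    """Fraction of ``organ`` covered by ``expansion``: |expansion ∩ organ| / |organ|.

    Both masks must live on the same grid; the organ must be nonempty.
    User-facing output reports this as a percent of organ volume.
    """
    if not expansion.grid.approx_equal(organ.grid):
        raise GridMismatchError("expansion and organ must share a voxel grid")
    n_organ = organ.voxel_count
    if n_organ == 0:
        raise EmptyOrganError("organ mask is empty")
    overlap = int(np.count_nonzero(expansion.data & organ.data))
    return overlap / n_organ


def v_of_m_curve(
    ptv: BinaryMask,
    organ: BinaryMask,
    m_values: Sequence[float],
    *,
    sdm: SignedDistanceMap | None = None,
) -> list[tuple[float, float]]:
    """The overlap curve V(m): fraction of ``organ`` inside ``ptv`` expanded by m.

    ``m_values`` must be ascending; the returned V values lie in [0, 1] and are
    non-decreasing in m.  Computed by thresholding the PTV signed distance map
    restricted to organ voxels, so edge clipping of the expansion far from an
    interior organ cannot bias the overlap.
    """
    m_arr = np.asarray(list(m_values), dtype=float)
    if m_arr.size == 0:
        raise ValueError("m_values must be nonempty")
    if np.any(np.diff(m_arr) < 0):
        raise ValueError("m_values must be sorted ascending")
    if not ptv.grid.approx_equal(organ.grid):
        raise GridMismatchError("ptv and organ must share a voxel grid")
    if organ.voxel_count == 0:
        raise EmptyOrganError("organ mask is empty")
    if sdm is None:
        sdm = signed_distance_map(ptv)
    d_organ = np.sort(sdm.values[organ.data])
    counts = np.searchsorted(d_organ, m_arr, side="right")
    fractions = counts / d_organ.size
    return list(zip(m_arr.tolist(), fractions.tolist()))
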