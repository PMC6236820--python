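"""Dose-grid handling and dose-volume histogram queries.

All dosimetric comparisons in the margin model are made in a common reference
frame obtained by rescaling every plan's prescription to 50.4 Gy(RBE): a voxel
dose ``d`` under prescription ``Rx`` becomes ``d * 50.4 / Rx``.  Equivalently,
querying an isodose of 20 Gy(RBE) on a 45 Gy(RBE) plan corresponds to
``20 * 45 / 50.4 ≈ 18`` Gy(RBE) in the plan's own frame.

Conventions (deterministic and oracle-checkable):

* ``V_D`` uses the closed threshold ``dose >= D``.
* ``D_V`` is read off the empirical (step) DVH: the largest dose D such that
  at least a fraction V of the organ receives >= D.  Linear interpolation
  between DVH steps is available as an option, not the default.
* Dose is resampled onto the structure grid (trilinear, 0 outside the dose
  field) before any per-voxel counting.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    EmptyOrganError,
    FalloffNotFoundError,
    GridMismatchError,
    NoOverlapError,
    UndefinedQueryError,
)
from .geometry import BinaryMask, DoseGrid, SignedDistanceMap, VoxelGrid
from .morphology import signed_distance_map

__all__ = [
    "REFERENCE_PRESCRIPTION",
    "rescale_to_reference",
    "resample_dose_to_grid",
    "volume_at_dose",
    "dose_at_volume",
    "falloff_width",
    "dvh_table",
]

REFERENCE_PRESCRIPTION = 50.4
"""Reference prescription dose in Gy(RBE) that all plans are rescaled to."""


def rescale_to_reference(
    dose: DoseGrid, reference: float = REFERENCE_PRESCRIPTION
) -> DoseGrid:
    """Rescale every voxel by ``reference / prescription``.

    The returned grid carries ``prescription = reference``.  A plan already at
    the reference prescription is returned with bit-identical values.
    """
    if dose.prescription == reference:
        return DoseGrid(grid=dose.grid, values=dose.values.copy(),
                        prescription=reference)
    factor = reference / dose.prescription
    return DoseGrid(grid=dose.grid, values=dose.values * factor,
                    prescription=reference)


def resample_dose_to_grid(dose: DoseGrid, target: VoxelGrid) -> DoseGrid:
    """Trilinear resampling of the dose onto ``target`` voxel centers.

    Positions outside the dose grid's extent map to 0 dose.  Raises
    :class:`NoOverlapError` if the two extents are spatially disjoint.
    """
    if target.approx_equal(dose.grid):
        return DoseGrid(grid=target, values=dose.values.copy(),
                        prescription=dose.prescription)
    for (lo_d, hi_d), (lo_t, hi_t) in zip(dose.grid.extent(), target.extent()):
        if hi_t < lo_d or hi_d < lo_t:
            raise NoOverlapError("dose and target grids have disjoint extents")
    axes = [dose.grid.axis_coordinates(a) for a in range(3)]
    interp = RegularGridInterpolator(
        axes, dose.values, method="linear", bounds_error=False, fill_value=0.0
    )
    xs, ys, zs = np.meshgrid(
        *(target.axis_coordinates(a) for a in range(3)), indexing="ij"
    )
    points = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=-1)
    values = interp(points).reshape(target.dims)
    values = np.maximum(values, 0.0)  # guard fp undershoot of non-negative fields
    return DoseGrid(grid=target, values=values, prescription=dose.prescription)


def _organ_doses(dose: DoseGrid, organ: BinaryMask) -> np.ndarray:
    if not dose.grid.approx_equal(organ.grid):
        raise GridMismatchError(
            "dose and organ must share a grid; resample the dose first"
        )
    if organ.voxel_count == 0:
        raise EmptyOrganError("organ mask is empty")
    return dose.values[organ.data]


def volume_at_dose(dose: DoseGrid, organ: BinaryMask, level: float) -> float:
    """V_D: fraction of organ voxels receiving at least ``level`` Gy(RBE)."""
    doses = _organ_doses(dose, organ)
    return float(np.count_nonzero(doses >= level)) / doses.size


def dose_at_volume(
    dose: DoseGrid,
    organ: BinaryMask,
    volume_fraction: float,
    *,
    interpolate: bool = False,
) -> float:
    """D_V: the largest dose D such that ``volume_at_dose(..., D) >= V``.

    Read off the empirical step DVH of the organ's voxel doses: with the doses
    sorted descending, D_V is the ``ceil(V * n)``-th value.  ``V = 1`` yields
    the minimum organ dose.  With ``interpolate=True``, D is interpolated
    linearly between adjacent DVH steps.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise UndefinedQueryError(
            f"volume fraction must be in (0, 1], got {volume_fraction}"
        )
    doses = np.sort(_organ_doses(dose, organ))[::-1]
    n = doses.size
    if not interpolate:
        k = int(math.ceil(volume_fraction * n - 1e-12))
        return float(doses[k - 1])
    # piecewise-linear DVH: step i covers fraction (i + 1) / n
    fractions = (np.arange(n) + 1.0) / n
    return float(np.interp(volume_fraction, fractions, doses))


def falloff_width(
    dose: DoseGrid,
    ptv: BinaryMask,
    hi: float = 0.8,
    lo: float = 0.2,
    *,
    step_mm: float = 1.0,
    max_scan_mm: float = 80.0,
    sdm: SignedDistanceMap | None = None,
) -> float:
    """Average hi%-to-lo% dose falloff distance (mm) outside the PTV.

    Scans expansion shells ``expand(ptv, m) \\ expand(ptv, m - step)`` for
    ascending m and records the first margin at which the shell-mean dose
    drops below ``hi * prescription`` and below ``lo * prescription``; the
    width is the difference of the two margins.  The dose should already be in
    the reference prescription frame.
    """
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    if not dose.grid.approx_equal(ptv.grid):
        raise GridMismatchError("dose and ptv must share a grid")
    if sdm is None:
        sdm = signed_distance_map(ptv)
    d = sdm.values
    rx = dose.prescription
    m_hi: float | None = None
    m_lo: float | None = None
    m = step_mm
    while m <= max_scan_mm + 1e-9:
        shell = (d > m - step_mm) & (d <= m)
        if shell.any():
            mean_dose = float(dose.values[shell].mean())
            if m_hi is None and mean_dose < hi * rx:
                m_hi = m
            if mean_dose < lo * rx:
                m_lo = m
                break
        m += step_mm
    if m_lo is None:
        raise FalloffNotFoundError(
            f"shell-mean dose never fell below {lo:.0%} of prescription "
            f"within {max_scan_mm} mm"
        )
    if m_hi is None:  # dose already below hi*rx at the first shell
        m_hi = step_mm
    return m_lo - m_hi


def dvh_table(dose: DoseGrid, organ: BinaryMask, n_bins: int = 200) -> pd.DataFrame:
    """Cumulative DVH as a table with columns ``dose_Gy_RBE``, ``fractional_volume``."""
    doses = _organ_doses(dose, organ)
    levels = np.linspace(0.0, float(doses.max()), n_bins)
    fractions = [float(np.count_nonzero(doses >= lv)) / doses.size for lv in levels]
    return pd.DataFrame({"dose_Gy_RBE": levels, "fractional_volume": fractions})
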