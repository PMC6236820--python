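"""Synthetic thoracic phantoms with exactly conformal dose.

The phantom emulates the geometry the margin model assumes: an ellipsoidal
lung, a curved shell-like PTV that follows the lung surface over an anterior
angular sector (breast/chest-wall target) separated from the lung by a
chest-wall gap, and a dose whose isodose surfaces are *exact* isotropic
expansions of the PTV.  Dose at a voxel is

    dose = prescription * f(max(0, d)),

where d is the signed distance to the PTV and f a piecewise-linear falloff
profile with f(0) = 1.  Hence the D isodose surface coincides voxel-exactly
with ``expand(ptv, f⁻¹(D / prescription))`` under the shared ``<=``
conventions — the property that makes margin calibration on phantom cohorts a
parameter-recovery exercise with a known answer.

The default falloff anchors place the 20 Gy(RBE) reference-frame isodose at
11 mm and the 5 Gy(RBE) isodose at 22 mm outside the PTV, so calibration on a
noiseless default cohort recovers those margins.  A cold-spot variant caps the
dose inside a (typically medial) region, breaking conformality the way
deliberate heart sparing does in clinical plans; the contour-only model then
overestimates the lung dose, reproducing the known failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dvh import REFERENCE_PRESCRIPTION
from .errors import DegenerateSpecError, GridMismatchError, InvalidFalloffError
from .geometry import BinaryMask, DoseGrid, SignedDistanceMap, VoxelGrid
from .model import CohortRecord
from .morphology import signed_distance_map

__all__ = [
    "FalloffProfile",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "conformal_dose",
    "make_cohort",
    "cold_spot_variant",
    "medial_cold_spot_region",
]

# Reference-frame construction constants: 20 Gy(RBE) at 11 mm, 5 Gy(RBE) at 22 mm.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 1.0),
    (11.0, 20.0 / 50.4),
    (22.0, 5.0 / 50.4),
    (35.0, 0.0),
)


@dataclass(frozen=True)
class FalloffProfile:
    """Piecewise-linear dose-vs-distance profile outside the PTV.

    Anchors map distance (mm, from the PTV surface) to a fraction of the
    prescription; they must start at (0, 1.0), be strictly increasing in
    distance and strictly decreasing in fraction.  Beyond the last anchor the
    fraction is held constant (the default profile ends at 0).
    """

    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        anchors = tuple((float(d), float(f)) for d, f in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if len(anchors) < 2:
            raise InvalidFalloffError("at least two anchors required")
        if anchors[0] != (0.0, 1.0):
            raise InvalidFalloffError("profile must start at (0 mm, 1.0)")
        ds = np.array([d for d, _ in anchors])
        fs = np.array([f for _, f in anchors])
        if np.any(np.diff(ds) <= 0) or np.any(np.diff(fs) >= 0):
            raise InvalidFalloffError(
                "anchor distances must strictly increase and fractions strictly decrease"
            )
        if np.any(fs < 0):
            raise InvalidFalloffError("fractions must be non-negative")

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for d, _ in self.anchors])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.anchors])

    def fraction_at(self, distance_mm: np.ndarray | float) -> np.ndarray | float:
        """f(d): fraction of prescription at distance d outside the PTV."""
        return np.interp(distance_mm, self.distances, self.fractions)

    def distance_at(self, fraction: float) -> float:
        """f⁻¹: distance (mm) at which the profile crosses ``fraction``."""
        fs = self.fractions
        if not fs[-1] <= fraction <= fs[0]:
            raise InvalidFalloffError(
                f"fraction {fraction} outside profile range [{fs[-1]}, {fs[0]}]"
            )
        # np.interp needs ascending x: reverse both axes of the profile
        return float(np.interp(fraction, fs[::-1], self.distances[::-1]))

    def shifted(self, offsets_mm: np.ndarray) -> "FalloffProfile":
        """Profile with interior anchor distances shifted (first anchor pinned
        at 0, ordering preserved by sequential clipping)."""
        ds = self.distances.copy()
        for i, off in zip(range(1, ds.size), np.atleast_1d(offsets_mm)):
            lo = ds[i - 1] + 0.5
            ds[i] = max(ds[i] + off, lo)
        ds = np.maximum.accumulate(ds + np.arange(ds.size) * 1e-9)
        return FalloffProfile(anchors=tuple(zip(ds.tolist(), self.fractions.tolist())))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic thoracic case (all lengths in mm).

    ``jitter_mm`` is the per-case perturbation scale applied by
    :func:`make_cohort` to every mm-valued geometric parameter *and* to the
    falloff anchor distances; the latter emulates case-to-case variation in
    achieved conformality, without which a phantom cohort would have exactly
    zero prediction error.  ``jitter_mm = 0`` gives a noiseless cohort.
    """

    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_semiaxes: tuple[float, float, float] = (40.0, 55.0, 70.0)
    chest_gap_mm: float = 5.0
    shell_thickness_mm: float = 20.0
    sector_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    sector_half_angle_deg: float = 55.0
    falloff: FalloffProfile = field(default_factory=FalloffProfile)
    prescription: float = REFERENCE_PRESCRIPTION
    jitter_mm: float = 2.0
    seed: int = 0
    headroom_mm: float = 48.0

    def __post_init__(self) -> None:
        if self.chest_gap_mm < 0:
            raise DegenerateSpecError("chest-wall gap must be >= 0")
        if self.shell_thickness_mm <= 0:
            raise DegenerateSpecError("shell thickness must be positive")
        if any(a <= 0 for a in self.lung_semiaxes):
            raise DegenerateSpecError("lung semi-axes must be positive")
        if not 0 < self.sector_half_angle_deg <= 180:
            raise DegenerateSpecError("sector half-angle must be in (0, 180] degrees")


@dataclass
class Phantom:
    """One synthetic case: PTV and lung masks on a shared grid."""

    ptv: BinaryMask
    lung: BinaryMask
    grid: VoxelGrid


def _build_grid(spec: PhantomSpec) -> VoxelGrid:
    reach = spec.chest_gap_mm + spec.shell_thickness_mm + spec.headroom_mm
    half = tuple(a + reach for a in spec.lung_semiaxes)
    dims = tuple(int(np.ceil(2 * h / s)) + 1 for h, s in zip(half, spec.spacing))
    origin = tuple(-(d - 1) / 2 * s for d, s in zip(dims, spec.spacing))
    return VoxelGrid(origin=origin, spacing=spec.spacing, dims=dims)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the lung ellipsoid and the shell-sector PTV abutting it.

    The PTV is the set of voxels whose distance outside the lung lies in
    ``[gap, gap + thickness]`` and whose direction from the lung center falls
    inside the anterior sector cone — a curved shell following the lung
    surface at the chest-wall gap.  Deterministic (no randomness here; cohort
    jitter lives in :func:`make_cohort`).
    """
    grid = _build_grid(spec)
    xs, ys, zs = grid.center_coordinates()
    a, b, c = spec.lung_semiaxes
    lung_occ = (xs / a) ** 2 + (ys / b) ** 2 + (zs / c) ** 2 <= 1.0
    if not lung_occ.any():
        raise DegenerateSpecError("lung ellipsoid contains no voxel centers")

    # distance outside the lung, to the nearest lung voxel center
    dist_out = ndimage.distance_transform_edt(~lung_occ, sampling=grid.spacing)
    band = (dist_out >= spec.chest_gap_mm) & (
        dist_out <= spec.chest_gap_mm + spec.shell_thickness_mm
    ) & ~lung_occ

    axis = np.asarray(spec.sector_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    radial = np.sqrt(xs**2 + ys**2 + zs**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (xs * axis[0] + ys * axis[1] + zs * axis[2]) / radial
    cosang = np.where(radial > 0, cosang, 1.0)
    sector = cosang >= np.cos(np.deg2rad(spec.sector_half_angle_deg))

    ptv_occ = band & sector
    if not ptv_occ.any():
        raise DegenerateSpecError("PTV shell sector contains no voxel centers")
    return Phantom(
        ptv=BinaryMask(grid=grid, data=ptv_occ),
        lung=BinaryMask(grid=grid, data=lung_occ),
        grid=grid,
    )


def conformal_dose(
    ptv: BinaryMask,
    params: FalloffProfile,
    prescription: float,
    *,
    sdm: SignedDistanceMap | None = None,
) -> DoseGrid:
    """Dose grid whose isodose surfaces are exact PTV expansions.

    ``dose = prescription * f(max(0, d))`` with d the signed distance to the
    PTV: flat at prescription inside, falling off with the profile outside.
    """
    if sdm is None:
        sdm = signed_distance_map(ptv)
    elif not ptv.grid.approx_equal(sdm.grid):
        raise GridMismatchError("sdm was computed on a different grid")
    outside = np.maximum(sdm.values, 0.0)
    values = prescription * np.asarray(params.fraction_at(outside))
    return DoseGrid(grid=ptv.grid, values=values, prescription=prescription)


# prescriptions cycled across cohort cases, Gy(RBE): exercises reference rescaling
_COHORT_PRESCRIPTIONS = (50.4, 45.0, 63.0)


def _jittered_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    s = spec.jitter_mm

    def draw(scale: float = s) -> float:
        return float(np.clip(rng.normal(0.0, scale), -2 * scale, 2 * scale))

    semiaxes = tuple(max(15.0, a + draw()) for a in spec.lung_semiaxes)
    gap = max(0.0, spec.chest_gap_mm + draw())
    thickness = max(4.0, spec.shell_thickness_mm + draw())
    offsets = np.array([draw() for _ in range(len(spec.falloff.anchors) - 1)])
    falloff = spec.falloff.shifted(offsets)
    return replace(
        spec,
        lung_semiaxes=semiaxes,
        chest_gap_mm=gap,
        shell_thickness_mm=thickness,
        falloff=falloff,
    )


def make_cohort(n: int, spec: PhantomSpec) -> list[CohortRecord]:
    """Generate ``n`` phantom cases with jittered geometry and conformal dose.

    Laterality alternates left/right (the phantom geometry is laterally
    symmetric; laterality is cohort bookkeeping), prescriptions cycle through
    50.4/45/63 Gy(RBE), and all randomness derives from ``spec.seed``, so the
    cohort is bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    for i in range(n):
        case_spec = _jittered_spec(spec, rng) if spec.jitter_mm > 0 else spec
        phantom = make_phantom(case_spec)
        prescription = _COHORT_PRESCRIPTIONS[i % len(_COHORT_PRESCRIPTIONS)]
        dose = conformal_dose(phantom.ptv, case_spec.falloff, prescription)
        records.append(
            CohortRecord(
                case_id=f"phantom-{i:03d}",
                laterality="left" if i % 2 == 0 else "right",
                ptv=phantom.ptv,
                ipsilateral_lung=phantom.lung,
                prescription=prescription,
                dose=dose,
            )
        )
    return records


def cold_spot_variant(
    dose: DoseGrid,
    ptv: BinaryMask,
    region: BinaryMask,
    floor: float,
) -> DoseGrid:
    """Cap the dose at ``floor`` inside ``region``; elsewhere unchanged.

    Emulates deliberate underdosing of part of the target (e.g. heart
    sparing): inside the region the dose becomes ``min(dose, floor)``.  An
    empty region returns the dose unchanged.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if not dose.grid.approx_equal(region.grid) or not dose.grid.approx_equal(ptv.grid):
        raise GridMismatchError("dose, ptv and region must share a grid")
    values = np.where(region.data, np.minimum(dose.values, floor), dose.values)
    return DoseGrid(grid=dose.grid, values=values, prescription=dose.prescription)


def medial_cold_spot_region(
    ptv: BinaryMask, radius_mm: float = 25.0
) -> BinaryMask:
    """Ball of ``radius_mm`` centered on the PTV's medial-most voxel (minimal
    x); covers part of the PTV and the adjacent lung falloff, the geometry of
    a heart-sparing compromise."""
    if ptv.is_empty:
        raise ValueError("ptv is empty")
    idx = np.argwhere(ptv.data)
    medial = idx[np.argmin(idx[:, 0])]
    grid = ptv.grid
    center = tuple(
        grid.origin[a] + medial[a] * grid.spacing[a] for a in range(3)
    )
    xs, ys, zs = grid.center_coordinates()
    occ = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2 \
        <= radius_mm**2
    return BinaryMask(grid=grid, data=occ)
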