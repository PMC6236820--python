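"""Voxel-grid geometry and the in-memory volume types.

Conventions
-----------
* Patient-space coordinates in millimetres; arrays are indexed ``[i, j, k]``
  along the (x, y, z) axes.
* Voxel ``(i, j, k)`` has its **center** at ``origin + (i, j, k) * spacing``
  (0-based indices).  A voxel belongs to a structure iff its center does.
* Spacing may be anisotropic (CT slices are typically thicker than the
  in-plane pixel pitch) and is always strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvalidPrescriptionError

__all__ = ["VoxelGrid", "BinaryMask", "SignedDistanceMap", "DoseGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometric frame shared by masks and dose grids.

    Parameters
    ----------
    origin
        Patient-space position (mm) of the center of voxel (0, 0, 0).
    spacing
        Voxel pitch (mm) along (x, y, z); strictly positive, may differ per axis.
    dims
        Voxel counts along (x, y, z); each at least 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must each have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def center_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse meshgrid) voxel-center coordinate arrays."""
        return tuple(  # type: ignore[return-value]
            np.meshgrid(*(self.axis_coordinates(a) for a in range(3)),
                        indexing="ij", sparse=True)
        )

    def extent(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (low, high) voxel-center coordinate bounds in mm."""
        return tuple(
            (self.origin[a], self.origin[a] + self.spacing[a] * (self.dims[a] - 1))
            for a in range(3)
        )

    def approx_equal(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def _require_same_grid(a: VoxelGrid, b: VoxelGrid, what: str) -> None:
    if not a.approx_equal(b):
        raise GridMismatchError(f"{what}: grids differ ({a} vs {b})")


@dataclass
class BinaryMask:
    """A structure (PTV, lung, ...) as voxel occupancy on a grid."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    @property
    def volume_cc(self) -> float:
        """Volume in cubic centimetres: occupied voxels times voxel volume."""
        return self.voxel_count * self.grid.voxel_volume_cc

    def same_grid_as(self, other: "BinaryMask | DoseGrid | SignedDistanceMap") -> bool:
        return self.grid.approx_equal(other.grid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.grid.approx_equal(other.grid) and bool(
            np.array_equal(self.data, other.data)
        )


@dataclass
class SignedDistanceMap:
    """Per-voxel signed Euclidean distance (mm) to the nearest voxel center of
    the opposite class: negative inside the source mask, positive outside."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"distance shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose in Gy(RBE) with its prescription dose."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)
    prescription: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"dose shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if not self.prescription > 0:
            raise InvalidPrescriptionError(
                f"prescription must be positive, got {self.prescription}"
            )
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
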