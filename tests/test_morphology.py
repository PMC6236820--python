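"""Signed distances, margin expansion and overlap volumes."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lungmargin import (
    BinaryMask,
    VoxelGrid,
    expand_mask,
    fractional_volume,
    pad_mask,
    signed_distance_map,
    v_of_m_curve,
)
from lungmargin.errors import (
    DegenerateMaskError,
    EmptyOrganError,
    GridMismatchError,
    InsufficientPaddingError,
)

from conftest import random_mask


def brute_force_signed_distance(mask: BinaryMask) -> np.ndarray:
    """Exhaustive nearest-opposite-voxel-center oracle (O(n^2))."""
    grid = mask.grid
    coords = np.stack(
        np.meshgrid(*(grid.axis_coordinates(a) for a in range(3)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    occ = mask.data.ravel()
    inside, outside = coords[occ], coords[~occ]
    d = np.empty(occ.size)
    d[occ] = -cdist(inside, outside).min(axis=1)
    d[~occ] = cdist(outside, inside).min(axis=1)
    return d.reshape(mask.grid.dims)


def sphere_mask(radius, spacing=(1.0, 1.0, 1.0), pad_mm=12.0) -> BinaryMask:
    half = radius + pad_mm
    dims = tuple(int(np.ceil(2 * half / s)) + 1 for s in spacing)
    origin = tuple(-(d - 1) / 2 * s for d, s in zip(dims, spacing))
    grid = VoxelGrid(origin=origin, spacing=spacing, dims=dims)
    xs, ys, zs = grid.center_coordinates()
    return BinaryMask(grid=grid, data=xs**2 + ys**2 + zs**2 <= radius**2)


class TestSignedDistance:
    def test_single_voxel_anisotropic_neighbors(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 2), dims=(5, 5, 5))
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        sdm = signed_distance_map(BinaryMask(grid=grid, data=data))
        assert sdm.values[2, 2, 3] == pytest.approx(2.0)  # thick-slice neighbor
        assert sdm.values[2, 3, 2] == pytest.approx(1.0)
        assert sdm.values[3, 3, 2] == pytest.approx(np.sqrt(2.0))
        assert sdm.values[2, 2, 2] == pytest.approx(-1.0)

    def test_solid_block_center_distance(self):
        # center of a 3x3x3 solid block is TWO voxel steps from the nearest
        # outside voxel center along the finest-spacing axis
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1.5, 2), dims=(9, 9, 9))
        data = np.zeros((9, 9, 9), bool)
        data[3:6, 3:6, 3:6] = True
        sdm = signed_distance_map(BinaryMask(grid=grid, data=data))
        assert sdm.values[4, 4, 4] == pytest.approx(-2.0)

    def test_matches_exhaustive_oracle_random_mask(self):
        rng = np.random.default_rng(42)
        mask = random_mask((12, 12, 12), (1.0, 1.5, 2.0), rng)
        sdm = signed_distance_map(mask)
        oracle = brute_force_signed_distance(mask)
        assert np.max(np.abs(sdm.values - oracle)) < 1e-9

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        mask = random_mask((8, 8, 8), (1.0, 1.0, 1.0), rng)
        sdm = signed_distance_map(mask)
        assert (sdm.values[mask.data] < 0).all()
        assert (sdm.values[~mask.data] > 0).all()

    @pytest.mark.parametrize("fill", [True, False])
    def test_degenerate_mask_rejected(self, fill):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(4, 4, 4))
        mask = BinaryMask(grid=grid, data=np.full((4, 4, 4), fill))
        with pytest.raises(DegenerateMaskError):
            signed_distance_map(mask)


class TestExpansion:
    def test_zero_margin_is_identity(self):
        rng = np.random.default_rng(11)
        mask = random_mask((10, 10, 10), (1.0, 1.0, 2.0), rng)
        assert expand_mask(mask, 0.0) == mask

    def test_sphere_expansion_matches_analytic_volume_ratio(self):
        sphere = sphere_mask(20.0)
        expanded = expand_mask(sphere, 10.0)
        ratio = expanded.voxel_count / sphere.voxel_count
        assert ratio == pytest.approx((30.0 / 20.0) ** 3, rel=0.02)

    def test_erosion_beyond_inradius_empties(self):
        # nearest outside center to the sphere's middle is the diagonal voxel
        # (3,3,3) at ~5.2 mm, so eroding by 6 mm removes everything
        sphere = sphere_mask(5.0, pad_mm=4.0)
        assert expand_mask(sphere, -6.0).is_empty

    def test_nesting_is_exact(self):
        rng = np.random.default_rng(5)
        data = np.zeros((14, 14, 12), bool)
        data[5:9, 5:9, 4:8] = rng.random((4, 4, 4)) < 0.4
        data[6, 6, 5] = True
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1.0, 1.0, 1.5), dims=(14, 14, 12))
        mask = BinaryMask(grid=grid, data=data)
        sdm = signed_distance_map(mask)
        margins = [-3.0, -1.0, 0.0, 1.0, 2.5, 4.0]
        previous = None
        for m in margins:
            current = expand_mask(mask, m, sdm=sdm)
            if previous is not None:
                assert not np.any(previous.data & ~current.data)
            previous = current

    def test_clipped_expansion_raises_and_padding_fixes_it(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(7, 7, 7))
        data = np.zeros((7, 7, 7), bool)
        data[3, 3, 3] = True
        mask = BinaryMask(grid=grid, data=data)
        with pytest.raises(InsufficientPaddingError):
            expand_mask(mask, 5.0)
        padded = pad_mask(mask, 5.0)
        expanded = expand_mask(padded, 5.0)
        assert expanded.voxel_count > mask.voxel_count
        # padded grid keeps voxel centers in place
        assert padded.grid.origin == (-6.0, -6.0, -6.0)


class TestOverlap:
    def test_disjoint_masks_give_zero(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(10, 10, 10))
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:3], b[7:] = True, True
        assert fractional_volume(BinaryMask(grid=grid, data=a),
                                 BinaryMask(grid=grid, data=b)) == 0.0

    def test_contained_organ_gives_one(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(10, 10, 10))
        outer = np.zeros((10, 10, 10), bool)
        inner = np.zeros((10, 10, 10), bool)
        outer[2:8, 2:8, 2:8] = True
        inner[4:6, 4:6, 4:6] = True
        assert fractional_volume(BinaryMask(grid=grid, data=outer),
                                 BinaryMask(grid=grid, data=inner)) == 1.0

    def test_matches_voxel_count_oracle_exactly(self):
        rng = np.random.default_rng(9)
        a = random_mask((20, 20, 20), (1.0, 1.0, 1.0), rng, p=0.4)
        b = random_mask((20, 20, 20), (1.0, 1.0, 1.0), rng, p=0.4)
        expected = np.count_nonzero(a.data & b.data) / np.count_nonzero(b.data)
        assert fractional_volume(a, b) == expected

    def test_grid_mismatch_and_empty_organ_rejected(self):
        g1 = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(5, 5, 5))
        g2 = VoxelGrid(origin=(1, 0, 0), spacing=(1, 1, 1), dims=(5, 5, 5))
        m1 = BinaryMask(grid=g1, data=np.ones((5, 5, 5), bool))
        m2 = BinaryMask(grid=g2, data=np.ones((5, 5, 5), bool))
        empty = BinaryMask(grid=g1, data=np.zeros((5, 5, 5), bool))
        with pytest.raises(GridMismatchError):
            fractional_volume(m1, m2)
        with pytest.raises(EmptyOrganError):
            fractional_volume(m1, empty)


class TestOverlapCurve:
    def test_monotone_and_bounded_on_phantom(self, small_phantom):
        margins = np.arange(-5.0, 30.0, 2.5)
        pairs = v_of_m_curve(small_phantom.ptv, small_phantom.lung, margins)
        values = np.array([v for _, v in pairs])
        assert np.all(values >= 0) and np.all(values <= 1)
        assert np.all(np.diff(values) >= 0)

    def test_zero_margin_consistent_with_fractional_volume(self, small_phantom):
        (_, v0), = v_of_m_curve(small_phantom.ptv, small_phantom.lung, [0.0])
        assert v0 == fractional_volume(small_phantom.ptv, small_phantom.lung)

    def test_matches_independent_per_margin_expansion(self, small_phantom):
        ptv, lung = small_phantom.ptv, small_phantom.lung
        margins = [0.0, 4.0, 9.0, 15.0]
        pairs = v_of_m_curve(ptv, lung, margins)
        for m, v in pairs:
            expanded = expand_mask(ptv, m)
            assert v == fractional_volume(expanded, lung)

    def test_distant_organ_gives_all_zero(self):
        grid = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(30, 8, 8))
        ptv = np.zeros((30, 8, 8), bool)
        organ = np.zeros((30, 8, 8), bool)
        ptv[1:3, 3:5, 3:5] = True
        organ[27:29, 3:5, 3:5] = True
        pairs = v_of_m_curve(BinaryMask(grid=grid, data=ptv),
                             BinaryMask(grid=grid, data=organ), [0.0, 5.0, 10.0])
        assert all(v == 0.0 for _, v in pairs)
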