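"""Shared fixtures: synthetic phantoms at two sizes.

The "small" spec shrinks the thoracic geometry so unit tests stay fast; the
default spec (2 mm voxels, full-size lung) is reserved for the end-to-end
calibration checks and is built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungmargin import (
    BinaryMask,
    FalloffProfile,
    PhantomSpec,
    VoxelGrid,
    conformal_dose,
    make_cohort,
    make_phantom,
)


def small_spec(**overrides) -> PhantomSpec:
    base = dict(
        spacing=(2.0, 2.0, 2.0),
        lung_semiaxes=(20.0, 26.0, 32.0),
        chest_gap_mm=4.0,
        shell_thickness_mm=12.0,
        headroom_mm=28.0,
        jitter_mm=0.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(small_spec())


@pytest.fixture(scope="session")
def small_phantom_dose(small_phantom):
    return conformal_dose(small_phantom.ptv, FalloffProfile(), 50.4)


@pytest.fixture(scope="session")
def small_cohort():
    """Four noiseless conformal cases at reduced size."""
    return make_cohort(4, small_spec())


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec(jitter_mm=0.0))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Ten noiseless conformal cases at the full default geometry."""
    return make_cohort(10, PhantomSpec(jitter_mm=0.0))


@pytest.fixture(scope="session")
def jittered_stream():
    """Fourteen jittered cases (fixed seed) for the cohort-growth procedure."""
    return make_cohort(14, PhantomSpec(jitter_mm=2.0, seed=7))


def random_mask(shape, spacing, rng, p=0.3, origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    grid = VoxelGrid(origin=origin, spacing=spacing, dims=shape)
    data = rng.random(shape) < p
    if not data.any():
        data.flat[0] = True
    if data.all():
        data.flat[-1] = False
    return BinaryMask(grid=grid, data=data)
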