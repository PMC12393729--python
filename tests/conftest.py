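"""Shared fixtures.

The fluid fixtures are session-scoped: equilibrating the reference WCA
fluid and tessellating its tilings is by far the most expensive setup
and is reused across the fluid, diagnostics and acceptance tests.
"""

import numpy as np
import pytest

from colonylat import fluid as fl
from colonylat.lattice import (
    VrlParams,
    build_restricted_vrl,
    lattice_from_points,
    rescale_to_unit_spacing,
    tile_lattice,
)

FLUID_SEED = 42


@pytest.fixture(scope="session")
def fluid_state():
    params = fl.FluidParams(
        n_particles=2500, equilibration_steps=20_000, seed=FLUID_SEED
    )
    return fl.run_fluid(params, sample_every=100)


@pytest.fixture(scope="session")
def fluid_points(fluid_state):
    return fl.snapshot_to_points(fluid_state)


@pytest.fixture(scope="session")
def fluid_lattice(fluid_points):
    return rescale_to_unit_spacing(lattice_from_points(fluid_points, kind="fluid"))


@pytest.fixture(scope="session")
def fluid_lattice_2x2(fluid_lattice):
    return rescale_to_unit_spacing(tile_lattice(fluid_lattice, 2, 2))


@pytest.fixture(scope="session")
def fluid_lattice_4x4(fluid_lattice):
    return rescale_to_unit_spacing(tile_lattice(fluid_lattice, 4, 4))


@pytest.fixture(scope="session")
def rvrl_lattice():
    """Small rescaled restricted VRL shared by solver tests."""
    return rescale_to_unit_spacing(
        build_restricted_vrl(VrlParams(16, 16, 0.5, seed=3))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
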