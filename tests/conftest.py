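"""Shared fixtures: solved reference field and analytic test fields."""

import numpy as np
import pytest

from mstsim.config import preset
from mstsim.fixtures import FixtureSpec, make_fixture
from mstsim.thermal import midplane_field, solve_steady_temperature
from mstsim.transport import ParticleModel


@pytest.fixture(scope="session")
def reference_solution():
    """Nonlinear steady solve of the default chamber at 20.5 mW."""
    cfg = preset(20.5)
    q_v = cfg.laser.q_v(cfg.chamber)
    return solve_steady_temperature(cfg.chamber, cfg.thermal, q_v, cfg.solver)


@pytest.fixture(scope="session")
def reference_field(reference_solution):
    """Mid-plane Cartesian field of the 20.5 mW solution (default grid)."""
    return midplane_field(reference_solution, 150e-6, 0.5e-6)


@pytest.fixture(scope="session")
def particle():
    return ParticleModel()


@pytest.fixture()
def flat_field():
    return make_fixture(FixtureSpec("flat", half_width=60e-6, spacing=1e-6))


@pytest.fixture()
def linear_field():
    # T = ambient + 1e4 K/m * x
    return make_fixture(
        FixtureSpec("linear", amplitude=0.5, length_scale=50e-6, half_width=60e-6, spacing=1e-6)
    )


@pytest.fixture()
def gaussian_field():
    return make_fixture(
        FixtureSpec("gaussian", amplitude=2.0, length_scale=10e-6, half_width=40e-6, spacing=0.5e-6)
    )
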