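import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ironfront as irf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return irf.default_parameters()


@pytest.fixture(scope="session")
def grid(params):
    return irf.RadialGrid.from_radius(params.R_dish, 900)


@pytest.fixture(scope="session")
def coarse_grid(params):
    return irf.RadialGrid.from_radius(params.R_dish, 300)


@pytest.fixture(scope="session")
def producer_traj(params, grid):
    """Full 160 h producer run at the default grid, with field snapshots."""
    return irf.simulate(
        params, grid, t_end=160.0, snapshot_times=[20.0, 40.0, 80.0, 120.0, 160.0]
    )


@pytest.fixture(scope="session")
def mutant_traj(params, grid):
    """Full 160 h non-producer (kb=0) run at the default grid."""
    return irf.simulate(
        params.as_mutant(), grid, t_end=160.0, snapshot_times=[40.0, 160.0]
    )
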