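import numpy as np
import pytest

from strandflow import Grid, RadSolver, preset
from strandflow.params import PHASES


@pytest.fixture(scope="session")
def spheroid():
    return preset("spheroid")


@pytest.fixture(scope="session")
def spheroid_grid(spheroid):
    return Grid.for_params(spheroid, dx=2.5, dt=2.5)


@pytest.fixture(scope="session")
def well_mixed_params(spheroid):
    """Spheroid rates with entry suppression and all active speeds off."""
    return spheroid.with_overrides(c1=0.0, V={p: 0.0 for p in PHASES})


@pytest.fixture(scope="session")
def stationary_no_drift(spheroid, spheroid_grid):
    """Entry-profile steady state with V_G2 = 0 (pre-switch state)."""
    p = spheroid.with_overrides(V={**spheroid.V, "G2": 0.0})
    solver = RadSolver(p, spheroid_grid)
    fld, age = solver.stationary_state()
    return solver, fld, age


@pytest.fixture(scope="session")
def stationary_full(spheroid, spheroid_grid):
    """Steady state of the full model (entry profile + G2 advection)."""
    solver = RadSolver(spheroid, spheroid_grid)
    fld, age = solver.stationary_state()
    return solver, fld, age


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
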