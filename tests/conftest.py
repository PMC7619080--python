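"""Shared fixtures: small, fast simulations reused across test modules.

Expensive network runs are session-scoped so the suite pays for each
simulation once.  Reduced sizes (short durations, n_side=16-24) are
used everywhere except the acceptance tests, which run the calibrated
study conditions.
"""

import numpy as np
import pytest

from thetasweep.hd_network import HDParams, run_hd
from thetasweep.grid_network import CoupledRun, GridParams, run_grid
from thetasweep.trajectory import make_straight_run


@pytest.fixture(scope="session")
def straight_traj():
    return make_straight_run(0.5, np.deg2rad(45), 3.0)


@pytest.fixture(scope="session")
def hd_run_default(straight_traj):
    """Calibrated HD network on a short straight run (theta sweeps)."""
    return run_hd(straight_traj, HDParams(), warmup=0.5)


@pytest.fixture(scope="session")
def small_grid_params():
    return GridParams(n_side=24)


@pytest.fixture(scope="session")
def coupled_small(straight_traj, hd_run_default, small_grid_params):
    """Coupled run with a reduced 24x24 torus for integration tests."""
    mod = run_grid(straight_traj, hd_run_default, small_grid_params,
                   warmup=0.5)
    return CoupledRun(traj=straight_traj, hd=hd_run_default, modules=[mod])
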