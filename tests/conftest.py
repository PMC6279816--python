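import warnings

import numpy as np
import pytest

from inertial_abp import SimConfig, simulate_ensemble
from inertial_abp.simulate import preset

# the orientation-freeze warning is informational; tests pick dt deliberately
warnings.filterwarnings("ignore", category=RuntimeWarning, message=".*splitting error.*")


@pytest.fixture(scope="session")
def fig2():
    """Generic-particle parameter set (circling, strong rotational noise)."""
    return preset("fig2")


@pytest.fixture(scope="session")
def fig6():
    """Torque-free density-sweep base parameter set."""
    return preset("fig6")


@pytest.fixture(scope="session")
def fig2_ensemble(fig2):
    """A moderate stationary ensemble at camera-like sampling, shared across tests."""
    cfg = SimConfig(
        dt=0.0066, n_steps=4000, n_runs=64, seed=11, init_mode="stationary"
    )
    return simulate_ensemble(fig2, cfg)


@pytest.fixture(scope="session")
def fig2_curves(fig2_ensemble):
    from inertial_abp import compute_curveset

    lags = np.unique(np.round(np.geomspace(1, 3800, 50)).astype(int))
    return compute_curveset(
        fig2_ensemble, k=1, msd_lags=lags, delay_lags=np.arange(0, 150, 3)
    )
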