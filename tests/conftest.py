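import numpy as np
import pytest

from emobook.dynamics import DYNAMICS_NAMES, LINC_MINUTES, make_dynamics

ALL_DYNAMICS = sorted(DYNAMICS_NAMES)
ALL_LINC = list(LINC_MINUTES)


@pytest.fixture(scope="session")
def rng():
    return np.random.RandomState(20260101)


@pytest.fixture(scope="session")
def params_grid():
    """One calibrated parameter set per (dynamics, linc) at LHW 2880."""
    return {(name, linc): make_dynamics(name, linc, 2880.0)
            for name in ALL_DYNAMICS for linc in ALL_LINC}


@pytest.fixture(scope="session")
def tiny_run():
    """A single very short run shared by engine/analysis tests."""
    from emobook.engine import RunConfig, run_simulation

    cfg = RunConfig(dynamics="alternative", linc="fast", lhw=720.0, lps=0.99,
                    seed=42, scale=0.01)
    return cfg, run_simulation(cfg)
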