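import numpy as np
import pytest

from lfplocal import benchmarks, simulate_session


@pytest.fixture(scope="session")
def vc_dataset():
    """Small volume-conduction session (6 channels, 10 trials)."""
    return simulate_session(benchmarks.volume_conduction_config(101, n_trials=10))


@pytest.fixture(scope="session")
def lagged_dataset():
    """Small lagged-coupling session (directed cortex -> striatum theta)."""
    return simulate_session(benchmarks.lagged_coupling_config(202, n_trials=10))


@pytest.fixture(scope="session")
def battery_config():
    return benchmarks.battery_analysis_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
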