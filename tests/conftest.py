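import numpy as np
import pytest

from nvcouple.nvc_model import GammaParams
from nvcouple.simulator import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim_cfg():
    """Reduced-scale config: 4 pulses, 512 Hz EEG, 2 kernel sets."""
    return SimulationConfig(
        n_pulses=4,
        eeg_fs=512.0,
        gamma_sets=(GammaParams(0.30, 2, 2.0), GammaParams(0.60, 4, 3.0)),
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_cfg):
    return simulate_dataset(small_sim_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale default simulation (8 pulses, 2048 Hz, 5 kernel sets)."""
    return simulate_dataset(SimulationConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
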