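import numpy as np
import pytest

from channelsim.markov import KineticModel, Topology
from channelsim.simulate import SimulationConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state():
    """Symmetric 2-state gate at 100 s^-1 (mean dwell 10 ms)."""
    return KineticModel(Topology("CO"), np.array([100.0, 100.0]))


@pytest.fixture(scope="session")
def slow_clean_recording():
    """Shared high-SNR, slow-gating recording with its ground truth.

    k = 20 s^-1 keeps dwells far above the filter rise time so detectors can
    be held to sample-accurate standards.
    """
    model = KineticModel(Topology("CO"), np.array([20.0, 20.0]))
    config = SimulationConfig(n_samples=400_000, seed=2024, snr=20.0)
    noisy, ideal = simulate_recording(model, config)
    return model, config, noisy, ideal
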