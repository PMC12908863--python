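import numpy as np
import pytest

from wfoi.metrics import StimulusProtocol
from wfoi.phantom import PhantomConfig, simulate_session
from wfoi.spectra import load_default_extinction, load_default_pathlengths


@pytest.fixture(scope="session")
def table():
    return load_default_extinction()


@pytest.fixture(scope="session")
def pathlengths():
    return load_default_pathlengths()


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free, drift-free 64x64 phantom, 60 s at 10 Hz camera rate."""
    cfg = PhantomConfig(
        shape=(64, 64), frame_rate_hz=10.0, duration_s=60.0,
        protocol=StimulusProtocol.regular(10.0, 20.0, 2),
        drift_amplitude=0.0, read_noise_sd=0.0, poisson_noise=False, seed=1)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small phantom with read noise, drift and vignetting."""
    cfg = PhantomConfig(
        shape=(16, 16), frame_rate_hz=20.0, duration_s=110.0,
        protocol=StimulusProtocol.regular(10.0, 20.0, 5),
        drift_amplitude=0.01, read_noise_sd=3.0, seed=11)
    return simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
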