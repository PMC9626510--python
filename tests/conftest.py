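import numpy as np
import pytest

from arp300.preprocess import preprocess_session
from arp300.simulate import SimParams, make_schedule, simulate_session

# Heavy synthetic fixtures are session-scoped and shared across test modules.

HIGH_SNR = dict(noise_pink_uv=1.0, noise_alpha_uv=0.5, noise_white_uv=0.3)


@pytest.fixture(scope="session")
def small_schedule():
    """2 runs x 9 blocks x 5 trials x 9 stimuli = 810 flashes."""
    return make_schedule(2, 9, 5, 9, seed=11)


@pytest.fixture(scope="session")
def highsnr_session(small_schedule):
    return simulate_session(small_schedule, SimParams(**HIGH_SNR), seed=21)


@pytest.fixture(scope="session")
def highsnr_epochs(highsnr_session):
    return preprocess_session(highsnr_session)


@pytest.fixture(scope="session")
def moderate_session(small_schedule):
    """Default noise levels: decodable but not saturated."""
    return simulate_session(small_schedule, SimParams(), seed=22)


@pytest.fixture(scope="session")
def moderate_epochs(moderate_session):
    return preprocess_session(moderate_session)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
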