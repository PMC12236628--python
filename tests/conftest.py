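import numpy as np
import pytest
from hypothesis import settings

from oknpupil.synth import SimConfig, simulate_session

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """The default study conditions: 2 conditions x 4 trials x 120 s at 1000 Hz."""
    return simulate_session(SimConfig(seed=42))


@pytest.fixture()
def small_cfg():
    """A fast trial template for unit tests."""
    return SimConfig(
        duration_s=60.0, n_trials=1, sample_rate_hz=500.0, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
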