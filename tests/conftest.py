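import numpy as np
import pytest
from hypothesis import settings

from farmstyles.config import build_scenario

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_scenario():
    return build_scenario("none", "no")


@pytest.fixture
def params(default_scenario):
    return default_scenario[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def quiet_overrides(**extra):
    """Overrides that switch off every stochastic term, freeze prices and
    remove droughts, for fixed-point and noise-free checks."""
    ov = {
        "yield_noise_halfwidth": 0.0,
        "price_expectation_noise": 0.0,
        "farm_drought_noise_halfwidth": 0.0,
        "base_drought_risk": 0.0,
        "oscillator_amplitude": 0.0,
    }
    ov.update(extra)
    return ov
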