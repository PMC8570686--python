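import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dgep.config import AnalysisConfig
from dgep.synth import EPSimParams

settings.register_profile(
    "default", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def noiseless_params():
    return EPSimParams(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
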