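import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibdrel import make_synthetic_map
from ibdrel.models import ModelParams

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gmap():
    """The default synthetic 22-autosome, 3500 cM map."""
    return make_synthetic_map(seed=1)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
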