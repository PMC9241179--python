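import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import visioncea as v
from visioncea.model_config import Lifetable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def config():
    """Packaged base case (synthetic long-term parameters and lifetable)."""
    return v.fixture_config()


@pytest.fixture
def immortal_lifetable():
    """q(age) = 0 everywhere up to age 200."""
    return Lifetable(np.arange(0, 201), np.zeros(201))


@pytest.fixture
def immortal_config(config, immortal_lifetable):
    config.lifetable = immortal_lifetable
    return config
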