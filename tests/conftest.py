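from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from listexp.pipeline import load_generator_config
from listexp.synthetic_respondents import generate_population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    """The packaged study configuration (n = 809, Table-style calibration)."""
    return load_generator_config()


@pytest.fixture(scope="session")
def default_population(default_config):
    """One seeded draw of the full synthetic survey."""
    return generate_population(default_config, seed=20170501)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
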