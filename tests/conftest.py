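import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from micropkpd import default_pd_population, default_pk_population

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def medium_pk():
    """Population one-compartment parameters of the 60 mg/kg group."""
    return default_pk_population(60.0)


@pytest.fixture
def medium_pd():
    """Population turnover parameters of the 60 mg/kg group."""
    return default_pd_population(60.0)


@pytest.fixture
def hourly_grid():
    return np.arange(0.0, 9.0)
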