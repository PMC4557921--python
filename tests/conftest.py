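import numpy as np
import pytest

from mchtrends.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_config():
    """Reduced geography for fast pipeline tests: 12 states, 4 zones."""
    return SimConfig(n_states=12, n_zones=4)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()
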