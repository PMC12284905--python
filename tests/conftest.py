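import numpy as np
import pytest

from wolbsim.params import ModelParams, beis_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def beis():
    return beis_params()


@pytest.fixture
def small_params():
    """Reduced carrying capacity for fast multi-replicate tests."""
    return ModelParams(K=800, P0=50)
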