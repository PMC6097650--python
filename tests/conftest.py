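import numpy as np
import pytest

from bpa import identity_function, make_variable_model


@pytest.fixture
def identity_f():
    return identity_function()


@pytest.fixture
def half_models():
    """Both variables with an even information/noise split."""
    return make_variable_model(0.5), make_variable_model(0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20180817)
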