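import numpy as np
import pytest

from phasl.synthetic import default_quant_params, make_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(shape=(32, 32, 8), seed=7)


@pytest.fixture(scope="session")
def qparams(phantom):
    return default_quant_params(n_slices=phantom.shape[2])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
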