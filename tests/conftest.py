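import numpy as np
import pytest

from plateau_snn.neuron_core import (FloatBackend, HardwareBackend,
                                     NetworkParams)


@pytest.fixture(scope="session")
def params():
    return NetworkParams()


@pytest.fixture(scope="session")
def float_backend():
    return FloatBackend()


@pytest.fixture(scope="session")
def hw_backend():
    return HardwareBackend(lut_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
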