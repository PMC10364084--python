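import numpy as np
import pytest

from hydromp.dielectric import water_parameters
from hydromp.synth import bsa13


@pytest.fixture(scope="session")
def truth():
    return bsa13()


@pytest.fixture(scope="session")
def water25():
    return water_parameters(25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
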