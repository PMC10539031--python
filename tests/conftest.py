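import numpy as np
import pytest

from cardassim.fk import FiberField, Grid3D, default_parameters


@pytest.fixture
def grid5():
    return Grid3D(5, 5, 5)


@pytest.fixture
def fiber():
    return FiberField()


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
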