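import numpy as np
import pytest

from megaedit import AcqConfig, FieldParams, make_spin_system


@pytest.fixture(scope="session")
def fld():
    return FieldParams()


@pytest.fixture(scope="session")
def acq():
    return AcqConfig()


@pytest.fixture(scope="session")
def gaba():
    return make_spin_system("gaba")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
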