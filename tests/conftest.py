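import numpy as np
import pytest

from mesoglass import BUILTIN_SILICAS, BUILTIN_SUBSTANCES


@pytest.fixture(scope="session")
def celecoxib():
    return BUILTIN_SUBSTANCES["celecoxib"]


@pytest.fixture(scope="session")
def syl350():
    return BUILTIN_SILICAS["SYL350"]


@pytest.fixture(scope="session")
def syl730():
    return BUILTIN_SILICAS["SYL730"]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
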