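import numpy as np
import pytest

from gliocart import REFERENCE_PARAMS, T0_REFERENCE


@pytest.fixture(scope="session")
def params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def T0():
    return T0_REFERENCE


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_states():
    """1000 random (T, C) states spanning the physiological range."""
    r = np.random.default_rng(7)
    T = 10 ** r.uniform(0, 12.3, size=1000)
    C = 10 ** r.uniform(0, 9.5, size=1000)
    return T, C
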