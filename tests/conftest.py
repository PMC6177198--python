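import numpy as np
import pytest

from aspiradyn import (
    AspirationProfile,
    PayoffTable,
    fermi_function,
    make_ring,
)


@pytest.fixture(scope="session")
def fermi():
    return fermi_function()


@pytest.fixture
def fig_table():
    """The running three-player example: a=(3,2,1), b=(4,1,1).

    Its weak-selection criterion value is 1*(3-1) + 2*(2-1) + 1*(1-4) = 1,
    so strategy A is (barely) favored.
    """
    return PayoffTable(a=[3.0, 2.0, 1.0], b=[4.0, 1.0, 1.0])


@pytest.fixture
def ring6():
    return make_ring(6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hetero_profile6(rng):
    return AspirationProfile(e=rng.uniform(-2.0, 4.0, 6), source="uniform(-2,4)")
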