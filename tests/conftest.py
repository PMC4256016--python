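import numpy as np
import pytest

from fimsim import BondParams, FimbriaParams


@pytest.fixture
def params():
    """Shipped default fimbrial parameters."""
    return FimbriaParams()


@pytest.fixture
def small_params():
    """Short fimbria for fast stochastic tests."""
    return FimbriaParams(n_subunits=300)


@pytest.fixture
def bond_params():
    return BondParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
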