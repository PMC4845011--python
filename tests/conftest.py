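import numpy as np
import pytest

from glycopoly.measurements import builtin_bkhs_table1
from glycopoly.parametric_fitting import project_markov


@pytest.fixture(scope="session")
def bkhs():
    return builtin_bkhs_table1()


@pytest.fixture(scope="session")
def rho(bkhs):
    return bkhs.table.rho


def random_balanced_P(rng, rho):
    """A random transition matrix keeping rho stationary (for HC tests)."""
    return project_markov(rng.random((2, 2)), rho).P


def random_profile(rng, rho, n):
    """A random n x 2 composition profile whose rows 2..n average to rho."""
    from glycopoly.parametric_fitting import project_gamma

    raw = rng.random((n, 2))
    return project_gamma(raw, rho).Gamma


@pytest.fixture
def rng():
    return np.random.default_rng(20160426)
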