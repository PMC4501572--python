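import numpy as np
import pytest

from eicircuit import (ARPCAConfig, LCAParams, adaptive_rpca,
                       make_planted, make_standard_fixture,
                       rpca_factorization)


@pytest.fixture(scope="session")
def small_fixture():
    """8×8-patch, 128-element Gabor dictionary and its Gram matrix."""
    return make_standard_fixture("small", seed=0)


@pytest.fixture(scope="session")
def small_dict(small_fixture):
    return small_fixture[0]


@pytest.fixture(scope="session")
def small_gram(small_fixture):
    return small_fixture[1]


@pytest.fixture(scope="session")
def lca_params():
    return LCAParams()


def small_arpca_config(m: int) -> ARPCAConfig:
    """Solver settings scaled to an M-column problem: the classic 1/√M
    column weight with a mass-scale reweighting offset."""
    lam0 = 1.0 / np.sqrt(m)
    return ARPCAConfig(lambda0=lam0, beta=lam0 * 10.0, gamma=10.0,
                       inner_max_iter=3000)


@pytest.fixture(scope="session")
def planted40():
    """Planted 40×40 rank-3 + 3-column model with its ARPCA solution."""
    pm = make_planted(40, 3, 3, magnitude=0.5, seed=7)
    res = adaptive_rpca(pm.g, small_arpca_config(40))
    return pm, res


def small_gabor_arpca_config() -> ARPCAConfig:
    """Reweighting calibration for the 128-element Gabor fixture: the
    1/√M-scale initial weight with a unit-mass reweighting offset."""
    return ARPCAConfig(lambda0=0.088, beta=0.5, gamma=1.0,
                       inner_max_iter=600, seed=0)


@pytest.fixture(scope="session")
def small_rpca(small_gram):
    """ARPCA decomposition + rank-truncated factorization of the small
    Gabor fixture, truncated at 99% of L's eigenvalue mass."""
    res = adaptive_rpca(small_gram, small_gabor_arpca_config())
    sv = np.linalg.svd(res.l, compute_uv=False)
    rank99 = int(np.searchsorted(np.cumsum(sv) / sv.sum(), 0.99) + 1)
    fact = rpca_factorization(res, rank99, column_tol=1e-2)
    return res, fact
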