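import numpy as np
import pytest

import permherit as ph
from permherit.derivative import DerivativeContext


@pytest.fixture(scope="session")
def small_eig():
    """n=40 centered kinship from 300 simulated markers (z = n-1)."""
    Z = ph.simulate_genotypes(ph.SimConfig(n=40, m=300, seed=11))
    return ph.eigendecompose(ph.build_kinship(Z))


@pytest.fixture(scope="session")
def small_ctx(small_eig):
    return DerivativeContext.build(small_eig)


@pytest.fixture(scope="session")
def lowrank_eig():
    """n=30 kinship from only 12 markers: many near-zero eigenvalues."""
    Z = ph.simulate_genotypes(ph.SimConfig(n=30, m=12, seed=13))
    return ph.eigendecompose(ph.build_kinship(Z))


@pytest.fixture(scope="session")
def cis_eig():
    """n=50 kinship from 50 markers: wide spectrum, small p-values reachable."""
    Z = ph.simulate_genotypes(ph.SimConfig(n=50, m=50, seed=1))
    return ph.eigendecompose(ph.build_kinship(Z))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
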