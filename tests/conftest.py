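import numpy as np
import pytest

from hetgwis.synthdata import SimScenario, simulate_cohort, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_null_data():
    """400-subject null cohort with dropout, shared across tests."""
    sc = SimScenario(n_subjects=400, n_snps=40, seed=99, dropout_prob=0.15)
    g = simulate_genotypes(sc)
    ph = simulate_cohort(sc, g)
    return sc, g, ph


@pytest.fixture(scope="session")
def tiny_fixture():
    """20-subject cohort for dense-oracle likelihood comparisons."""
    sc = SimScenario(n_subjects=20, n_snps=5, seed=7, dropout_prob=0.25)
    g = simulate_genotypes(sc)
    ph = simulate_cohort(sc, g)
    return sc, g, ph
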