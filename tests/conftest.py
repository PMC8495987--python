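import numpy as np
import pandas as pd
import pytest

from polyliab.io import GenotypeMatrix, make_variant_table
from polyliab.simdata import SimConfig, simulate_cohort, simulate_population


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    cfg = SimConfig(
        n_cases=80,
        n_matched_controls=80,
        n_pool_controls=200,
        k_clusters=3,
        fst=0.02,
        m_snps=800,
        m_causal=160,
        seed=11,
    )
    geno, subjects, truth = simulate_cohort(cfg)
    return cfg, geno, subjects, truth


@pytest.fixture(scope="session")
def big_population():
    """Large unascertained population for moment checks (no genotype matrix)."""
    cfg = SimConfig(m_snps=600, m_causal=500, seed=5)
    return cfg, simulate_population(cfg, 200_000)


def random_genotypes(rng, n, m, maf_low=0.1, maf_high=0.5):
    """HWE genotypes at uniform random allele frequencies."""
    p = rng.uniform(maf_low, maf_high, size=m)
    dose = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = np.array([f"s{i}" for i in range(n)])
    return GenotypeMatrix(dose, ids, make_variant_table(m))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
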