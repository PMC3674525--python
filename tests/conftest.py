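import numpy as np
import pytest

from lmqc import (
    GenotypeMatrix,
    PhenotypeVector,
    SimulationConfig,
    simulate_replicate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20100854)


@pytest.fixture
def toy_pheno_geno(rng):
    """10-individual quantitative toy with two correlated SNPs."""
    g_i = rng.integers(0, 3, 10)
    g_j = np.clip(g_i + rng.integers(-1, 2, 10), 0, 2)
    y = 0.4 * g_i + 0.2 * g_j + rng.normal(0, 1, 10)
    return PhenotypeVector(y), g_i.astype(np.int8), g_j.astype(np.int8)


def make_matrix(codes, chrom=None, pos=None):
    codes = np.asarray(codes, dtype=np.int8)
    m = codes.shape[1]
    return GenotypeMatrix(
        codes=codes,
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos_bp=np.array(pos if pos is not None else np.arange(1, m + 1) * 1000),
        alleles=np.array([("A", "G")] * m, dtype=object),
    )


@pytest.fixture
def small_config():
    """Desk-size simulation: 300 individuals, 12 SNPs, moderate LD."""
    return SimulationConfig(
        theta=40.0, rho=40.0, n_sites=12, n_individuals=300,
        n_cases=100, n_controls=100, seed=7,
    )


@pytest.fixture(scope="session")
def small_replicate():
    cfg = SimulationConfig(theta=40.0, rho=40.0, n_sites=12, n_individuals=300,
                           n_cases=100, n_controls=100, seed=7)
    return simulate_replicate(cfg)


def hwe_genotypes(rng, n, maf):
    """HWE genotype column at the given minor allele frequency."""
    h = rng.random((n, 2)) < maf
    return h.sum(axis=1).astype(np.int8)
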