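import numpy as np
import pandas as pd
import pytest

from pleionet.datatypes import GenotypeTable, PhenotypeTable
from pleionet.ldsc import GeneticCorrelationMatrix


@pytest.fixture
def toy_genotypes():
    """Six samples, one SNP with dosages 0,0,1,1,2,2."""
    variants = pd.DataFrame(
        {"SNP": ["rs1"], "CHR": ["1"], "BP": [100], "A1": ["A"], "A2": ["G"]}
    )
    samples = np.array([f"S{i}" for i in range(6)], dtype=object)
    dos = np.array([[0, 0, 1, 1, 2, 2]], dtype=float).T
    return GenotypeTable(samples, variants, dos)


def make_genotype_table(dosages, chrom="1"):
    """GenotypeTable from an (n_samples, n_snps) dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(m)],
            "CHR": chrom,
            "BP": np.arange(1, m + 1) * 100,
            "A1": "A",
            "A2": "G",
        }
    )
    samples = np.array([f"S{i + 1}" for i in range(n)], dtype=object)
    return GenotypeTable(samples, variants, dosages)


def make_phenotypes(samples, traits: dict, covariates: dict | None = None):
    n = len(samples)
    cov = pd.DataFrame(covariates or {}, index=range(n))
    return PhenotypeTable(np.asarray(samples, dtype=object), pd.DataFrame(traits), cov)


def block_rg_matrix(block_sizes, within=0.9, noise=0.0, p_within=1e-4, p_between=0.4,
                    seed=0):
    """Planted block-diagonal genetic-correlation matrix with P-values."""
    rng = np.random.default_rng(seed)
    K = sum(block_sizes)
    R = rng.uniform(-noise, noise, (K, K)) if noise else np.zeros((K, K))
    R = (R + R.T) / 2
    start = 0
    truth = np.zeros(K, dtype=int)
    for b, size in enumerate(block_sizes):
        idx = slice(start, start + size)
        R[idx, idx] = within
        truth[idx] = b + 1
        start += size
    np.fill_diagonal(R, 1.0)
    P = np.where(np.abs(R) >= within - 1e-9, p_within, p_between)
    np.fill_diagonal(P, 0.0)
    rg = GeneticCorrelationMatrix(
        traits=[f"t{i}" for i in range(K)],
        rg=R,
        se=np.full((K, K), 0.05),
        p=P,
        valid=np.ones((K, K), dtype=bool),
    )
    return rg, truth
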