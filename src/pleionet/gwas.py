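"""SNP quality control, additive-model association scans, and genomic control.

The association model is ordinary least squares of a quantitative trait on the
A1 dosage plus covariates plus an intercept, with casewise deletion of samples
whose dosage is missing (mean imputation is deliberately not offered — it
would overstate the effective n). The Wald statistic T = beta/SE is referred
to the standard normal by default (large-n regime); a Student-t reference is
available via ``t_reference='t'``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeTable, PhenotypeTable, SummaryStats

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df, to 5 decimals
CHI2_1_MEDIAN = 0.45494


@dataclass
class QCConfig:
    """Per-SNP filter thresholds; ties at a threshold are inclusive (>=)."""

    min_call_rate: float = 0.98
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_rsq: Optional[float] = None  # pass-through filter on an RSQ column, off by default

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_rsq is not None and not (0.0 <= self.min_rsq <= 1.0):
            raise ValueError("min_rsq must lie in [0, 1]")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit P (1-df chi-square, upper tail)."""
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = terms.sum()
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(genotypes: GenotypeTable, config: Optional[QCConfig] = None):
    """Apply call-rate, MAF and HWE filters.

    Returns the surviving :class:`GenotypeTable` and a report naming every
    excluded SNP with its first failing rule (rules checked in the order
    call_rate, maf, hwe). MAF and HWE are computed on the non-missing samples.
    """
    if genotypes.n_snps == 0:
        raise ValueError("genotype table is empty")
    config = config or QCConfig()
    config.validate()
    dos = genotypes.dosages
    n = genotypes.n_samples
    obs = ~np.isnan(dos)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / n
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dos, axis=0) / np.maximum(2 * n_obs, 1)
    maf = np.minimum(freq, 1 - freq)
    hwe_p = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        col = dos[obs[:, j], j]
        if col.size == 0:
            hwe_p[j] = 0.0
            continue
        hwe_p[j] = hwe_test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))

    keep = np.ones(genotypes.n_snps, dtype=bool)
    rows = []
    for j in range(genotypes.n_snps):
        snp = genotypes.snp_ids[j]
        if call_rate[j] < config.min_call_rate:
            rows.append((snp, "call_rate", call_rate[j], config.min_call_rate))
        elif maf[j] < config.min_maf:
            rows.append((snp, "maf", maf[j], config.min_maf))
        elif hwe_p[j] < config.min_hwe_p:
            rows.append((snp, "hwe", hwe_p[j], config.min_hwe_p))
        else:
            continue
        keep[j] = False
    report = pd.DataFrame(rows, columns=["SNP", "rule", "value", "threshold"])
    if not keep.any():
        logger.warning("QC removed every SNP")
    return genotypes.subset_snps(keep), report


def gwas_scan(
    genotypes: GenotypeTable,
    phenotypes: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] = (),
    trait_id: Optional[str] = None,
    sample_subset: Optional[np.ndarray] = None,
    t_reference: str = "normal",
) -> SummaryStats:
    """Per-SNP OLS association scan for one trait.

    Uses precomputed cross-products with per-SNP corrections for samples whose
    dosage is missing, so casewise deletion costs O(missing) instead of a full
    refit. SNPs with zero post-deletion dosage variance, or a perfect fit
    (zero residual variance), are emitted with ``OK=False`` and NaN statistics.
    """
    y_all = phenotypes.traits[trait].to_numpy(dtype=float)
    C_all = phenotypes.covariates[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(y_all), 0))
    dos_all = genotypes.dosages

    if sample_subset is not None:
        idx = pd.Index(phenotypes.samples).get_indexer(list(sample_subset))
        if (idx < 0).any():
            raise ValueError("sample_subset contains unknown sample ids")
        y_all, C_all, dos_all = y_all[idx], C_all[idx], dos_all[idx]

    ok_rows = ~np.isnan(y_all)
    if C_all.shape[1]:
        ok_rows &= ~np.isnan(C_all).any(axis=1)
    y = y_all[ok_rows]
    C = C_all[ok_rows]
    X = dos_all[ok_rows]
    n, m = X.shape
    p = C.shape[1] + 1  # covariates + intercept
    if n <= p + 1:
        raise ValueError("too few complete samples for the requested model")

    # center covariates for conditioning; leaves the dosage coefficient unchanged
    Q = np.column_stack([np.ones(n), C - C.mean(axis=0)]) if p > 1 else np.ones((n, 1))

    miss = np.isnan(X)
    X0 = np.where(miss, 0.0, X)

    QtQ = Q.T @ Q
    Qty = Q.T @ y
    yty = float(y @ y)
    QtX = Q.T @ X0                      # (p, m): exact since missing entries are 0
    xty = X0.T @ y                      # (m,)
    xtx = (X0 * X0).sum(axis=0)         # (m,)
    n_j = n - miss.sum(axis=0)

    # batched normal equations; missing-dosage samples enter as sparse
    # rank-one corrections to the covariate blocks
    A11 = np.broadcast_to(QtQ, (m, p, p)).copy()
    b1 = np.broadcast_to(Qty, (m, p)).copy()
    yty_j = np.full(m, yty)
    rows, cols = np.nonzero(miss)
    if rows.size:
        Qr = Q[rows]
        np.subtract.at(A11, cols, Qr[:, :, None] * Qr[:, None, :])
        np.subtract.at(b1, cols, Qr * y[rows, None])
        np.subtract.at(yty_j, cols, y[rows] ** 2)
    A = np.empty((m, p + 1, p + 1))
    A[:, :p, :p] = A11
    A[:, :p, p] = QtX.T
    A[:, p, :p] = QtX.T
    A[:, p, p] = xtx
    b = np.empty((m, p + 1))
    b[:, :p] = b1
    b[:, p] = xty

    se = np.full(m, np.nan)
    ok = np.ones(m, dtype=bool)
    flags = np.array([""] * m, dtype=object)

    df = n_j - (p + 1)
    bad_n = df <= 0
    ok[bad_n] = False
    flags[bad_n] = "insufficient_n"

    rhs = np.concatenate(
        [b[:, :, None],
         np.broadcast_to(np.eye(p + 1)[:, p][None, :, None], (m, p + 1, 1))],
        axis=2,
    )
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        sol = np.full((m, p + 1, 2), np.nan)
        for j in range(m):
            try:
                sol[j] = np.linalg.solve(A[j], rhs[j])
            except np.linalg.LinAlgError:
                pass  # flagged as zero dosage variance below

    coef = sol[:, :, 0]
    ainv_last = sol[:, p, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_resid = np.where(ainv_last > 0, 1.0 / ainv_last, 0.0)
    degenerate_x = ~np.isfinite(sxx_resid) | (sxx_resid < 1e-10 * np.maximum(n_j, 1))
    newly = degenerate_x & ok
    ok[newly] = False
    flags[newly] = "zero_dosage_variance"

    rss = yty_j - np.einsum("ij,ij->i", coef, b)
    beta = np.where(degenerate_x | bad_n, np.nan, coef[:, p])
    perfect = ok & (rss <= np.maximum(1e-12 * yty_j, 0.0))
    ok[perfect] = False
    flags[perfect] = "degenerate_perfect_fit"
    se[perfect] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df
    se[ok] = np.sqrt(sigma2[ok] * ainv_last[ok])

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    if t_reference == "t":
        pval = 2 * stats.t.sf(np.abs(tstat), df=np.maximum(n_j - (p + 1), 1))
    else:
        pval = 2 * stats.norm.sf(np.abs(tstat))

    v = genotypes.variants
    table = pd.DataFrame(
        {
            "SNP": v["SNP"].to_numpy(),
            "CHR": v["CHR"].to_numpy(),
            "BP": v["BP"].to_numpy(),
            "A1": v["A1"].to_numpy(),
            "A2": v["A2"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "Z": tstat,
            "P": pval,
            "N": n_j,
            "OK": ok,
            "FLAG": flags,
        }
    )
    return SummaryStats(trait_id=trait_id or trait, table=table)


def genomic_control_lambda(stats_in: SummaryStats) -> float:
    """Genomic inflation factor: median observed T^2 over the chi2(1) median."""
    t = stats_in.valid["Z"].to_numpy(dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no valid statistics for genomic control")
    if t.size < 100:
        warnings.warn("fewer than 100 SNPs: lambda_GC is unstable", stacklevel=2)
    return float(np.median(t * t) / CHI2_1_MEDIAN)
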