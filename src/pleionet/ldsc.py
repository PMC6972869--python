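"""Simplified LD score regression: heritability and genetic correlation.

Two regimes, chosen automatically from the LD scores:

* varying l_j — regression of chi2 (or the cross-trait Z product) on l with a
  free intercept absorbing sample overlap. The fit is weighted least squares
  with LD-score weights (1/l times the inverse squared predicted mean,
  iterated twice from a 1/l^2 start): unweighted OLS is dominated by the
  heteroskedastic high-LD SNPs and is far too noisy at desk-scale SNP counts.
* constant l_j (independent SNPs) — the slope is unidentifiable with a free
  intercept, so the intercept is pinned: at its theoretical null value 1 for
  the single-trait regression, and for a trait pair at the null correlation of
  the two Z-vectors recovered from SNPs with both |Z| below a cutoff, inverted
  through the exact truncated bivariate-normal product moment (plain truncated
  means are attenuated by roughly a quarter at a 1.96 cutoff and would bias
  the slope badly).

Standard errors come from a delete-a-block jackknife over contiguous SNP
blocks in both regimes. This estimator is deliberately simple and documented
as not a replacement for the published LDSC software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import bvn_corr_from_truncated_product
from .datatypes import LDScoreTrack, SummaryStats

DEFAULT_BLOCKS = 200
MIN_SNPS = 200
DEFAULT_NULL_Z = 1.96
_CONST_L_TOL = 1e-12


@dataclass
class HeritabilityEstimate:
    trait_id: str
    h2: float
    se: float
    intercept: float
    slope: float = 0.0
    mean_n: float = 0.0

    @property
    def flagged_nonpositive(self) -> bool:
        return not (self.h2 > 0)


@dataclass
class RgEstimate:
    rg: float
    se: float
    p: float
    valid: bool
    rho_g: float
    n_snps: int
    n_allele_mismatch: int


@dataclass
class GeneticCorrelationMatrix:
    """Symmetric r_g matrix with per-pair SE, P and validity flags.

    Invalid pairs (estimation failed, non-positive h2, or |r_g| outside
    [-1, 1]) carry NaN and valid=False; the diagonal is exactly 1.
    """

    traits: list
    rg: np.ndarray
    se: np.ndarray
    p: np.ndarray
    valid: np.ndarray

    @property
    def n_invalid(self) -> int:
        iu = np.triu_indices(len(self.traits), k=1)
        return int((~self.valid[iu]).sum())


# -- weighted regression with block jackknife ---------------------------------

def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _n_blocks_for(m: int, requested: int) -> int:
    if m < 400:
        return max(m // 2, 2)
    return min(requested, m // 2)


def _wls(y, x, w) -> Tuple[float, float]:
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxy = (w * x * y).sum()
    sxx = (w * x * x).sum()
    denom = sxx - sx * sx / sw
    slope = (sxy - sx * sy / sw) / denom
    return float(slope), float((sy - slope * sx) / sw)


def _free_intercept_fit(
    y: np.ndarray, l: np.ndarray, weight_fn, n_blocks: int, n_iter: int = 2
) -> Tuple[float, float, np.ndarray]:
    """Iterated WLS of y on l; jackknife slopes use the final weights."""
    w = 1.0 / l**2
    slope, intercept = _wls(y, l, w)
    for _ in range(n_iter):
        w = weight_fn(slope, intercept)
        slope, intercept = _wls(y, l, w)
    m = len(y)
    bounds = _block_bounds(m, n_blocks)
    cols = np.column_stack([w, w * l, w * y, w * l * y, w * l * l])
    block_sums = np.add.reduceat(cols, bounds[:-1], axis=0)
    total = block_sums.sum(axis=0)

    def slope_from(s):
        sw, sx, sy, sxy, sxx = s
        denom = sxx - sx * sx / sw
        return (sxy - sx * sy / sw) / denom

    jack = np.array([slope_from(total - block_sums[b]) for b in range(n_blocks)])
    return slope, intercept, jack


def _pinned_fit(
    y: np.ndarray,
    l: np.ndarray,
    n_blocks: int,
    pin: Optional[float] = None,
    null_mask: Optional[np.ndarray] = None,
    cutoff: float = DEFAULT_NULL_Z,
) -> Tuple[float, float, np.ndarray]:
    """Moment fit for constant LD scores: slope = (mean y - intercept)/mean l.

    ``pin`` fixes the intercept outright; otherwise it is recovered from the
    truncated product moment over ``null_mask``.
    """
    m = len(y)
    bounds = _block_bounds(m, n_blocks)
    if null_mask is None:
        null_mask = np.zeros(m, dtype=bool)
    cols = np.column_stack([np.ones(m), y, l, null_mask, np.where(null_mask, y, 0.0)])
    block_sums = np.add.reduceat(cols, bounds[:-1], axis=0)
    total = block_sums.sum(axis=0)

    def fit_from(s):
        n, sy, sl, n_null, sy_null = s
        if pin is not None:
            intercept = pin
        else:
            if n_null <= 0:
                raise ValueError("no null SNPs below the |Z| cutoff")
            intercept = bvn_corr_from_truncated_product(sy_null / n_null, cutoff)
        return (sy / n - intercept) / (sl / n), intercept

    slope, intercept = fit_from(total)
    jack = np.array([fit_from(total - block_sums[b])[0] for b in range(n_blocks)])
    return slope, intercept, jack


def _jackknife_se(jack: np.ndarray) -> float:
    B = len(jack)
    se = np.sqrt((B - 1) / B * ((jack - jack.mean()) ** 2).sum())
    return float(max(se, np.finfo(float).tiny))


def _h2_weight_fn(l: np.ndarray):
    def fn(slope, intercept):
        line = np.maximum(intercept, 0.9) + np.maximum(slope, 0.0) * l
        return 1.0 / (l * line * line)

    return fn


# -- public estimators --------------------------------------------------------

def estimate_h2(
    stats_in: SummaryStats, ld: LDScoreTrack, n_blocks: int = DEFAULT_BLOCKS
) -> HeritabilityEstimate:
    """Single-trait LD score regression: chi2_j on l_j.

    h2 = slope * M / mean(N); SE by delete-a-block jackknife. With constant
    LD scores the intercept is pinned at its null value 1. Estimates may be
    <= 0 — flagged downstream, never clipped.
    """
    tab = stats_in.valid
    if len(tab) < MIN_SNPS:
        raise ValueError(f"need at least {MIN_SNPS} SNPs, got {len(tab)}")
    z = tab["Z"].to_numpy(dtype=float)
    l = ld.for_snps(tab["SNP"])
    nbar = float(tab["N"].mean())
    B = _n_blocks_for(len(tab), n_blocks)
    chi2 = z * z
    if np.var(l) < _CONST_L_TOL:
        slope, intercept, jack = _pinned_fit(chi2, l, B, pin=1.0)
    else:
        slope, intercept, jack = _free_intercept_fit(chi2, l, _h2_weight_fn(l), B)
    scale = ld.M / nbar
    return HeritabilityEstimate(
        trait_id=stats_in.trait_id,
        h2=slope * scale,
        se=_jackknife_se(jack * scale),
        intercept=intercept,
        slope=slope,
        mean_n=nbar,
    )


def align_pair(s1: SummaryStats, s2: SummaryStats) -> Tuple[pd.DataFrame, int]:
    """Intersect two summary tables by SNP id with allele alignment.

    Z of the second trait is sign-flipped when A1/A2 are swapped relative to
    the first; pairs whose alleles match neither orientation are dropped and
    counted.
    """
    a = s1.valid
    b = s2.valid
    merged = a.merge(b, on="SNP", suffixes=("_1", "_2"))
    same = (merged["A1_1"] == merged["A1_2"]) & (merged["A2_1"] == merged["A2_2"])
    flipped = (merged["A1_1"] == merged["A2_2"]) & (merged["A2_1"] == merged["A1_2"])
    n_mismatch = int((~(same | flipped)).sum())
    merged = merged[same | flipped].copy()
    sign = np.where(merged["A1_1"] == merged["A1_2"], 1.0, -1.0)
    merged["Z_2"] = merged["Z_2"] * sign
    merged["BETA_2"] = merged["BETA_2"] * sign
    return merged, n_mismatch


def estimate_rg_pair(
    s1: SummaryStats,
    s2: SummaryStats,
    ld: LDScoreTrack,
    n_blocks: int = DEFAULT_BLOCKS,
    h2_1: Optional[HeritabilityEstimate] = None,
    h2_2: Optional[HeritabilityEstimate] = None,
    null_z_cutoff: float = DEFAULT_NULL_Z,
) -> RgEstimate:
    """Cross-trait LD score regression for one trait pair.

    Regression of z1*z2 on l with an intercept absorbing sample overlap
    (free when l varies, pinned to the de-attenuated null-SNP product moment
    when l is constant); rho_g = slope * M / sqrt(mean N1 * mean N2);
    r_g = rho_g / sqrt(h2_1 * h2_2). If either heritability estimate is
    non-positive the result is the NaN sentinel with valid=False. SE and P of
    r_g by block jackknife, holding the h2 denominators at their full-sample
    values.
    """
    merged, n_mismatch = align_pair(s1, s2)
    if len(merged) < MIN_SNPS:
        if n_mismatch and len(merged) == 0:
            raise ValueError("all alleles mismatched between the two inputs")
        raise ValueError(f"need at least {MIN_SNPS} intersecting SNPs, got {len(merged)}")
    h2_1 = h2_1 or estimate_h2(s1, ld, n_blocks)
    h2_2 = h2_2 or estimate_h2(s2, ld, n_blocks)

    z1 = merged["Z_1"].to_numpy(dtype=float)
    z2 = merged["Z_2"].to_numpy(dtype=float)
    l = ld.for_snps(merged["SNP"])
    n1 = float(merged["N_1"].mean())
    n2 = float(merged["N_2"].mean())
    scale = ld.M / np.sqrt(n1 * n2)
    B = _n_blocks_for(len(merged), n_blocks)
    y = z1 * z2
    if np.var(l) < _CONST_L_TOL:
        null_mask = (np.abs(z1) < null_z_cutoff) & (np.abs(z2) < null_z_cutoff)
        slope, _intercept, jack = _pinned_fit(
            y, l, B, pin=None, null_mask=null_mask, cutoff=null_z_cutoff
        )
    else:
        a1 = np.maximum(h2_1.intercept, 0.9) + max(h2_1.slope, 0.0) * l
        a2 = np.maximum(h2_2.intercept, 0.9) + max(h2_2.slope, 0.0) * l

        def weight_fn(slope, intercept):
            line = intercept + slope * l
            return 1.0 / (l * (a1 * a2 + line * line))

        slope, _intercept, jack = _free_intercept_fit(y, l, weight_fn, B)
    rho_g = slope * scale

    if not (h2_1.h2 > 0 and h2_2.h2 > 0):
        return RgEstimate(np.nan, np.nan, np.nan, False, rho_g, len(merged), n_mismatch)

    denom = np.sqrt(h2_1.h2 * h2_2.h2)
    rg = rho_g / denom
    se = _jackknife_se(jack * scale / denom)
    p = float(2 * stats.norm.sf(abs(rg) / se))
    return RgEstimate(float(rg), se, p, True, float(rho_g), len(merged), n_mismatch)


def build_rg_matrix(
    stats_list: Sequence[SummaryStats],
    ld: LDScoreTrack,
    n_blocks: int = DEFAULT_BLOCKS,
) -> GeneticCorrelationMatrix:
    """All-pairs genetic correlations with the NA/out-of-range filter.

    A pair is marked invalid when its estimate is NaN, above 1 or below -1,
    or when per-pair estimation fails — reproducing the removal of incorrectly
    estimated pairs before network construction.
    """
    if len(stats_list) < 3:
        raise ValueError("need at least 3 traits")
    K = len(stats_list)
    traits = [s.trait_id for s in stats_list]
    h2s: List[Optional[HeritabilityEstimate]] = []
    for s in stats_list:
        try:
            h2s.append(estimate_h2(s, ld, n_blocks))
        except ValueError:
            h2s.append(None)
    rg = np.eye(K)
    se = np.zeros((K, K))
    p = np.zeros((K, K))
    valid = np.eye(K, dtype=bool)
    for i in range(K):
        for j in range(i + 1, K):
            est = None
            if h2s[i] is not None and h2s[j] is not None:
                try:
                    est = estimate_rg_pair(
                        stats_list[i], stats_list[j], ld, n_blocks, h2s[i], h2s[j]
                    )
                except ValueError:
                    est = None
            if est is None or not est.valid or not np.isfinite(est.rg) or abs(est.rg) > 1:
                rg[i, j] = rg[j, i] = np.nan
                se[i, j] = se[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rg[i, j] = rg[j, i] = est.rg
            se[i, j] = se[j, i] = est.se
            p[i, j] = p[j, i] = est.p
            valid[i, j] = valid[j, i] = True
    return GeneticCorrelationMatrix(traits=traits, rg=rg, se=se, p=p, valid=valid)


class GeneticCorrelationLDSC(BaseEstimator):
    """Estimator wrapper: fit on a list of summary-stat tables plus LD scores.

    Fitted attributes: ``rg_matrix_`` (:class:`GeneticCorrelationMatrix`),
    ``h2_`` (per-trait estimates, None where estimation was refused),
    ``n_invalid_``.
    """

    def __init__(self, n_blocks: int = DEFAULT_BLOCKS):
        self.n_blocks = n_blocks

    def fit(self, stats_list: Sequence[SummaryStats], ld: LDScoreTrack):
        self.rg_matrix_ = build_rg_matrix(stats_list, ld, self.n_blocks)
        self.h2_: List[Optional[HeritabilityEstimate]] = []
        for s in stats_list:
            try:
                self.h2_.append(estimate_h2(s, ld, self.n_blocks))
            except ValueError:
                self.h2_.append(None)
        self.n_invalid_ = self.rg_matrix_.n_invalid
        return self
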