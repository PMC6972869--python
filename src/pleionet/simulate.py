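"""Seeded synthetic cohorts with known ground truth.

The generator emulates a single imaging-genetics cohort: one set of subjects
measured on K correlated quantitative traits (all traits on overlapping
samples, which induces correlated test statistics), genotyped at m mostly
independent SNPs. Ground truth (per-trait heritability, pairwise genetic
correlation targets, causal sets, planted multi-trait signal SNPs) is recorded
in a :class:`SimulationTruth` so every downstream estimator can be scored
against what was planted.

SNPs are independent by default; the block-LD mode draws haplotypes from
equicorrelated latent Gaussians per block, giving heterogeneous LD scores —
the regime LD score regression actually needs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datatypes import GenotypeTable, LDScoreTrack, PhenotypeTable

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ["AGE", "SEX", "EDU", "HAND", "PC1", "PC2", "PC3"]


@dataclass
class LDBlocks:
    """Block-equicorrelated haplotype structure for the LD genotype mode."""

    block_size: int = 25
    rho_range: Tuple[float, float] = (0.1, 0.9)


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    ld: Optional[LDBlocks] = None,
    chrom: str = "1",
    bp_step: int = 1000,
) -> GenotypeTable:
    """Draw an additive-dosage genotype table.

    Each SNP gets its own MAF uniform in ``maf_range``; without ``ld`` the
    genotypes are Binomial(2, MAF) independently per sample, with ``ld`` the
    two haplotypes per subject come from block-equicorrelated latent
    Gaussians thresholded at the MAF quantile. Missing calls are applied
    uniformly at random. Deterministic given ``seed``.
    """
    if n_samples <= 0 or n_snps <= 0:
        raise ValueError("n_samples and n_snps must be positive")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not (0.0 <= missing_rate <= 0.2):
        raise ValueError("missing_rate must lie in [0, 0.2]")

    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)

    if ld is None:
        dos = rng.binomial(2, maf[None, :], size=(n_samples, n_snps)).astype(float)
    else:
        dos = np.zeros((n_samples, n_snps))
        thresh = stats.norm.ppf(maf)
        start = 0
        while start < n_snps:
            stop = min(start + ld.block_size, n_snps)
            rho = rng.uniform(*ld.rho_range)
            for _hap in range(2):
                shared = rng.standard_normal(n_samples)[:, None]
                own = rng.standard_normal((n_samples, stop - start))
                z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
                dos[:, start:stop] += (z < thresh[None, start:stop])
            start = stop

    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan

    alleles = np.array(["A", "C", "G", "T"])
    a_idx = rng.integers(0, 4, size=n_snps)
    b_idx = (a_idx + rng.integers(1, 4, size=n_snps)) % 4
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "CHR": chrom,
            "BP": np.arange(1, n_snps + 1) * bp_step,
            "A1": alleles[a_idx],
            "A2": alleles[b_idx],
        }
    )
    samples = np.array([f"S{i + 1:05d}" for i in range(n_samples)], dtype=object)
    return GenotypeTable(samples, variants, dos)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort.

    h2: per-trait heritability targets in [0, 1].
    rho_g: K x K genetic-correlation target matrix (PSD, unit diagonal).
    causal_snps: per-trait lists of causal SNP ids; traits only share genetic
        covariance at SNPs causal for both.
    env_corr: residual (environmental) correlation applied between every trait
        pair; with h2 = 0 this is the full phenotypic correlation.
    fixed_effects: planted signal SNPs — id -> length-K vector of effects on
        the standardized-dosage scale, added on top of the polygenic part.
    covariate_effects: optional per-covariate length-K effect vectors.
    """

    h2: np.ndarray
    rho_g: np.ndarray
    causal_snps: List[np.ndarray]
    env_corr: float = 0.0
    fixed_effects: Dict[str, np.ndarray] = field(default_factory=dict)
    covariate_effects: Dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.h2 = np.asarray(self.h2, dtype=float)
        self.rho_g = np.asarray(self.rho_g, dtype=float)
        self.causal_snps = [np.asarray(c, dtype=object) for c in self.causal_snps]

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    def validate(self) -> None:
        K = self.n_traits
        if self.rho_g.shape != (K, K):
            raise ValueError("rho_g must be K x K")
        if np.any(self.h2 < 0) or np.any(self.h2 > 1):
            raise ValueError("h2 targets must lie in [0, 1]")
        if np.any(np.abs(self.rho_g) > 1 + 1e-12):
            raise ValueError("|rho_g| must not exceed 1")
        if not np.allclose(self.rho_g, self.rho_g.T):
            raise ValueError("rho_g must be symmetric")
        if np.linalg.eigvalsh((self.rho_g + self.rho_g.T) / 2).min() < -1e-8:
            raise ValueError("rho_g target matrix must be positive semi-definite")
        if len(self.causal_snps) != K:
            raise ValueError("one causal set per trait required")
        if not (-1.0 <= float(self.env_corr) <= 1.0):
            raise ValueError("env_corr must lie in [-1, 1]")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "h2": [float(x) for x in self.h2],
            "rho_g": [[float(x) for x in row] for row in self.rho_g],
            "causal_snps": [[str(s) for s in c] for c in self.causal_snps],
            "env_corr": float(self.env_corr),
            "fixed_effects": {str(k): [float(x) for x in v] for k, v in self.fixed_effects.items()},
            "covariate_effects": {str(k): [float(x) for x in v] for k, v in self.covariate_effects.items()},
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            h2=np.asarray(doc["h2"], dtype=float),
            rho_g=np.asarray(doc["rho_g"], dtype=float),
            causal_snps=[np.asarray(c, dtype=object) for c in doc["causal_snps"]],
            env_corr=float(doc.get("env_corr", 0.0)),
            fixed_effects={k: np.asarray(v, dtype=float) for k, v in doc.get("fixed_effects", {}).items()},
            covariate_effects={k: np.asarray(v, dtype=float) for k, v in doc.get("covariate_effects", {}).items()},
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def make(
        cls,
        genotypes: GenotypeTable,
        h2,
        rho_g,
        n_causal: Optional[int] = None,
        mode: str = "shared",
        env_corr: float = 0.0,
        seed: int = 0,
        fixed_effects: Optional[Dict[str, np.ndarray]] = None,
    ) -> "SimulationTruth":
        """Convenience factory: pick causal sets from a genotype table.

        ``mode='shared'`` gives every trait the same causal set (genetic
        correlations realized per rho_g); ``mode='disjoint'`` gives each trait
        its own non-overlapping set (realized genetic correlation 0 whatever
        the targets). ``n_causal=None`` means all SNPs (infinitesimal model).
        """
        h2 = np.atleast_1d(np.asarray(h2, dtype=float))
        K = len(h2)
        rho_g = np.asarray(rho_g, dtype=float)
        if rho_g.ndim == 0:
            rho_g = np.full((K, K), float(rho_g))
            np.fill_diagonal(rho_g, 1.0)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0A]))
        ids = genotypes.snp_ids
        m = len(ids)
        if n_causal is None:
            n_causal = m
        if mode == "shared":
            chosen = rng.choice(m, size=n_causal, replace=False)
            causal = [ids[np.sort(chosen)] for _ in range(K)]
        elif mode == "disjoint":
            if n_causal * K > m:
                raise ValueError("not enough SNPs for disjoint causal sets")
            perm = rng.permutation(m)
            causal = [ids[np.sort(perm[k * n_causal : (k + 1) * n_causal])] for k in range(K)]
        else:
            raise ValueError("mode must be 'shared' or 'disjoint'")
        return cls(
            h2=h2,
            rho_g=rho_g,
            causal_snps=causal,
            env_corr=env_corr,
            fixed_effects=dict(fixed_effects or {}),
            seed=int(seed),
        )


def _standardize_dosages(dos: np.ndarray) -> np.ndarray:
    """Center/scale dosages; missing entries become 0 (= the mean).

    Used only inside the generative model and LD scoring — file readers never
    impute.
    """
    mean = np.nanmean(dos, axis=0)
    sd = np.nanstd(dos, axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    x = (dos - mean) / sd
    return np.nan_to_num(x, nan=0.0)


def _psd_factor(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def make_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Imaging-cohort covariate slots: age, sex, education, handedness, 3 PCs.

    The PC columns are independent Gaussians — they exercise the covariate
    machinery, not stratification correction.
    """
    return pd.DataFrame(
        {
            "AGE": rng.normal(75.0, 6.0, n),
            "SEX": rng.binomial(1, 0.45, n).astype(float),
            "EDU": rng.normal(16.0, 2.8, n),
            "HAND": rng.binomial(1, 0.9, n).astype(float),
            "PC1": rng.standard_normal(n),
            "PC2": rng.standard_normal(n),
            "PC3": rng.standard_normal(n),
        }
    )


def simulate_phenotypes(genotypes: GenotypeTable, truth: SimulationTruth) -> PhenotypeTable:
    """Generate K correlated traits on the cohort per the recorded truth.

    Trait k = sum of causal effects x standardized dosages + planted fixed
    effects + covariate effects + correlated Gaussian noise; effect vectors
    across traits are drawn so the expected genetic covariance matches the
    rho_g targets; every trait is standardized to unit realized variance
    (ROI-volume units are not emulated), with the stored genetic values scaled
    identically so variance fractions stay interpretable.
    """
    truth.validate()
    K = truth.n_traits
    n = genotypes.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 0xFE0]))

    snp_index = pd.Index(genotypes.snp_ids)
    for k, cset in enumerate(truth.causal_snps):
        if len(cset) and not snp_index.isin(cset).sum() == len(cset):
            raise ValueError(f"trait {k}: causal SNPs missing from genotype table")

    D = np.sqrt(truth.h2)
    sigma_g = np.outer(D, D) * truth.rho_g

    union = sorted(set().union(*[set(c.tolist()) for c in truth.causal_snps])) if K else []
    union_pos = snp_index.get_indexer(union)
    counts = np.array([max(len(c), 1) for c in truth.causal_snps], dtype=float)
    scale = 1.0 / np.sqrt(counts)
    per_snp_cov = sigma_g * np.outer(scale, scale)
    L = _psd_factor(per_snp_cov)

    U = rng.standard_normal((len(union), L.shape[1])) @ L.T  # (n_union, K)
    # zero effects for traits a SNP is not causal for
    member = np.zeros((len(union), K), dtype=bool)
    upos = {s: i for i, s in enumerate(union)}
    for k, cset in enumerate(truth.causal_snps):
        for s in cset:
            member[upos[s], k] = True
    U = np.where(member, U, 0.0)

    Xstd_all = _standardize_dosages(genotypes.dosages)
    G = Xstd_all[:, union_pos] @ U if len(union) else np.zeros((n, K))

    for snp, eff in truth.fixed_effects.items():
        j = snp_index.get_loc(snp)
        G = G + np.outer(Xstd_all[:, j], np.asarray(eff, dtype=float))

    Dv = np.sqrt(np.clip(1.0 - truth.h2, 0.0, 1.0))
    rho_e = np.full((K, K), float(truth.env_corr))
    np.fill_diagonal(rho_e, 1.0)
    sigma_e = np.outer(Dv, Dv) * rho_e
    E = rng.standard_normal((n, K)) @ _psd_factor(sigma_e).T

    covars = make_covariates(n, rng)
    Y = G + E
    for name, eff in truth.covariate_effects.items():
        c = covars[name].to_numpy()
        c = (c - c.mean()) / (c.std() or 1.0)
        Y = Y + np.outer(c, np.asarray(eff, dtype=float))

    sd = Y.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant trait generated; check truth parameters")
    mu = Y.mean(axis=0)
    Y = (Y - mu) / sd
    Gs = G / sd

    trait_names = [f"T{k + 1}" for k in range(K)]
    return PhenotypeTable(
        samples=genotypes.samples,
        traits=pd.DataFrame(Y, columns=trait_names),
        covariates=covars,
        genetic_values=pd.DataFrame(Gs, columns=trait_names),
    )


def make_ld_scores(genotypes: GenotypeTable, window_snps: int) -> LDScoreTrack:
    """LD scores l_j = 1 + sum of squared dosage correlations within a window.

    The window is in SNP index units and never crosses a chromosome boundary;
    window 0 gives l_j = 1 for every SNP. Zero-variance SNPs contribute 0 to
    their neighbours (with a logged warning) and score l = 1 themselves.
    """
    if window_snps < 0:
        raise ValueError("window_snps must be >= 0")
    m = genotypes.n_snps
    n = genotypes.n_samples
    scores = np.ones(m)
    if window_snps > 0 and m > 1:
        sd = np.nanstd(genotypes.dosages, axis=0, ddof=0)
        zero_var = sd == 0
        if zero_var.any():
            logger.warning("%d zero-variance SNP(s) contribute 0 to LD scores", int(zero_var.sum()))
            warnings.warn("zero-variance SNP(s) contribute 0 to LD scores", stacklevel=2)
        X = _standardize_dosages(genotypes.dosages)
        X[:, zero_var] = 0.0
        chroms = genotypes.variants["CHR"].to_numpy()
        for d in range(1, window_snps + 1):
            if d >= m:
                break
            r = (X[:, :-d] * X[:, d:]).sum(axis=0) / n
            r2 = r * r
            same_chr = chroms[:-d] == chroms[d:]
            r2 = np.where(same_chr, r2, 0.0)
            scores[:-d] += r2
            scores[d:] += r2
    return LDScoreTrack(genotypes.snp_ids, scores, M=m)
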