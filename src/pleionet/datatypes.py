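"""Core data containers shared across the pipeline.

Conventions: genotype dosages count copies of the effect allele A1 and live in
{0, 1, 2, NaN} (NaN = missing, never silently imputed by readers); genomic
coordinates are 1-based and strictly increasing within a chromosome, matching
PLINK-style summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: columns every summary-statistics table must carry
SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "Z", "P", "N"]


@dataclass
class GenotypeTable:
    """Sample x SNP additive dosage table with variant metadata.

    ``variants`` has columns SNP, CHR, BP, A1, A2 (one row per SNP, aligned
    with the columns of ``dosages``). ``dosages`` is float (n_samples, n_snps)
    with NaN marking missing calls.
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples x variants")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.variants["SNP"].to_numpy()

    def validate(self) -> None:
        v = self.variants
        if v["SNP"].duplicated().any():
            dup = v.loc[v["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup}")
        for _, grp in v.groupby("CHR", sort=False):
            bp = grp["BP"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must lie in {0, 1, 2} or be missing")

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.samples,
            self.variants.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
        )


@dataclass
class PhenotypeTable:
    """Quantitative traits plus covariates on one cohort.

    ``traits`` and ``covariates`` are DataFrames indexed like ``samples``.
    ``genetic_values`` (optional) holds the simulated additive genetic values
    on the same scale as the standardized traits — ground truth for
    parameter-recovery tests, absent for real data.
    """

    samples: np.ndarray
    traits: pd.DataFrame
    covariates: pd.DataFrame
    genetic_values: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=object)
        if len(self.traits) != len(self.samples) or len(self.covariates) != len(self.samples):
            raise ValueError("trait/covariate rows must match samples")

    @property
    def trait_names(self) -> list:
        return list(self.traits.columns)

    def validate(self, genotypes: Optional[GenotypeTable] = None) -> None:
        if genotypes is not None and not np.array_equal(self.samples, genotypes.samples):
            raise ValueError("phenotype samples do not match genotype samples")
        sd = self.traits.std(axis=0, ddof=1)
        if (sd.fillna(0.0) == 0).any():
            bad = sd.index[(sd.fillna(0.0) == 0)].tolist()
            raise ValueError(f"constant trait column(s): {bad}")


@dataclass
class SummaryStats:
    """One trait's per-SNP association results.

    ``table`` carries SUMSTAT_COLUMNS plus an ``OK`` flag: rows with degenerate
    statistics (zero dosage variance after deletion, perfect fit) keep their
    identifiers but are excluded when written to disk.
    """

    trait_id: str
    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        if "OK" not in self.table.columns:
            self.table = self.table.assign(OK=True)

    @property
    def valid(self) -> pd.DataFrame:
        return self.table[self.table["OK"]].reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return int(self.table["OK"].sum())


@dataclass
class LDScoreTrack:
    """Per-SNP LD scores l_j >= 1 and the total scored SNP count M."""

    snp_ids: np.ndarray
    scores: np.ndarray
    M: int = field(default=0)

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.M == 0:
            self.M = len(self.scores)
        if len(self.snp_ids) != len(self.scores):
            raise ValueError("snp_ids and scores length mismatch")

    def for_snps(self, snps: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.snp_ids)
        pos = idx.get_indexer(list(snps))
        if (pos < 0).any():
            missing = np.asarray(list(snps))[pos < 0][:3]
            raise KeyError(f"SNPs not in LD score track, e.g. {missing.tolist()}")
        return self.scores[pos]
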