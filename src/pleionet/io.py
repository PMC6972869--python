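"""Readers and writers for the pipeline's delimited text formats.

Formats:

* summary statistics — tab-delimited, header ``SNP CHR BP A1 A2 BETA SE Z P N``
  (Z optional on read, recomputed as BETA/SE);
* genotypes — tab-delimited sample x SNP dosage table; the SNP header row is
  followed by two commented variant-metadata rows (``#ALLELES`` A1,A2 and
  ``#POS`` chr:bp); missing dosages written as ``NA`` and kept missing on read;
* phenotypes/covariates — tab-delimited with an ``IID`` key column and a
  ``#traits:`` comment naming the trait columns;
* genetic-correlation matrices — long-format TSV (trait1, trait2, rg, se, p,
  valid) plus a square-matrix TSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import SUMSTAT_COLUMNS, GenotypeTable, PhenotypeTable, SummaryStats

MISSING = "NA"
REQUIRED_ON_READ = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N"]
_NUMERIC = ["BP", "BETA", "SE", "Z", "P", "N"]


class FormatError(ValueError):
    """Malformed input file."""


def read_summary_stats(path, trait_id: Optional[str] = None) -> SummaryStats:
    """Read a summary-statistics TSV, validating columns and numerics.

    Rows with non-parsable numeric fields are rejected with a row-indexed
    error report; a missing required column or duplicate SNP id is a
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_ON_READ:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    bad_rows = {}
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.upper() != MISSING)
        for i in df.index[bad]:
            bad_rows.setdefault(int(i), []).append(col)
        df[col] = parsed
    if bad_rows:
        report = "; ".join(f"row {i}: {cols}" for i, cols in sorted(bad_rows.items()))
        raise FormatError(f"non-parsable numeric values — {report}")
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise FormatError(f"duplicate SNP id: {dup}")
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    else:
        fill = df["Z"].isna()
        df.loc[fill, "Z"] = df.loc[fill, "BETA"] / df.loc[fill, "SE"]
    df = df[SUMSTAT_COLUMNS]
    if trait_id is None:
        trait_id = Path(path).name.split(".")[0]
    return SummaryStats(trait_id=trait_id, table=df)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write valid rows; floats use repr formatting so round-trips are lossless."""
    stats.valid[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


# -- genotypes -------------------------------------------------------------

def write_genotypes(gt: GenotypeTable, path) -> None:
    v = gt.variants
    with open(path, "w") as fh:
        fh.write("IID\t" + "\t".join(map(str, v["SNP"])) + "\n")
        fh.write("#ALLELES\t" + "\t".join(f"{a},{b}" for a, b in zip(v["A1"], v["A2"])) + "\n")
        fh.write("#POS\t" + "\t".join(f"{c}:{p}" for c, p in zip(v["CHR"], v["BP"])) + "\n")
        for i, iid in enumerate(gt.samples):
            row = gt.dosages[i]
            cells = [MISSING if np.isnan(x) else str(int(x)) for x in row]
            fh.write(str(iid) + "\t" + "\t".join(cells) + "\n")


def read_genotypes(path) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        alleles = fh.readline().rstrip("\n").split("\t")
        pos = fh.readline().rstrip("\n").split("\t")
        rest = fh.read()
    if header[0] != "IID" or alleles[0] != "#ALLELES" or pos[0] != "#POS":
        raise FormatError("genotype file must start with IID / #ALLELES / #POS rows")
    snps = header[1:]
    a1, a2 = zip(*(a.split(",") for a in alleles[1:]))
    chrom, bp = zip(*(p.split(":") for p in pos[1:]))
    body = pd.read_csv(
        _io.StringIO(rest), sep="\t", header=None, names=["IID"] + snps, na_values=[MISSING]
    )
    variants = pd.DataFrame(
        {"SNP": snps, "CHR": chrom, "BP": np.asarray(bp, dtype=int), "A1": a1, "A2": a2}
    )
    gt = GenotypeTable(
        samples=body["IID"].to_numpy(dtype=object),
        variants=variants,
        dosages=body[snps].to_numpy(dtype=float),
    )
    gt.validate()
    return gt


def write_vcf(gt: GenotypeTable, path) -> None:
    """Minimal GT-only unphased VCF export (REF = A2, ALT = A1)."""
    v = gt.variants
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, gt.samples)) + "\n")
        for j in range(gt.n_snps):
            calls = [gtmap.get(x, "./.") for x in gt.dosages[:, j]]
            fh.write(
                f"{v['CHR'].iat[j]}\t{v['BP'].iat[j]}\t{v['SNP'].iat[j]}\t"
                f"{v['A2'].iat[j]}\t{v['A1'].iat[j]}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# -- phenotypes ------------------------------------------------------------

def write_phenotypes(ph: PhenotypeTable, path) -> None:
    df = pd.concat(
        [pd.Series(ph.samples, name="IID"), ph.traits.reset_index(drop=True),
         ph.covariates.reset_index(drop=True)],
        axis=1,
    )
    with open(path, "w") as fh:
        fh.write("#traits: " + ",".join(ph.trait_names) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def read_phenotypes(path) -> PhenotypeTable:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#traits:"):
            raise FormatError("phenotype file must start with a '#traits:' line")
        trait_cols = [c for c in first.split(":", 1)[1].strip().split(",") if c]
        df = pd.read_csv(fh, sep="\t", na_values=[MISSING])
    if "IID" not in df.columns:
        raise FormatError("missing required column: IID")
    covar_cols = [c for c in df.columns if c not in trait_cols and c != "IID"]
    return PhenotypeTable(
        samples=df["IID"].to_numpy(dtype=object),
        traits=df[trait_cols],
        covariates=df[covar_cols],
    )


# -- genetic-correlation matrices ------------------------------------------

def write_rg_matrix(rg, prefix) -> None:
    """Write long-format (``<prefix>.tsv``) and square (``<prefix>.square.tsv``)."""
    rows = []
    K = len(rg.traits)
    for i in range(K):
        for j in range(i + 1, K):
            rows.append(
                {
                    "trait1": rg.traits[i],
                    "trait2": rg.traits[j],
                    "rg": rg.rg[i, j],
                    "se": rg.se[i, j],
                    "p": rg.p[i, j],
                    "valid": bool(rg.valid[i, j]),
                }
            )
    pd.DataFrame(rows).to_csv(f"{prefix}.tsv", sep="\t", index=False)
    pd.DataFrame(rg.rg, index=rg.traits, columns=rg.traits).to_csv(
        f"{prefix}.square.tsv", sep="\t"
    )


def read_rg_matrix(path):
    from .ldsc import GeneticCorrelationMatrix

    df = pd.read_csv(path, sep="\t")
    traits = sorted(set(df["trait1"]) | set(df["trait2"]))
    K = len(traits)
    idx = {t: i for i, t in enumerate(traits)}
    rg = np.eye(K)
    se = np.zeros((K, K))
    p = np.zeros((K, K))
    valid = np.eye(K, dtype=bool)
    for _, row in df.iterrows():
        i, j = idx[row["trait1"]], idx[row["trait2"]]
        rg[i, j] = rg[j, i] = row["rg"]
        se[i, j] = se[j, i] = row["se"]
        p[i, j] = p[j, i] = row["p"]
        valid[i, j] = valid[j, i] = bool(row["valid"])
    return GeneticCorrelationMatrix(traits=traits, rg=rg, se=se, p=p, valid=valid)
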