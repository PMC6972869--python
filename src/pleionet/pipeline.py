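"""End-to-end orchestration: synth -> GWAS -> r_g -> network -> CPASSOC.

One YAML config drives every stage; all randomness flows from the single
config seed through named per-stage substreams; each stage writes delimited
text outputs under its own subdirectory and the run manifest records a
checksum per file, so a repeated run with the same config is byte-identical
and a resumed run can skip completed stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from ._utils import sha256_file, sha256_text, substream
from .cpassoc import module_scan
from .datatypes import GenotypeTable
from .gwas import QCConfig, genomic_control_lambda, gwas_scan, snp_qc
from .ldsc import build_rg_matrix, estimate_h2
from .network import DegenerateFitError, ModuleDetector
from .simulate import (
    LDBlocks,
    SimulationTruth,
    make_ld_scores,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

STAGES = ["synth", "gwas", "ldscores", "gencorr", "network", "cpassoc", "report"]
DEFAULT_COVARIATES = ["AGE", "SEX", "EDU", "HAND", "PC1", "PC2", "PC3"]


@dataclass
class SynthConfig:
    n_samples: int = 2000
    n_snps: int = 5000
    n_traits: int = 10
    maf_range: Tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    ld_block_size: int = 25
    ld_rho_range: Tuple[float, float] = (0.1, 0.9)
    h2: float = 0.5
    module_sizes: Tuple[int, ...] = (4, 3)
    rho_within: float = 0.8
    env_corr: float = 0.2
    n_causal: Optional[int] = None  # None = all SNPs (infinitesimal model)
    signal_snps: int = 2
    signal_effect: float = 0.12


@dataclass
class PipelineConfig:
    outdir: str = "pleionet_run"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    covariates: Tuple[str, ...] = tuple(DEFAULT_COVARIATES)
    ld_window: int = 50
    gencorr_blocks: int = 200
    beta_grid: Tuple[float, ...] = (2, 4, 6, 8)
    threshold_grid: Tuple[float, ...] = (0.5, 0.3, 0.2, 0.1)
    fallback_beta: float = 6.0
    fallback_threshold: float = 0.2
    min_module_size: int = 3
    cut_height_fraction: float = 0.9
    cpassoc_draws: int = 20_000
    cpassoc_z_cutoff: float = 1.96
    cpassoc_threshold: float = 1e-7

    def validate(self) -> None:
        self.qc.validate()
        if self.synth.n_samples <= 0 or self.synth.n_snps <= 0 or self.synth.n_traits <= 0:
            raise ValueError("synth dimensions must be positive")
        if not (0 <= self.synth.h2 <= 1):
            raise ValueError("h2 must lie in [0, 1]")
        if sum(self.synth.module_sizes) > self.synth.n_traits:
            raise ValueError("module sizes exceed the trait count")
        if any(b < 1 for b in self.beta_grid):
            raise ValueError("beta grid values must be >= 1")
        if any(not (0 < t <= 1) for t in self.threshold_grid):
            raise ValueError("threshold grid values must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.cpassoc_draws < 10_000:
            raise ValueError("cpassoc_draws must be >= 10,000")
        if not (0 < self.cpassoc_threshold < 1):
            raise ValueError("cpassoc_threshold must lie in (0, 1)")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in d["synth"].items()})
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCConfig(**d["qc"])
        for key in ("covariates", "beta_grid", "threshold_grid"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # the output location is not part of the science
        return sha256_text(json.dumps(d, sort_keys=True, default=str))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: Dict[str, str]
    stages: Dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "versions": self.versions, "stages": self.stages},
                fh, indent=2, sort_keys=True,
            )

    def checksums(self) -> Dict[str, str]:
        out = {}
        for stage in self.stages.values():
            out.update(stage["files"])
        return out


def default_truth(genotypes: GenotypeTable, cfg: SynthConfig, seed: int) -> SimulationTruth:
    """Build the default block-structured trait truth from the synth config.

    Traits are grouped into the configured modules with rho_within genetic
    correlation inside each module and 0 between; leftover traits are
    genetically independent. Signal SNPs get aligned effects on the first
    module's traits (the last one with opposite signs on two traits, so both
    homogeneous and heterogeneous detection paths are exercised).
    """
    K = cfg.n_traits
    rho = np.eye(K)
    start = 0
    blocks: List[List[int]] = []
    for size in cfg.module_sizes:
        idx = list(range(start, start + size))
        blocks.append(idx)
        for i in idx:
            for j in idx:
                if i != j:
                    rho[i, j] = cfg.rho_within
        start += size

    rng = substream(seed, "truth")
    snp_ids = genotypes.snp_ids
    fixed = {}
    if cfg.signal_snps > 0 and blocks:
        chosen = rng.choice(len(snp_ids), size=cfg.signal_snps, replace=False)
        for s, j in enumerate(np.sort(chosen)):
            eff = np.zeros(K)
            members = blocks[0]
            eff[members] = cfg.signal_effect
            if s == cfg.signal_snps - 1 and len(members) >= 2:
                eff[members[1]] = -cfg.signal_effect
            fixed[str(snp_ids[j])] = eff

    return SimulationTruth.make(
        genotypes,
        h2=np.full(K, cfg.h2),
        rho_g=rho,
        n_causal=cfg.n_causal,
        mode="shared",
        env_corr=cfg.env_corr,
        seed=seed,
        fixed_effects=fixed,
    )


class _Runner:
    def __init__(self, config: PipelineConfig, resume: bool):
        self.cfg = config
        self.resume = resume
        self.out = Path(config.outdir)
        self.dirty = False
        self.manifest = RunManifest(
            config_hash=config.config_hash(),
            seed=config.seed,
            versions={"pleionet": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        )

    def stage_dir(self, name: str) -> Path:
        d = self.out / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def run_stage(self, name: str, outputs: List[Path], fn) -> None:
        rel = [str(p.relative_to(self.out)) for p in outputs]
        if self.resume and not self.dirty and all(p.exists() for p in outputs):
            logger.info("stage=%s event=skipped (outputs present)", name)
            self.manifest.stages[name] = {
                "files": {r: sha256_file(p) for r, p in zip(rel, outputs)},
                "recomputed": False,
                "seconds": 0.0,
            }
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        self.dirty = True
        missing = [p for p in outputs if not p.exists()]
        if missing:
            raise RuntimeError(f"stage '{name}' did not produce {missing}")
        self.manifest.stages[name] = {
            "files": {r: sha256_file(p) for r, p in zip(rel, outputs)},
            "recomputed": True,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage=%s event=done seconds=%.2f", name, self.manifest.stages[name]["seconds"])


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunManifest:
    """Execute all stages in order; fails fast with the failing stage named."""
    config.validate()
    r = _Runner(config, resume)
    cfg = config

    synth_dir = r.stage_dir("synth")
    geno_path = synth_dir / "genotypes.tsv"
    pheno_path = synth_dir / "phenotypes.tsv"
    truth_path = synth_dir / "truth.yaml"

    def do_synth():
        seed = int(substream(cfg.seed, "synth").integers(0, 2**31 - 1))
        gt = simulate_genotypes(
            cfg.synth.n_samples,
            cfg.synth.n_snps,
            cfg.synth.maf_range,
            cfg.synth.missing_rate,
            seed=seed,
            ld=LDBlocks(cfg.synth.ld_block_size, cfg.synth.ld_rho_range),
        )
        truth = default_truth(gt, cfg.synth, seed)
        ph = simulate_phenotypes(gt, truth)
        io.write_genotypes(gt, geno_path)
        io.write_phenotypes(ph, pheno_path)
        truth.to_yaml(truth_path)

    r.run_stage("synth", [geno_path, pheno_path, truth_path], do_synth)

    gwas_dir = r.stage_dir("sumstats")
    n_traits = cfg.synth.n_traits
    trait_names = [f"T{k + 1}" for k in range(n_traits)]
    sumstat_paths = [gwas_dir / f"{t}.sumstats.tsv" for t in trait_names]
    qc_path = gwas_dir / "qc_report.tsv"
    lambda_path = gwas_dir / "lambda_gc.tsv"

    def do_gwas():
        gt = io.read_genotypes(geno_path)
        ph = io.read_phenotypes(pheno_path)
        gt_qc, report = snp_qc(gt, cfg.qc)
        report.to_csv(qc_path, sep="\t", index=False)
        logger.info("stage=gwas event=qc excluded=%d retained=%d", len(report), gt_qc.n_snps)
        lam_rows = []
        for t, path in zip(trait_names, sumstat_paths):
            ss = gwas_scan(gt_qc, ph, t, covariates=list(cfg.covariates))
            io.write_summary_stats(ss, path)
            lam_rows.append({"trait": t, "lambda_gc": genomic_control_lambda(ss)})
        pd.DataFrame(lam_rows).to_csv(lambda_path, sep="\t", index=False)

    r.run_stage("gwas", sumstat_paths + [qc_path, lambda_path], do_gwas)

    ld_dir = r.stage_dir("ldscores")
    ld_path = ld_dir / "ldscores.tsv"

    def do_ld():
        gt = io.read_genotypes(geno_path)
        gt_qc, _ = snp_qc(gt, cfg.qc)
        track = make_ld_scores(gt_qc, cfg.ld_window)
        pd.DataFrame({"SNP": track.snp_ids, "L2": track.scores, "M": track.M}).to_csv(
            ld_path, sep="\t", index=False
        )

    r.run_stage("ldscores", [ld_path], do_ld)

    rg_dir = r.stage_dir("rg")
    rg_long = rg_dir / "rg.tsv"
    rg_square = rg_dir / "rg.square.tsv"
    h2_path = rg_dir / "h2.tsv"

    def do_gencorr():
        stats_list = [io.read_summary_stats(p, trait_id=t) for t, p in zip(trait_names, sumstat_paths)]
        ld_df = pd.read_csv(ld_path, sep="\t")
        from .datatypes import LDScoreTrack

        track = LDScoreTrack(ld_df["SNP"].to_numpy(dtype=object), ld_df["L2"].to_numpy(),
                             M=int(ld_df["M"].iloc[0]))
        rows = []
        for s in stats_list:
            est = estimate_h2(s, track, cfg.gencorr_blocks)
            rows.append({"trait": s.trait_id, "h2": est.h2, "se": est.se,
                         "intercept": est.intercept})
        pd.DataFrame(rows).to_csv(h2_path, sep="\t", index=False)
        rg = build_rg_matrix(stats_list, track, cfg.gencorr_blocks)
        logger.info("stage=gencorr event=filter invalid_pairs=%d", rg.n_invalid)
        io.write_rg_matrix(rg, str(rg_dir / "rg"))

    r.run_stage("gencorr", [rg_long, rg_square, h2_path], do_gencorr)

    net_dir = r.stage_dir("network")
    adj_path = net_dir / "adjacency.tsv"
    tom_path = net_dir / "tom.tsv"
    grid_path = net_dir / "grid_fits.tsv"
    modules_path = net_dir / "modules.tsv"
    merges_path = net_dir / "merges.tsv"

    def do_network():
        rg = io.read_rg_matrix(rg_long)
        det = ModuleDetector(
            beta_grid=cfg.beta_grid,
            threshold_grid=cfg.threshold_grid,
            min_size=cfg.min_module_size,
            cut_height_fraction=cfg.cut_height_fraction,
        )
        try:
            det.fit(rg)
            grid = det.grid_
        except DegenerateFitError as exc:
            logger.warning(
                "stage=network event=fallback reason=%s beta=%s threshold=%s",
                exc, cfg.fallback_beta, cfg.fallback_threshold,
            )
            det = ModuleDetector(
                beta=cfg.fallback_beta,
                p_threshold=cfg.fallback_threshold,
                min_size=cfg.min_module_size,
                cut_height_fraction=cfg.cut_height_fraction,
            ).fit(rg)
            grid = pd.DataFrame(
                [{"beta": cfg.fallback_beta, "threshold": cfg.fallback_threshold,
                  "r2": np.nan, "slope": np.nan, "n_zero_degree": np.nan,
                  "status": "fallback"}]
            )
        grid.to_csv(grid_path, sep="\t", index=False)
        adj = det.adjacency_
        pd.DataFrame(adj.a, index=adj.traits, columns=adj.traits).to_csv(adj_path, sep="\t")
        if det.tom_ is not None:
            pd.DataFrame(det.tom_.w, index=det.tom_.traits, columns=det.tom_.traits).to_csv(
                tom_path, sep="\t"
            )
            from scipy.cluster.hierarchy import linkage
            from scipy.spatial.distance import squareform

            d = det.tom_.d.copy()
            np.fill_diagonal(d, 0.0)
            Z = linkage(squareform(d, checks=False), method="average")
            pd.DataFrame(Z, columns=["left", "right", "height", "size"]).to_csv(
                merges_path, sep="\t", index=False
            )
        else:
            pd.DataFrame(columns=["left", "right", "height", "size"]).to_csv(
                merges_path, sep="\t", index=False
            )
            pd.DataFrame().to_csv(tom_path, sep="\t")
        pd.DataFrame({"trait": det.partition_.traits, "module": det.partition_.labels}).to_csv(
            modules_path, sep="\t", index=False
        )
        logger.info("stage=network event=modules n_modules=%d isolated=%d",
                    det.partition_.n_modules, int((det.partition_.labels == 0).sum()))

    r.run_stage("network", [adj_path, tom_path, grid_path, modules_path, merges_path], do_network)

    cp_dir = r.stage_dir("cpassoc")
    summary_path = cp_dir / "modules_summary.tsv"

    def module_list() -> Dict[int, List[str]]:
        mod = pd.read_csv(modules_path, sep="\t")
        out = {}
        for lab, grp in mod[mod["module"] > 0].groupby("module"):
            out[int(lab)] = list(grp["trait"])
        return out

    def do_cpassoc():
        mods = module_list()
        stats_by_trait = {
            t: io.read_summary_stats(p, trait_id=t) for t, p in zip(trait_names, sumstat_paths)
        }
        rows = []
        for lab, members in sorted(mods.items()):
            stats_list = [stats_by_trait[t] for t in members]
            seed = int(substream(cfg.seed, f"cpassoc-{lab}").integers(0, 2**31 - 1))
            res = module_scan(
                stats_list,
                threshold=cfg.cpassoc_threshold,
                z_cutoff=cfg.cpassoc_z_cutoff,
                B=cfg.cpassoc_draws,
                seed=seed,
            )
            res.to_csv(cp_dir / f"module{lab}.cpassoc.tsv", sep="\t", index=False)
            rows.append({
                "module": lab, "n_traits": len(members), "n_snps": len(res),
                "n_significant": int(res["SIGNIFICANT"].sum()),
                "min_p_hom": res["P_HOM"].min(), "min_p_het": res["P_HET"].min(),
            })
        pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)

    cp_outputs = [summary_path]
    r.run_stage("cpassoc", cp_outputs, do_cpassoc)

    rep_dir = r.stage_dir("report")
    report_path = rep_dir / "association_tables.done"

    def do_report():
        mods = module_list()
        for lab in sorted(mods):
            res = pd.read_csv(cp_dir / f"module{lab}.cpassoc.tsv", sep="\t")
            assoc, qq = export_association_table(res, threshold=cfg.cpassoc_threshold)
            assoc.to_csv(rep_dir / f"module{lab}.assoc.tsv", sep="\t", index=False)
            qq.to_csv(rep_dir / f"module{lab}.qq.tsv", sep="\t", index=False)
        report_path.write_text("ok\n")

    r.run_stage("report", [report_path], do_report)

    r.manifest.to_json(r.out / "manifest.json")
    return r.manifest


def export_association_table(
    scan: pd.DataFrame, threshold: float = 1e-7
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready association and QQ tables from a module scan.

    Rows sorted by (CHR, BP) with -log10(P) columns for both statistics and
    inclusive flags at the genome-wide 5e-8 line and the configured threshold;
    the QQ table pairs expected -log10((i-0.5)/m) with the observed order
    statistics.
    """
    if scan.empty:
        raise ValueError("empty scan results")
    out = scan.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    with np.errstate(divide="ignore"):
        out["NEG_LOG10_P_HOM"] = -np.log10(out["P_HOM"])
        out["NEG_LOG10_P_HET"] = -np.log10(out["P_HET"])
    best = np.minimum(out["P_HOM"], out["P_HET"])
    out["PASS_GENOME_WIDE"] = best <= 5e-8
    out["PASS_MODULE_SCAN"] = best <= threshold
    m = len(out)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame(
        {
            "expected_neglog10_p": expected,
            "observed_neglog10_p_hom": np.sort(out["NEG_LOG10_P_HOM"].to_numpy())[::-1],
            "observed_neglog10_p_het": np.sort(out["NEG_LOG10_P_HET"].to_numpy())[::-1],
        }
    )
    return out, qq
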