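# pleionet

Cross-phenotype GWAS analysis for families of correlated quantitative traits —
originally motivated by brain-imaging genetics, where a cohort is measured on
dozens to hundreds of regional brain volumes (ROIs) and each trait's GWAS is
underpowered on its own. `pleionet` implements the full chain from per-trait
summary statistics to combined cross-phenotype association evidence:

1. **GWAS stage** — per-SNP quality control (call rate ≥ 0.98, MAF ≥ 0.01,
   HWE P ≥ 10⁻⁶), additive-model linear regression with covariates, and the
   genomic-control diagnostic λ = median(T²)/0.45494.
2. **Genetic correlations** — a simplified cross-trait LD score regression:
   for traits *k*, *l* with Z-scores z, regress z_k·z_l on the LD score l_j
   with an intercept absorbing sample overlap;
   ρ̂_g = slope·M/√(N̄_k·N̄_l) and r̂_g = ρ̂_g/√(ĥ²_k·ĥ²_l), with block-jackknife
   standard errors. Pairs estimated as NA or outside [−1, 1] are flagged
   invalid and excluded from the network.
3. **Trait network and modules** — soft-threshold adjacency a_ij = |r_g,ij|^β
   (pairs failing the r_g P-value threshold set to 0), (β, threshold) chosen
   over the grid β ∈ {2,4,6,8} × P ∈ {0.5,0.3,0.2,0.1} by the scale-free fit
   R² of log p(k) on log k, topological overlap
   w_ij = (l_ij + a_ij)/(min{k_i,k_j} + 1 − a_ij), and average-linkage
   clustering of d = 1 − w into trait modules.
4. **Cross-phenotype association (CPASSOC-style)** — within each module, the
   per-SNP Wald statistics T are combined as

   S_Hom = [e′(RW)⁻¹T]² / e′(WRW)⁻¹e  ~ χ²₁ under H₀,

   with W = diag(√n) and R the null correlation of the statistics estimated
   from sub-significant SNPs, and S_Het = max_τ S(τ) over magnitude-truncated
   subvectors {|T| > τ}, calibrated by Monte-Carlo simulation from MVN(0, R)
   with a fitted beta tail approximation.
5. **Synthetic cohorts** — a seeded generator producing genotypes (optionally
   with block LD), correlated multi-trait phenotypes with known heritability
   and genetic-correlation targets, covariates, and planted multi-trait signal
   SNPs, so every stage is testable with ground truth.

## Worked example

```python
import numpy as np
from pleionet import (SimulationTruth, simulate_genotypes, simulate_phenotypes,
                      gwas_scan, make_ld_scores, estimate_rg_pair, module_scan)

gt = simulate_genotypes(2000, 5000, maf_range=(0.05, 0.5), seed=7)
truth = SimulationTruth.make(gt, h2=[0.5, 0.5, 0.5], rho_g=0.6, n_causal=250,
                             seed=8, env_corr=0.2,
                             fixed_effects={"rs1000": np.array([0.12, 0.12, 0.12])})
ph = simulate_phenotypes(gt, truth)
stats = [gwas_scan(gt, ph, t, covariates=["AGE", "SEX"]) for t in ph.trait_names]

ld = make_ld_scores(gt, 0)
est = estimate_rg_pair(stats[0], stats[1], ld)
print(f"rg = {est.rg:.3f} (SE {est.se:.3f}, P {est.p:.2e})")

scan = module_scan(stats, B=20_000, seed=9).set_index("SNP")
hit = scan.loc["rs1000"]
print(f"planted SNP: S_Hom = {hit.S_HOM:.1f}, P_Hom = {hit.P_HOM:.2e}, "
      f"P_Het = {hit.P_HET:.2e}")
```

Output from this exact snippet:

```
rg = 0.472 (SE 0.106, P 7.96e-06)
planted SNP: S_Hom = 40.6, P_Hom = 1.90e-10, P_Het = 2.28e-09
```

The estimated genetic correlation (0.472) lands within about one standard
error of the planted target 0.6 — at this cohort size (n = 2000, m = 5000)
per-pair estimates carry SEs around 0.1, which is exactly why the downstream
network filters pairs on their r_g P-values. The SNP planted with aligned
effects on all three traits passes genome-wide significance on the homogeneous
combined statistic (P_Hom ≈ 2·10⁻¹⁰), and the heterogeneous statistic agrees
while paying a small price for its extra flexibility, the expected ordering
for a homogeneous signal.

The full pipeline (synthesis → GWAS → r_g → network → modules → CPASSOC) runs
from a single YAML config:

```bash
pleionet run --config run.yaml      # outputs under <outdir>/{synth,sumstats,rg,network,cpassoc,report}
```

Individual stages are also exposed: `pleionet synth | gwas | gencorr |
network | cpassoc`.

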