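# Methods

This note documents the models implemented in `pleionet`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## 1. GWAS stage

**Model.** For each SNP j and trait k, ordinary least squares of the trait on
the A1 dosage plus an intercept and covariates; the Wald statistic
T = β̂/ŝ is referred to the standard normal (the cohorts of interest have
n in the thousands; an exact Student-t reference is available via
`t_reference="t"`). Samples with a missing dosage are casewise-deleted per
SNP — mean imputation is deliberately not offered because it silently
overstates the per-SNP n. Internally the scan solves per-SNP normal equations
with sparse corrections for the deleted rows, so a 5000-SNP scan on 2000
samples takes well under a second; the coefficients and standard errors are
bitwise-checked against statsmodels OLS in the test suite.

**QC.** Per-SNP filters, inclusive at the threshold: call rate ≥ 0.98,
MAF ≥ 0.01 (computed on the post-call-rate samples), Hardy-Weinberg
equilibrium P ≥ 10⁻⁶ from the 1-df chi-square goodness-of-fit test (an exact
test is a documented alternative, off by default; the chi-square is standard
and matches the printed thresholds). The exclusion report names each removed
SNP with the first failing rule in the order call rate → MAF → HWE. Whether
MAF/HWE should use all subjects or controls only is unresolved upstream; here
they use all analyzed samples.

**Genomic control.** λ = median(T²)/0.45494, the χ²₁ median to five decimals.
Under a polygenic trait λ exceeds 1 by design (true signal inflation), so the
pipeline reports it as a diagnostic rather than applying correction.

## 2. Simplified cross-trait LD score regression

The single-trait model is E[χ²_j] = 1 + N·h²·l_j/M and the cross-trait model
E[z_kj·z_lj] = ρ_null + √(N_k N_l)·ρ_g·l_j/M, where l_j is the LD score, M the
number of scored SNPs, and ρ_null the null correlation of the statistics
induced by sample overlap and phenotypic correlation. Two regimes are handled:

* **Varying LD scores** — weighted least squares with a free intercept.
  Weights are 1/l times the inverse squared predicted mean response, iterated
  twice from a 1/l² start (the cross-trait variance proxy is
  (1+a_k)(1+a_l)+line², with a_k the trait's own fitted mean curve). Plain
  unweighted OLS was evaluated first and rejected: at desk scale (m = 5000,
  n = 2000, a few hundred LD blocks) it is dominated by the heteroskedastic
  high-LD SNPs and its per-pair error roughly doubles.
* **Constant LD scores (independent SNPs)** — the slope of a regression on a
  constant regressor is unidentifiable, so the intercept is pinned: at 1 (its
  theoretical null value) for the single-trait fit, and for a pair at the null
  correlation recovered from SNPs with both |Z| below 1.96. The truncated
  sample attenuates the product moment (E[z²| |z|<1.96] ≈ 0.759), so the
  observed truncated mean is inverted through the exact doubly-truncated
  bivariate-normal moment curve, computed by Gauss-Legendre quadrature with
  the inner integral in closed form. This makes the independent-SNP regime the
  *more* precise one — the information sits in the genome-wide mean rather
  than in a slope across a limited number of LD blocks.

r̂_g = ρ̂_g/√(ĥ²_k ĥ²_l). Heritability estimates may be ≤ 0 and are never
clipped; any pair whose r_g is NA or outside [−1, 1], or whose h² denominators
are non-positive, is flagged invalid and dropped from the network — the same
filter the original analysis applied to its incorrectly estimated pairs.
Standard errors are delete-a-block jackknives over 200 contiguous SNP blocks
(⌊m/2⌋ when m < 400), holding the h² denominators at their full-sample values;
pair P-values use the normal reference on estimate/SE. Strand-ambiguous (A/T,
C/G) SNPs are kept by default because the synthetic data have no strand
issues; real-data users should drop them upstream. This estimator is
intentionally simple and is not a replacement for the published LDSC software.

## 3. Trait network and modules

Adjacency a_ij = |r_g,ij|^β for valid pairs with r_g P ≤ threshold, else 0;
zero diagonal. The (β, threshold) pair is selected over the grid
β ∈ {2,4,6,8} × P ∈ {0.5,0.3,0.2,0.1} by the scale-free fit: node degree k =
count of direct connections, nodes with k = 0 excluded, k binned into 10
equal-width bins, and R² of the regression of log₁₀(bin frequency) on
log₁₀(bin mean k) maximized; fits with a rising slope are disqualified (a
rising degree distribution is not scale-free), and ties resolve to the smaller
β, then the larger threshold. Two connectivity notions coexist deliberately:
the *count* degree drives the scale-free selection, while the topological
overlap uses the *weighted* connectivity k_i = Σ_u a_iu. Because the nonzero
pattern of |r_g|^β does not depend on β, the count-based R² varies only with
the P threshold and the tie-break effectively decides β — both connectivities
are therefore reported in the grid table so users can judge.

TOM: w_ij = (l_ij + a_ij)/(min{k_i,k_j} + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu·a_uj (the zero diagonal makes the plain matrix product
equivalent), w_ii = 1, dissimilarity d = 1 − w; w is provably in [0,1] for
adjacencies in [0,1] and is property-tested on random matrices.

Modules: average-linkage hierarchical clustering of d on the k > 0 subgraph,
cut at `cut_height_fraction` × the maximum merge height; clusters below
`min_size` (default 3, the smallest module size the motivating analysis
reports) and isolated nodes get label 0; labels are assigned in decreasing
size order. The cut method is an open design point (no static cut is
prescribed upstream); the default fraction is 0.9, chosen because at
desk-scale r_g noise (per-pair SE ≈ 0.1–0.2) distinct planted modules merge at
about 0.89–0.95 of the top height and a 0.95 cut fails to separate them.
A dendrogram in which every merge happens at a single height (a perfectly
uniform network) is treated as one branch, i.e. one module. Dynamic tree cut
is a documented alternative, not implemented.

## 4. CPASSOC statistics

With T the vector of per-trait Wald statistics for one SNP, W = diag(w),
w_k = √(mean N_k), and R the null correlation of the statistics:

* S_Hom = [e′(RW)⁻¹T]²/[e′(WRW)⁻¹e], χ²₁ under the null (the implementation
  verifies the variance identity: the numerator's null variance equals the
  denominator). The weights enter through (RW)⁻¹ exactly as the defining
  expression is printed; because that convention *down*-weights large samples,
  an alternate convention applying W directly (e′WR⁻¹T, e′WR⁻¹We) is available
  via `convention="direct"`. Both reduce to the same statistic for equal
  weights — which is the J = 1 single-cohort case throughout this package —
  and both are exactly χ²₁-calibrated.
* S_Het = max over magnitude thresholds τ of the same form evaluated on the
  subvector {|T| > τ}. The supremum over τ > 0 can only change value at the
  order statistics of |T|, so the implementation visits the top-q components
  for q = 1..K (ties broken by index, so the singleton of the largest |T| is
  always a candidate; the numerator of the truncated form is read as the
  square of the scalar e′(R(τ)W(τ))⁻¹T(τ)). Near-singular R or submatrices
  receive a 10⁻⁸ ridge, logged.

**R estimation.** Sample correlation of per-SNP Z-scores across the module's
traits over SNPs with max |Z| < 1.96 (excluding associated loci; the cutoff is
configurable). Truncation attenuates correlations — 0.6 is observed as ≈ 0.48
at this cutoff — so each pairwise value is mapped back through the truncated
bivariate-normal Pearson curve before use, and the matrix is projected to the
nearest correlation matrix if an eigenvalue dips below zero.

**S_Het null.** B Monte-Carlo draws from MVN(0, R) (B ≥ 10,000 enforced;
100,000 by default for standalone scans, 20,000 in the demo pipeline). The
empirical P is (r+1)/(B+1); a beta distribution fitted by maximum likelihood
to the χ²₁-tail transform X = P_χ²₁(S_Het) supplies a smooth tail map used
when the empirical P hits its floor 1/(B+1). At K = 1 X is exactly uniform and
the fit recovers Beta(1, 1).

**Module scan.** SNPs intersected and allele-aligned across the module's
traits (Z sign-flipped for swapped A1/A2; unresolvable allele pairs dropped
and counted); both statistics computed per SNP (vectorized via per-subset
contrast caching); flags at the configured threshold 10⁻⁷ and at the
genome-wide 5·10⁻⁸ line, both inclusive.

## 5. Synthetic cohorts: what they emulate, and what not

One cohort measured on K quantitative traits, so all traits share samples and
their test statistics are correlated under the null — the situation the R
matrix exists for. Genotypes are Binomial(2, MAF) with per-SNP MAF uniform in
a configurable range; the optional block-LD mode draws haplotypes from
block-equicorrelated latent Gaussians (block size 25, within-block latent
correlation uniform in (0.1, 0.9) by default), giving heterogeneous LD scores.
Trait k is Σ causal effects × standardized dosages + planted fixed effects +
covariate effects + correlated Gaussian noise; per-SNP effect vectors are
drawn MVN with covariance diag(√h²)·ρ_g·diag(√h²) scaled by causal-set sizes,
so realized heritabilities and genetic correlations match their targets in
expectation (verified within ±0.05 over 20 replicate draws). Traits are
standardized to unit variance — volumetric units and their scale are not
emulated. Covariates (age, sex, education, handedness, three
principal-component placeholders) exercise the covariate machinery only; there
is no population structure, no real-LD haplotype structure from reference
panels, no family relatedness, and no imputation. Passing tests therefore
demonstrate statistical correctness of the estimators under their assumed
models, not robustness to stratification or real LD.

Default demo cohort (`PipelineConfig()`): n = 2000, m = 5000 SNPs with block
LD, 10 traits with two planted modules (sizes 4 and 3, within-module ρ_g 0.8,
residual correlation 0.2, h² = 0.5, infinitesimal causal model), 1% missing
genotypes, and two signal SNPs on the first module — one aligned, one with
opposite signs on two traits, so the scan exercises both statistics. The full
run takes well under a minute on one CPU and is byte-identical under a fixed
seed; all stage randomness derives from the single config seed through named
substreams.

## 6. Problem sizes, tolerances, tie-breaks

* Recovery simulations use m = 5000 SNPs, n = 2000 samples, 20 replicate
  seeds; genetic-correlation recovery is run in the independent-SNP regime
  with 250 shared causal SNPs and two trait pairs per target value, where the
  pinned-intercept estimator is near-unbiased (per-pair SE ≈ 0.1, per-seed
  two-pair average MAE ≈ 0.06).
* S_Het equals brute-force subset enumeration to 1e-10; TOM matches a
  triple-loop oracle to 1e-12.
* χ²₁ median fixed at 0.45494; λ warnings below 100 SNPs; LD-score regression
  refuses fewer than 200 SNPs; R estimation requires 500 shared and 100 null
  SNPs.
* Degenerate inputs: zero-dosage-variance and perfect-fit SNPs are emitted
  flagged and excluded from written files; a monomorphic SNP contributes
  nothing to neighbours' LD scores (with a warning); an empty QC survivor set
  is legal and reported.
* Network selection tie-break: smaller β, then larger threshold. S_Het ties
  resolve to the smallest retained subset.

## 7. Known limitations

The LDSC estimator assumes the generative regimes above; on real data it is a
rough screen, not a substitute for the published software. The scale-free
selection on tens of traits is statistically weak (the pipeline falls back to
β = 6, threshold 0.2 with a logged warning when every grid cell is degenerate
or rising). The beta tail approximation for S_Het is an extrapolation beyond
the Monte-Carlo floor and is secondary to the empirical P wherever the latter
is resolvable. Multi-cohort (J > 1) bookkeeping is limited to running scans on
sample subsets; no genuine meta-analysis across distinct genotype panels is
attempted.
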