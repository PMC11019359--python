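# Methods

## Model and hypotheses

For each SNP × module pair the model is the multivariate linear regression
of the module's K residualised expression levels on the SNP dosage,
`(y_1 … y_K) = G (β_1 … β_K) + covariates + e`, and the null hypothesis is
`β_1 = … = β_K = 0`. The test operates entirely on the vector of univariate
Wald Z scores, which under H₀ is distributed N(0, Σ) with Σ the gene-gene
correlation of residual expression — so the same machinery serves
individual-level data (Z computed internally from dosages and residual
expression via the correlation→t→normal bridge) and summary statistics
(Z supplied, Σ approximated from null SNPs).

## The PC omnibus

Projecting Z on the eigenvectors of Σ gives independent PC scores
`T_PCk ~ N(0, λ_k)`. Six combinations (PCMinP, PCFisher, PCLC, WI, Wald, VC;
see the README table) cover complementary alternatives: Wald weights
low-variance PCs up (sensitive to effects orthogonal to the co-expression
structure), VC and PCLC weight the leading PCs (sensitive to effects aligned
with it), WI is basis-neutral, PCMinP catches single-PC signals, PCFisher
diffuse multi-PC signals. The omnibus statistic is
`t_pco = min(p_PCMinP, …, p_VC)` and the reported p-value is
`p_pco = P₀(t_pco ≤ t_obs)`.

**PC retention.** Only PCs with λ_k > 0.1 (`lambda_min`, dimensionless) are
used. Near-degenerate PCs carry almost no signal variance but destabilise
Wald-type statistics through the 1/λ_k weight; on estimated Σ they are also
the least identifiable directions.

**Component null laws.** PCFisher and Wald use χ² distributions; PCLC a
normal; PCMinP the exact independent-minimum formula `1 − (1 − t)^m` (the
retained PC scores are independent under H₀ because the eigenvectors are
orthogonal). WI and VC are positively weighted sums of independent χ²₁
variables with weights λ_k and λ_k²; their survival functions are computed
exactly — scaled χ² for one or equal weights, a closed-form Bessel-I₀
density for two weights, Imhof's characteristic-function inversion
(oscillation-resolved Gauss–Legendre panels, absolute tolerance ~1e-8
relative to the local tail) for three or more, and a second-order
Lugannani–Rice saddlepoint (~0.7% relative accuracy, validated against
hypoexponential closed forms over 20 decades) beyond survival 1e-10.
Vectorised evaluation interpolates a per-eigenvalue-profile monotone
log-survival grid, so scans pay the quadrature once per model.

**Omnibus calibration.** `calibrate_omnibus` draws B null PC-score vectors
(default B = 100,000, seeded; 200,000 in the simulation front-end), computes
the six p-values per draw, and records (a) the sorted null sample of t_pco
and (b) the 6×6 correlation of the inverse-normal-transformed p-values.
The default p_pco evaluation is the **empirical null curve**: the ECDF of
t_pco on monotone log-log knots where at least ~2,000 exceedances support
it, with the exceedance ratio p(t)/t frozen at its junction value further
into the tail. Brute-force checks (10⁶–2×10⁷ draws across equicorrelated,
AR(1) and decaying-spectrum models) show that ratio plateaus as t → 0, and
the frozen-ratio tail tracks truth within a few percent. An alternative
Gaussian-copula evaluation (`method="mvn"`: a deterministic Genz lattice
orthant probability over the calibrated 6×6 correlation, with a stable
log-space bivariate-normal second-order Bonferroni below t = 1e-4) is
retained as a draw-free cross-check; it is 5–20% conservative in the
moderate tail because the quadratic components are tail-dependent, which a
Gaussian copula cannot represent, and is therefore not the default.
Components whose transformed statistics correlate above 0.9999 (e.g. all six
when one PC is retained) are collapsed before any joint evaluation. Every
evaluation is clamped into the sandwich `t ≤ p_pco ≤ min(1, 6t)`.

**Determinism.** All Monte Carlo is seeded; the MVN lattice integrator uses
a fixed internal seed (scipy's MVN CDF is internally randomised, which would
break bit-reproducibility of scans and power tables).

## Scanning pipelines

*Individual level.* Genes on the test SNP's chromosome are removed from the
module before testing (trans effects must cross chromosomes); when a
cross-mappability table is supplied, module genes cross-mappable to any gene
whose span intersects the closed ±100 kb window around the SNP are removed
as well (coordinates 1-based inclusive everywhere). Each surviving gene
subset gets its own eigendecomposition and omnibus calibration, cached per
(module, excluded set). Multiple testing uses an empirical FDR: genotype
sample labels are permuted (preserving the expression correlation the test
conditions on; one shared permutation per pass, default 10 passes), the full
scan is re-run per pass, and q(t) = [(#null ≤ t)/n_perm] / max(1, #obs ≤ t),
monotonised by a running minimum from the largest p down; a pair is
significant when q ≤ 0.10. Significant SNPs are grouped into loci by greedy
LD clumping: best-p SNP leads (ties by genomic order), absorbing SNPs with
dosage R² ≥ 0.2.

At the permutation-resolution limit this plug-in estimator assigns q = 0
whenever the observed minimum undercuts the whole pooled null — under a
fully null cohort that happens with probability ≈ 1/(n_perm+1) per scan, so
a 10%-FDR scan of a null cohort produces at least one (single-pair) call in
roughly 10–17% of datasets. This is inherent to FDR-level-0.10 calibration
(family-wise error under the global null ≈ the level), not a defect of the
implementation; pseudo-count variants push the planted-signal boundary case
to exactly q = level and were rejected.

*Summary statistics.* Σ is the Pearson correlation of the Z-score rows of
"null SNPs" — SNPs with per-gene two-sided p > 0.05 on every module gene
(configurable; note that this truncation shrinks estimated correlations by
up to ~0.2 at ρ = 0.5, which matters only when the null panel is itself the
target of inference). The estimate is PSD-repaired by eigenvalue clipping at
1e-6 and rescaling to unit diagonal. Modules with a null-SNP-to-gene ratio
at or below 50 are gated out: the desk-scale study in
`tests/test_acceptance.py` shows genomic-control λ falling monotonically
from ≈1.6 at ratio 5 to ≈1.03–1.06 at ratios 50–100. Significance defaults
to Bonferroni across performed tests (the meta-analysis convention);
empirical FDR is available when a null pool is supplied.

## Simulation framework

Z panels are simulated directly on the summary-statistic scale:
`Z_null ~ N(0, Σ)` and `Z_alt ~ N(√n·β, Σ)` with point-normal effects —
round(γK) causal genes (minimum one when γ > 0) at uniform positions, each
β_k ~ N(0, σ_b²). The √n mean scaling is the score-statistic asymptotics of
a per-SNP effect at sample size n (σ_b² is the per-SNP trans genetic
variance on the standardised-genotype scale; 0.001 is a realistic per-SNP
trans heritability). Defaults mirror a realistic study: n = 500, γ = 0.3,
σ_b² = 0.001, 10,000 SNPs × 1,000 replicates, with a desk-scale preset of
2,000 SNPs × 100 replicates used throughout the test suite and acceptance
script. Power uses the same empirical-FDR machinery as the scan, against 10
matched null panels pooled within each replicate; comparators are PC1
(first-PC score only) and MinP (best per-gene p, Bonferroni by K). Identical
seeds give bit-identical power tables.

## Synthetic data

The generator provides (a) block-equicorrelated correlation matrices
(`make_block_sigma`) for planted-structure tests, (b) geometric-decay-
spectrum matrices in a random basis (`make_decay_sigma`), which emulate the
continuous eigenvalue profile of empirical module correlation matrices —
block equicorrelation has exactly degenerate retained eigenvalues, an
unidentifiable-basis edge case real modules do not exhibit, which matters
for any study of Σ-estimation noise — and (c) full cohorts: Hardy–Weinberg
binomial dosages (optionally AR(1)-correlated within chromosomes for LD
tests), expression `G·B + E` with multivariate-normal noise, deterministic
annotations and cross-mappability tables, and exact planted-truth records.
It does not emulate read-level artefacts (multimapping is represented only
through the gene-level mappability and cross-mappability inputs), count
overdispersion, or realistic LD panels — so passing tests demonstrate the
statistics under the model's assumptions, not robustness to alignment error
or population structure.

## Numerical and design notes

- Eigenvector signs are fixed (largest-magnitude loading positive, ties to
  the lowest gene index) so PC scores are reproducible; quadratic statistics
  are sign-invariant.
- Component p-values are clamped at 1e-300 with a logged warning; |Z| is
  capped at 37 (the two-sided-normal underflow point).
- Quantile normalisation equalises each sample's distribution to the mean
  quantile profile (average-rank ties); the per-gene inverse-normal step
  maps average ranks through Φ⁻¹((r − ½)/N). Re-applying the map preserves
  each gene's value multiset and each sample's sorted profile; individual
  assignments can flip at exact rank collisions, so strict idempotence holds
  only up to those ties.
- HWE uses the exact conditional test up to 1,000 hard calls (dosages
  rounded for HWE only) and the χ² approximation above.
- Module detection is average-linkage clustering on 1 − |r| with a 0.5 cut
  height and minimum module size 10; it is a deliberately plain stand-in for
  topological-overlap clustering, since module definitions are an
  exchangeable input (GMT import covers exact reproduction).
- The sumstats mode subsets the module-level Σ estimate after per-SNP gene
  exclusion rather than re-estimating Σ per SNP; per-subset recalibration is
  cached.

## Known limitations

- The omnibus tail below the calibration's resolution relies on the
  frozen-exceedance-ratio extrapolation (ranking is exact by monotonicity;
  absolute deep-tail p-values carry a few-percent systematic uncertainty,
  more beyond ~10 decades below the junction).
- The test does not report which module genes drive a signal; per-gene Z
  scores are exposed for exploratory follow-up.
- Mode agreement between individual-level and summary-statistics scans
  degrades when retained eigenvalues are closely spaced (the PC basis
  becomes ill-determined under Σ-estimation noise); the basis-free
  components (WI, Wald, VC) are unaffected.
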