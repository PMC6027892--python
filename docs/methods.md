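# Methods

## Model

The package fits the standard ridge / SNP-BLUP model

    y = W b + Z a + e,   a ~ N(0, I σa²),   e ~ N(0, I σe²),

with the variance components supplied by the user and treated as known
(as is common when they come from an earlier REML or pedigree analysis;
treating a point estimate as exact makes all downstream statistics
slightly optimistic, which is a property of the approach, not of this
implementation). `W` is an intercept plus optional user covariates and
must be full column rank; `Z` holds dosages centered by twice the allele
frequency (column mean). Genotypes are *not* scaled per marker: any
VanRaden-style scaling lives entirely in σa², keeping the prior
`I σa²` literal. Missing dosages are mean-imputed, i.e. exactly zero
after centering, which is neutral under the linear model. Monomorphic
markers are dropped before fitting but retain their place in the output
indexing, with the convention that their posterior equals the prior
(â = 0, Var = σa², zero covariance with everything): this makes the
EMMAX statistic 0 with p = 1 and the log10 BF 0 without special-casing
downstream.

Henderson's mixed-model equations

    [ W'W   W'Z      ] [b]   [W'y]
    [ Z'W   Z'Z + λI ] [a] = [Z'y],    λ = σe²/σa²,

are solved by a dense Cholesky factorization, and the posterior
covariance of the marker effects is the marker block of the inverse
coefficient matrix times σe²:  Caa = C^{aa} σe². The inversion is exact;
no sampling is involved anywhere in the statistics. This limits the
package to desk-scale panels (the coefficient matrix is
(k + m) × (k + m)); a few thousand markers fit comfortably in memory and
seconds of CPU, and sparse or iterative solvers for much larger panels
are deliberately out of scope.

Two conversions connect the fit to the quantities users typically have:

* heritability → variances: σu² = h²·Vp spread over markers gives
  σa² = σu² / (2 Σ p_j(1−p_j)), σe² = (1−h²)·Vp;
* GBLUP → SNP-BLUP: given genomic breeding values u, marker effects are
  recovered as â = σa² Z' G⁻ u with G = ZZ'σa². Because column-centering
  puts the ones vector in G's null space, the solve is least-squares and
  is exact precisely when u lies in the range of G (any u = Za does);
  inconsistent breeding values raise instead of being silently projected.

## Statistics

**EMMAX, single marker.** The frequentist variance of the BLUP estimator
is Var(â_i) = σa² − Var(a_i|y) (prior minus posterior); round-off can
make it infinitesimally negative, which is clamped to zero with a
warning and the marker reported as degenerate (p = 1). The test is
t = â_i/√Var(â_i), standard normal under the null, with **two-sided**
p-values (the GWAS convention; the null distribution itself has no
sidedness). This t is numerically identical to the fixed-regression
mixed-model (EMMAX) t with polygenic covariance V = ZZ'σa² + Iσe², which
the test suite verifies against an explicit GLS oracle.

**EMMAX, window.** x = â_w' Σ⁻¹ â_w with Σ = Iσa² − Caa_w, χ²(n) under
the joint null. Σ is diagonalized symmetrically (no explicit inverse);
it is declared singular when its smallest eigenvalue is below 1e−10 of
the largest, with an error suggesting a smaller window. Degenerate
markers inside a window are excluded and the degrees of freedom reduced,
with a warning. A window of size 1 delegates to the single-marker code
path so the reduction t² = x is exact.

**Bayes factors.** The Savage–Dickey density ratio: for markers S,

    BF = MVN(0 | 0, prior) / MVN(0 | â_S, Caa_S),

which equals the ratio of marginal likelihoods of the data with the
markers in versus out of the model. Note the denominator uses the
**posterior** covariance, not the frequentist variance of the EMMAX
test — the two differ and only the posterior gives the marginal-
likelihood identity (verified in the tests by brute-force MVN marginal
likelihoods at small n). All densities are computed in log10 via
Cholesky; the log-space path stays finite for posterior standard
deviations down to 1e−8 of the prior sd, where linear-space densities
(≈1e−21 already in the desk example) would underflow. Single-marker,
window and multi-trait BFs share one code path, so the reductions
(1 trait → window, size-1 window → single marker) are exact.

No BF rejection threshold is enforced — the thresholds proposed in the
literature disagree — but results carry Kass–Raftery labels on the log10
scale (<0 against; 0–0.5 barely worth mentioning; 0.5–1 substantial;
1–1.5 strong; 1.5–2 very strong; ≥2 decisive) and the constants
log10(3) ≈ 0.477 ("suggestive") and log10(150) ≈ 2.176 are exported.
(Jeffreys' verbal scale would label some of these differently; one
consistent scale is emitted.)

**Scans.** Windows slide with default stride 1, never span a chromosome
boundary, and are capped at 100 consecutive markers unless explicitly
overridden. One SNP-BLUP fit serves every window size and both
statistics. Bonferroni thresholds are −log10(α/n_tests).

## Synthetic data

The generator emulates a SNP-chip panel with block LD and a quantitative
trait with one major QTL:

* **Genotypes.** Two independent haplotypes per individual; within a
  block of `ld_block_size` consecutive markers the haplotype alleles
  share a latent Gaussian factor with correlation `within_block_corr`,
  thresholded at the marker's allele frequency (Gaussian copula). Blocks
  are independent, so LD is piecewise-constant rather than decaying —
  enough to induce the negative posterior correlations between
  neighboring estimates that the window statistics exercise, but not a
  model of recombination, demography or chip ascertainment. Allele
  frequencies are uniform on `maf_range`; positions sit on a regular
  grid.
* **Phenotypes.** y = μ + QTL + polygenic + residual. The QTL effect is
  specified in trait-sd units; the polygenic term spreads the remaining
  genetic variance over the other markers; the residual is rescaled
  empirically so the realized h² matches the target closely. The
  realized per-marker effect variance and residual variance are recorded
  in `SimTruth`, so recovery tests can fit with the *realized* variance
  components — the exactly-calibrated case.
* **Defaults.** 630 individuals and h² = 0.56 mirror a small horse
  breeding data set of the kind this methodology targets; 1000 markers,
  5-marker blocks with latent correlation 0.6 and MAF in (0.05, 0.5) are
  realistic chip-like choices at desk scale. A single integer seed
  drives everything; identical configurations are bit-identical.

Because the generator satisfies the SNP-BLUP model assumptions by
construction (normal effects, normal residuals, known variances),
passing calibration tests demonstrates internal correctness of the
statistics, not robustness to the model misspecification real data
carries (non-normal effects, structure, variance-component error).

## Validation choices and problem sizes

* Worked desk examples (prior 0.2, estimates (0.5, 0.4), posterior sd
  0.05 / covariance [[0.05, −0.02], [−0.02, 0.08]]) are asserted to the
  printed precision.
* Savage–Dickey and GLS equivalences are checked on 20 random small
  instances each (n ≤ 12, m ≤ 4 and n ≤ 30, m ≤ 8) at 1e−6 in log10 /
  on t.
* Null calibration uses 200 replicates of 300 × 200 with a polygenic
  background at h² = 0.56, fitting with realized components; the
  empirical 5%-level type-I error must land in (0.04, 0.06) and pooled
  p-values pass a KS uniformity test at 0.01.
* Localization power uses 50 replicates of 500 × 500 with a 1.0-sd QTL;
  the top single-marker hit and top 5-marker-window BF must fall in the
  QTL's LD block in ≥ 90% of replicates.

These sizes keep the whole suite under a minute on one CPU while giving
the stochastic checks comfortable margins.

## Known limitations

* Dense algebra only: no sparse/iterative solvers, no Single-Step
  (H-matrix) models, no variance-component estimation.
* The single-marker EMMAX p-value assumes the variance components are
  exact; uncertainty in them is not propagated.
* Window statistics are for sets of biallelic markers; they are not
  haplotype (multiallelic segment) models, which would require a
  separate fit per segment length.
* The Gaussian-copula LD model has no recombination map; distances in bp
  are decorative beyond chromosome assignment.
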