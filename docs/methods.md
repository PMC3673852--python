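# Methods

## Model

For probe *g* on array *i*, channel *c* ∈ {green, red}, the background
corrected, normalized log2 intensity is modelled as

y_gic = x_ic' β_g + b_gi + ε_gic,  b_gi ~ N(0, ρσ_g²),  ε_gic ~ N(0, (1−ρ)σ_g²),

with all spot effects b and residuals ε independent. The two channels of a
spot therefore share correlation ρ (the intra-spot correlation) and each
observation has marginal variance σ_g². ρ is assumed **common to all
genes**: it reflects the technical design of the arrays (shared spot
morphology, printing, local background), not gene biology, which is what
justifies pooling it genome-wide. Assumptions worth stating explicitly:
normality of log intensities, no missing values (enforced — a missing cell
is a hard error, never imputed), observations on different arrays
independent, and a gene-specific but array-constant variance σ_g².

The design matrix X (2n × p) stacks **all green rows for arrays 1..n, then
all red rows**. Any consistent ordering is statistically equivalent; this
one makes the M/A transformation matrices literal block operations
(C_M' = (−1,1)⊗I_n, C_A' = (½,½)⊗I_n). The default parameterization is one
indicator column per condition with no intercept, so coefficients are mean
log2 expressions per condition and every comparison is an explicit
contrast. An optional dye effect is a red-channel indicator column.

## M/A reparameterization

M_gi = y_gi2 − y_gi1 and A_gi = (y_gi2 + y_gi1)/2 are uncorrelated, with
var(M) = 2σ²(1−ρ) and var(A) = σ²(1+ρ)/2, so z_g = (M_g, A_g) follows an
independent two-stratum heteroscedastic regression E(z_g) = Zβ_g with
Z = (C_M C_A)'X. Note ½·log(4σ_A²/σ_M²) = atanh(ρ): the variance ratio
identifies ρ, including negative values that the variance-component form
cannot represent.

## Per-gene REML

With only two variance strata, the REML score equations reduce to a fixed
point, iterated from the pooled OLS residual mean square:

1. weighted least squares for β with weights 1/σ̂²_M (M rows), 1/σ̂²_A (A rows);
2. leverages h_i of the weighted projection;
3. σ̂²_s ← Σ_{i∈s} e_i² / Σ_{i∈s}(1 − h_i) for each stratum s.

At convergence the stratum score is exactly zero, so this *is* the REML
estimate (verified in tests against brute-force grid maximization of the
explicit residual likelihood). The effective degrees of freedom are the
leverage complements at the converged weights, d_M = Σ_{M rows}(1 − h_i)
and d_A likewise; they are fractional, satisfy d_M + d_A = 2n − rank(Z),
and calibrate the approximating scaled chi-square distributions of the
variance estimates. Numerical guards: tolerance 1e−5 on the relative change
of both variances, at most 40 iterations, a variance floor of 1e−10 × the
gene's mean squared scale (hitting it flags the gene unusable, e.g. an
all-constant gene), and a stratum residual-df floor of 1e−3 (a stratum
saturated by the design flags the gene unusable). Unusable genes are kept
in the gene-wise linear modelling but excluded from correlation pooling.

The d's are computed from each gene's own converged weights. An alternative
reading defines the hat matrix from the common-ρ rescaled design, which
gives identical d's only when the gene's variance ratio equals the common
one; the per-gene choice is self-contained and avoids a circular dependence
between ρ̂ and the d's.

## Pooling the correlation

Each usable gene yields τ̂_g = ½·log(4σ̂²_Ag/σ̂²_Mg), an estimate of
τ = atanh(ρ). From the chi-square log-moments
(E log σ̂² = log σ² + ψ(d/2) − log(d/2)),

bias(τ̂_g) = ½[(ψ(d_A/2) − log(d_A/2)) − (ψ(d_M/2) − log(d_M/2))],

which vanishes for d_M = d_A and is verified against Monte Carlo in the
tests. (Published variants of this correction differ in sign and scale
factor; the form above is the one that matches the simulated mean of τ̂_g,
and for near-balanced designs the difference is numerically negligible.)
The bias is applied per gene with that gene's own (d_M, d_A), then a
trimmed mean with 15% removed from each tail — robust to outlier genes —
gives τ̂ and ρ̂ = tanh(τ̂). The non-robust pooled estimator
½·log(4Σσ̂²_A/Σσ̂²_M) is exposed for diagnostics only and is left
uncorrected, as classically presented. ρ̂ is clamped to ±0.99 (logged)
because the rescaling divisors vanish as |ρ| → 1.

## Gene-wise inference

Treating ρ̂ as known (it averages thousands of genes), dividing the M rows
of data and design by √(2(1−ρ̂)) and the A rows by √((1+ρ̂)/2) — division,
the only direction that homoscedastizes — yields an ordinary linear model
per gene: β̂_g = (Z*'Z*)⁻¹Z*'z*_g, residual df d = 2n − rank(Z*) (the
number of observations is 2n, not n). This is algebraically identical to
GLS on the raw channels with the block correlation matrix (tested to
1e−10). The same rescaled design is shared by all genes.

The classic log-ratio analysis is OLS of the M-values on the difference
design (red row − green row). That design loses one rank per connected
island, so it is fitted by minimum-norm least squares with an explicit
row-space estimability check: a contrast crossing unconnected islands
raises an error rather than returning a meaningless number. For the paired
design the two analyses coincide in their point estimates exactly; the t
statistics differ slightly because the separate-channel residual variance
also pools A-stratum residuals.

Variance moderation follows the standard conjugate empirical Bayes scheme:
s̃_g² = (d₀s₀² + d·s_g²)/(d₀+d), with (d₀, s₀²) estimated by log-scale
moment matching (digamma/trigamma, Newton root-finding at tolerance 1e−8,
≤ 50 iterations; estimated d₀ above 1e6 is reported as infinite and
propagates to a normal reference distribution). Under the null,
t̃ = β̂/(s̃√v) is exactly t on d₀+d df — the central distributional
guarantee, tested by KS uniformity of null p-values. Multiple testing
defaults to Benjamini–Hochberg; a fixed-λ (λ = 0.5) Storey π₀ estimate is
reported alongside but does not rescale the q-values. (A spline-smoothed π₀
over a λ grid is deliberately out of scope, so π₀ values will differ
slightly from qvalue's.)

## Normalization

`normalize_m_loess` replaces each array's M-values by residuals from a
robust local-linear regression of M on A (span 0.3, 4 robustifying
iterations — conventional MA-normalization settings; the operation is
standard and is delegated to statsmodels' lowess). `normalize_a_quantile`
replaces each array's sorted A-values by the across-array mean of sorted
values; ties receive the mean of the means at their tied positions
(deterministic and symmetric). Operating on M and A rather than channels
keeps the M-values identical to the classic log-ratio pipeline — quantile
normalization of A provably leaves M untouched (tested). At least 10 spots
per array are required for the loess curve.

## Synthetic data

The generator draws σ_g² ~ s₀²d₀/χ²_{d₀}, then spot effects and residuals
per the model; for ρ < 0 (no variance-component representation) it draws
each spot's (M, A) pair directly from the implied bivariate normal — the
same distribution for ρ ≥ 0. Defaults describe a realistic two-treatment
common reference experiment: n = 8 arrays, ρ = 0.85, d₀ = 4, s₀² = 0.25 on
the log2 scale, 10% DE genes at ±1 log2-fold-change with random signs,
baseline expression uniform on [6, 14] log2 units (a typical microarray
intensity range; a package default, not an empirical estimate). Layout
generators cover common reference, paired, dye-swap pairs, loop, and the
two-island unconnected design. Everything is reproducible bit-for-bit from
the seed.

What the simulator does **not** emulate: intensity-dependent dye bias,
spatial artefacts, background noise, or any normalization-violating trend —
normalization tests use purpose-built fixtures instead. Passing tests on
simulated data therefore validate the statistical machinery under the
model's own assumptions; they do not certify behaviour on raw scanner
output, where background correction and normalization quality dominate.

## Problem sizes and verification

The test suite checks, among others: exact GLS equivalence across 50 random
designs; correlation recovery |ρ̂ − ρ| ≤ 0.02 at G = 5000, n = 8 for
ρ ∈ {−0.3, 0.5, 0.85}; variance-prior recovery (d̂₀ within 20%, ŝ₀² within
5% at G = 10⁴); KS-uniform null p-values at G = 5000; separate-channel ≥
log-ratio BH-0.05 discoveries in ≥ 18 of 20 replicates at ρ = 0.65, 20% DE,
G = 2000; REML fixed point vs grid search to |Δlog σ²| < 1e−3 on 25
instances; and a cross-check of ρ̂, (d̂₀, ŝ₀²) and the moderated t values
against the reference Bioconductor implementation on a 400-gene simulation.
These sizes keep the whole suite around ten seconds while leaving
Monte-Carlo margins at 3 standard errors.

## Known limitations

- A single common ρ is assumed; gene-wise or spot-quality-weighted
  correlations are out of scope.
- No within-array duplicate-spot pooling, print-tip loess, or background
  correction; inputs are expected background-corrected and positive.
- The paired-design t statistics from the two analyses are close but not
  identical (shared point estimate, different residual pooling).
- Negative ρ̂ is permitted by the estimator and the simulator, but the
  generative variance-component interpretation only covers ρ ≥ 0.
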