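# sepchan

Separate-channel differential expression analysis for two-colour
microarrays, using a **common intra-spot correlation**.

## The problem

Two-colour (two-channel) microarrays competitively hybridize two RNA
samples, labelled green (Cy3) and red (Cy5), to the same array. The
traditional analysis works on the per-spot log-ratios

M<sub>gi</sub> = y<sub>gi2</sub> − y<sub>gi1</sub>

and discards the spot means

A<sub>gi</sub> = (y<sub>gi2</sub> + y<sub>gi1</sub>)/2,

where y<sub>gic</sub> is the log2 intensity of probe *g*, array *i*,
channel *c*. The two channel intensities of one physical spot are strongly
correlated (they share everything local to that spot), with intra-spot
correlation ρ. M and A are *independent* contrasts of the two correlated
observations, with

var(M) = 2σ²(1−ρ),  var(A) = σ²(1+ρ)/2,

so the A-values carry real information about treatment differences that the
log-ratio analysis throws away — all of it, for comparisons between
"unconnected" treatments that never share an array. `sepchan` recovers that
information.

## The method

The per-gene model for the stacked channel observations is
E(y_g) = Xβ_g with a block correlation structure linking the two channels
of each spot. Reparameterized to z_g = (M_g, A_g), this becomes an
independent two-stratum heteroscedastic regression E(z_g) = Zβ_g with
variances σ²<sub>Mg</sub> and σ²<sub>Ag</sub>. The pipeline is:

1. **Per-gene REML.** A fixed-point algorithm estimates
   (σ̂²<sub>Mg</sub>, σ̂²<sub>Ag</sub>) per gene, together with fractional
   effective degrees of freedom d<sub>Mg</sub>, d<sub>Ag</sub> from the
   leverages of the weighted fit.
2. **Common correlation.** Because 4σ²<sub>A</sub>/σ²<sub>M</sub> =
   (1+ρ)/(1−ρ), each gene gives τ̂_g = ½·log(4σ̂²<sub>Ag</sub>/σ̂²<sub>Mg</sub>),
   an estimate of τ = atanh(ρ). After a digamma bias correction these are
   pooled by a 15%-trimmed mean; ρ̂ = tanh(τ̂) is extremely precise because
   it averages over all genes.
3. **Rescale to ordinary least squares.** Treating ρ̂ as known, dividing the
   M rows by √(2(1−ρ̂)) and the A rows by √((1+ρ̂)/2) makes the model
   homoscedastic, so each gene is fitted by OLS — exactly equivalent to GLS
   on the raw channels.
4. **Empirical Bayes moderation.** Gene variances get a scaled
   inverse-chi-square prior with hyperparameters (d₀, s₀²) estimated from
   all genes; moderated t statistics t̃ = β̂/(s̃√v) follow an exact t
   distribution on d₀ + d df under the null. BH false discovery rates and a
   fixed-λ Storey π₀ estimate are reported.

Closed-form efficiency results quantify what the A-values buy: for a common
reference design the extra information is (1−ρ)/(1+ρ) (8% at ρ = 0.85, 21%
at ρ = 0.65); the log-ratio analysis of a common reference design beats a
one-channel design iff ρ > 0.5; and a cross-island contrast in an
unconnected design has relative efficiency 1−ρ versus a direct one.

## Worked example

```python
from sepchan import SimConfig, simulate_two_channel, SeparateChannelModel

y, targets, truth = simulate_two_channel(
    SimConfig(G=5000, n_arrays=8, rho=0.85, d0=4, s0_2=0.25,
              prop_de=0.1, lfc=1.0, seed=1))
model = SeparateChannelModel(y, targets, contrasts=["BvsC = B - C"])
res = model.fit()
print(res.summary())
```

```
Separate-channel linear model (common intra-spot correlation)
=============================================================
Probes: 5000    Arrays: 8
Intra-spot correlation rho = 0.8481 (estimated)
  pooled from 5000 genes, trim 15%, tau = 1.2492
Residual df per gene: 13
Variance prior: d0 = 3.922, s0^2 = 0.2497; moderated t on 16.9222 df
    contrast  #q<0.05  #q<0.01    pi0
        BvsC      431      323   0.91
```

The simulated truth had ρ = 0.85, d₀ = 4, s₀² = 0.25 and 10% DE genes at
one log2-fold-change: the pipeline recovers ρ̂ = 0.848 and the variance
prior almost exactly, and calls 431 genes at BH 0.05. The same data
analysed by log-ratios only (`model.fit(method="log_ratio")`) yields 397
discoveries — the A-values buy extra power. The ranked gene list:

```python
print(res.top_table(coef="BvsC", n=5).to_string(index=False))
```

```
   probe     logFC          t            p        q
gene1631 -1.126067 -10.167775 1.267944e-08 0.000039
gene3242  1.208383   9.412386 3.886710e-08 0.000039
gene1135  0.990806   9.208363 5.317327e-08 0.000039
gene4624  1.052697   8.957615 7.867606e-08 0.000039
gene1699 -1.164594  -8.942848 8.053093e-08 0.000039
```

`logFC` is the estimated B−C log2-fold-change; all five are true DE genes
with |logFC| ≈ 1.

A `sepchan` command-line tool wraps the same pipeline
(`sepchan simulate`, `sepchan correlation`, `sepchan fit`,
`sepchan toptable`, `sepchan normalize`, `sepchan efficiency`); run
`sepchan --help`.

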