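# twosample-mr

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
for studies of the kind that ask whether circulating biomarkers (e.g.
inflammatory markers such as hsCRP, IL-6, ESR, MCP-1) causally affect a
downstream trait (e.g. bone mineral density at several skeletal sites),
using only published per-SNP association tables from separate exposure and
outcome consortia.

It is a library for epidemiologists and statistical geneticists who want
the whole workflow as tested, composable functions: instrument
construction, allele harmonization, the standard estimator suite, a
synthetic summary-statistic generator with known ground truth, and a
pipeline that turns input files plus a config into a publication-shaped
report table with a full per-SNP audit trail.

## The model

Genetic variants are used as instrumental variables. For SNP *j*, let
γ̂*ⱼ* (SE σ*γⱼ*) be its estimated effect on the exposure in one sample and
Γ̂*ⱼ* (SE σ*Γⱼ*) its estimated effect on the outcome in an independent
sample. Under a linear causal effect θ and valid instruments,
Γ*ⱼ* = θ γ*ⱼ*, so each SNP supplies a Wald ratio
β̂*ⱼ* = Γ̂*ⱼ*/γ̂*ⱼ* with first-order SE σ*Γⱼ*/|γ̂*ⱼ*|. The suite combines
them as:

- **IVW** — inverse-variance-weighted mean of the ratios;
  fixed-effects SE = (Σ*wⱼ*)^(−1/2), or multiplicative random-effects SE
  inflated by the residual dispersion φ (floored at 1); the `auto` rule
  uses fixed effects for ≤3 SNPs, random for ≥4.
- **IVW with correlated instruments** — generalized least squares of Γ̂ on
  γ̂ through the origin with covariance Ω*ⱼₖ* = σ*Γⱼ* σ*Γₖ* ρ*ⱼₖ* built
  from the signed LD matrix ρ.
- **Weighted median** — the weight-interpolated 50th percentile of the
  ordered ratios; consistent while valid instruments carry >50% of the
  weight; SE by parametric bootstrap.
- **MR-Egger** — weighted regression Γ̂*ⱼ* = β₀ + θ γ̂*ⱼ* after orienting
  all γ̂*ⱼ* ≥ 0; β₀ estimates average directional pleiotropy (its p-value
  is the pleiotropy test, valid under the InSIDE assumption), and the
  slope remains a causal estimate even with invalid instruments.

Instrument QC follows the standard recipe: greedy LD pruning at r² ≥ 0.8
keeping smallest p-values, proxy substitution (r² ≥ 0.8) for SNPs missing
from the outcome GWAS, optional exclusion of SNPs flagged as pleiotropic,
and per-SNP strength reporting via R² = 2p(1−p)β² and
F = R²(n−2)/(1−R²) for a variance-standardized exposure.

## Worked example

`examples/01_simulate_and_estimate.py` simulates a study with 20 valid
instruments, two samples of 50 000, and a true causal effect of 0.3, then
runs the suite:

```
true causal effect: 0.3
instruments: 20

IVW       beta= 0.2980  se=0.0091  95% CI [ 0.2802,  0.3158]  p=4.08e-236
WM        beta= 0.2918  se=0.0127  95% CI [ 0.2670,  0.3167]  p=5.07e-117
MR-Egger  beta= 0.3136  se=0.0224  95% CI [ 0.2665,  0.3606]  p=4.06e-11  intercept=-0.0030 (p=0.46)
```

All three estimators recover θ = 0.3 within sampling error; the MR-Egger
intercept is indistinguishable from zero because no directional pleiotropy
was simulated. The other examples cover allele harmonization
(`02`), instrument QC (`03`), the multi-outcome pipeline with NA semantics
for infeasible estimators (`04`), and LD-aware GLS estimation (`05`).

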