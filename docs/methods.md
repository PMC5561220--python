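# Methods

## Scope and model

The package implements summary-data two-sample Mendelian randomization: the
SNP–exposure associations (γ̂ⱼ, σγⱼ) and SNP–outcome associations
(Γ̂ⱼ, σΓⱼ) come from independent samples, and the causal effect θ of the
exposure on the outcome is identified under the usual instrumental-variable
assumptions (relevance, independence from confounders, exclusion
restriction). All estimators operate on the harmonized per-SNP pairs; no
individual-level data are touched.

## Harmonization

Published effect alleles need not agree between consortia, so every shared
SNP is re-expressed on the exposure table's effect allele: identical allele
pairs are kept, swapped pairs flip the sign of the outcome beta and mirror
its allele frequency, and strand-complement reports are complemented before
matching. Palindromic (A/T, C/G) SNPs cannot be oriented from allele labels
alone; the default policy orients them so the effect-allele frequencies
agree across samples and excludes them as ambiguous when both frequencies
lie within 0.08 of 0.5. The window of 0.08 is a deliberate default for the
common situation where per-study strand information is unavailable;
`drop` (always exclude) and `keep` (trust the published orientation)
are available when the user knows more. Irreconcilable allele pairs (e.g.
A/C vs A/G) exclude the SNP with a recorded reason rather than aborting the
analysis. The allele-flip transform is involutive up to floating-point
round-off in `1 − eaf`.

Allele frequency and sample size are optional fields; the operations that
need them (frequency-policy palindromes, F-statistics) raise a targeted
error when they are missing instead of guessing. rsID matching is exact
string equality — genomic coordinates, liftover, and reference-genome
strand inference are out of scope.

## Instrument construction

- **LD pruning** is greedy: SNPs are visited in ascending p-value order
  (ties broken lexicographically by rsid, making the procedure
  deterministic) and kept when their squared correlation with every
  already-kept SNP is below the threshold (default r² = 0.8). The output
  is maximal: every discarded SNP conflicts with a kept one.
- **Proxy substitution** replaces an instrument absent from the outcome
  dataset by its highest-r² available proxy at r² ≥ 0.8, ties broken by
  rsid. The proxy table carries only (original, proxy, r²); the
  substituted record keeps the original's exposure beta and SE under the
  proxy's rsid, and the proxy's own published outcome association is used
  at harmonization. This mirrors direct substitution without r²-based
  attenuation correction; users holding the proxy's own exposure statistics
  can simply put them in the exposure table instead.
- **Pleiotropy exclusion** removes SNPs named by rsid or carrying a flagged
  phenotype label (the flags file stands in for a manual annotation
  search). The pipeline always runs both variants — all SNPs and
  flagged-excluded — so the sensitivity analysis is never forgotten; with
  an empty exclusion set the variants coincide exactly.
- **F-statistics** use R² = 2·eaf·(1−eaf)·β² and F = R²(n−2)/(1−R²),
  which assume a variance-standardized exposure. If the published betas are
  unstandardized they must be divided by the trait SD first; this is
  documented on the function and deliberately not guessed. F < 10 flags a
  weak instrument.

## Estimators

- **Wald ratio**: β̂ⱼ = Γ̂ⱼ/γ̂ⱼ, SE = σΓⱼ/|γ̂ⱼ| — the first-order
  delta-method SE, ignoring uncertainty in the (strong) instrument's
  exposure effect. γ̂ⱼ = 0 is a hard error naming the SNP.
- **IVW**: precision-weighted mean with wⱼ = SEⱼ⁻². The random-effects
  variant is multiplicative: SE × max(1, φ) with
  φ² = Σwⱼ(β̂ⱼ−θ̂)²/(J−1). The floor at 1 means random effects can never
  claim more precision than fixed effects; the `auto` rule (fixed for J ≤ 3,
  random for J ≥ 4) reflects that dispersion cannot be usefully estimated
  from three ratios. The rule is re-applied per analysis variant, so a
  pleiotropy-excluded set that drops to 3 SNPs switches to fixed effects.
- **GLS for correlated instruments**: origin-constrained generalized
  weighted regression with Ω = D ρ D, D = diag(σΓ). Solved by Cholesky
  factorization; if the condition number exceeds 1e12 a 1e-10 ridge is
  added to the diagonal and logged; a covariance that is still not positive
  definite is an error. An intercept-free fit is the default; an Egger-style
  intercept with LD weighting is available through `mr_egger` on a set with
  an LD matrix attached (experimental).
- **Weighted median**: ratios ordered ascending, weights normalized,
  cumulative midpoints sⱼ = Σₖ≤ⱼ w′ₖ − w′ⱼ/2, estimate interpolated
  linearly at s = 0.5. The SE is a parametric bootstrap (default 2000
  replicates) redrawing γ̂ⱼ and Γ̂ⱼ from normals at the observed values
  with the reported SEs; a seed is mandatory, making results reproducible.
  Correlated instruments are rejected with a hard error — the weighted
  median has no accepted LD-aware form.
- **MR-Egger**: SNPs oriented to γ̂ⱼ ≥ 0 (flipping both effects), then
  weighted regression with intercept, weights σΓⱼ⁻², multiplicative
  residual scaling floored at 1, and t(J−2) reference for p-values and
  CIs. IVW and WM use the normal reference and ±1.96·SE intervals; the t
  reference for Egger reflects its two estimated parameters from few SNPs.
  These reference choices, and the Egger t-based CI, are package
  conventions where the field's software differs.
- Feasibility: WM and MR-Egger require more than two SNPs. In the pipeline
  an infeasible estimator produces an NA row carrying the reason, keeping
  the report's shape fixed.

## Synthetic data generator

The generator emulates the sampling structure of two-sample summary
statistics, not genotypes. For SNP j: eafⱼ ~ U(0.1, 0.5),
γⱼ ~ U(0.05, 0.3), and for a variance-standardized trait estimated in n
individuals the effect-estimate SE is 1/√(2·eafⱼ(1−eafⱼ)·n) — so
F-statistics scale realistically with n. True outcome effects are
Γⱼ = θγⱼ + αⱼ with αⱼ drawn per the pleiotropy law: none, balanced
(mean 0), or directional (mean μα), optionally restricted to a fraction of
SNPs. αⱼ is independent of γⱼ (InSIDE holds) unless an explicit
`inside_violation` correlation is set. Observed effects add normal noise
with the stated SEs; within configured LD blocks the noise is correlated
through the Cholesky factor of the block correlation, independently in the
two samples (shared subjects within a sample, none across). Reported
p-values are two-sided normal. Everything is deterministic given the seed,
to the byte in the written files.

Default study conditions (20 SNPs, both samples 50 000, γ and eaf laws
above) were chosen to resemble a well-powered biomarker GWAS applied to a
large outcome consortium: per-SNP F-statistics fall in the hundreds,
matching the strong-instrument regime the estimators assume. What the
generator does **not** emulate: winner's curse from significance selection,
allele-frequency differences between samples, population stratification,
strand mislabeling, or palindromic alleles (simulated pairs are always
unambiguous). Tests passing on this generator therefore validate the
estimators and plumbing under a correctly specified sampling model, not
robustness to those real-data pathologies.

Named scenarios freeze the study designs used by the validation bench:
`null` (θ=0), `causal` (θ=0.3), `balanced`, `directional` (μα=0.05,
τ=0.01), `thirty-percent-invalid` (6 of 20 SNPs directional),
`correlated-blocks` (blocks of 5 at r 0.6 and 0.4), and `paper-shaped`
(one exposure against three outcome tables, θ=0).

## Pipeline

`run_analysis` is a pure function of (input files, config, seed): prune →
proxy → harmonize → both analysis variants → every requested method, per
exposure × outcome, with one report row per cell and a per-SNP audit log
(pruned / proxied / dropped / harmonization-excluded / pleiotropy-excluded
/ used, each with a reason). The significance threshold defaults to
0.05 / number-of-exposures — the Bonferroni-style rule that yields 0.0125
for a four-marker study — and is recomputed from the config rather than
hard-coded. Funnel data (ratio vs precision) and scatter data (per-SNP
points with 95% error bars plus per-method fitted lines, intercept 0 for
IVW/WM) are exported as plain tables; rendering plots from them is left to
the user's plotting stack.

## Validation bench and problem sizes

`twosample_mr.benchmarks` backs both the acceptance tests and
`scripts/acceptance.py`, so every claimed number is recomputed on demand:
GLS/IVW equivalence on 100 random instances; the closed-form two-ratio IVW
(θ̂ = 0.6, SE = 125^−1/2); parameter recovery over 500 replicate causal
studies; type-I error over 2000 null replicates; weighted-median vs IVW
bias over 500 thirty-percent-invalid replicates; and Egger intercept
recovery over 500 directional replicates. These replicate counts keep
Monte-Carlo error well inside the asserted tolerances (e.g. recovery means
are estimated to ≈0.001) while the whole bench completes in seconds.
Inside the bench the weighted median uses 100 bootstrap replicates — its
point estimate, the only quantity the bench aggregates, does not depend on
the bootstrap at all.

The type-I calibration check uses the fixed-effects IVW test, which is
exact under the no-heterogeneity null; the multiplicative random-effects
test is conservative by construction (its inflation is floored at 1, so it
can only lose rejections), and its rate is reported alongside and checked
against the same upper bound.

## Known limitations

- No MR-PRESSO, mode-based estimators, multivariable MR, Steiger filtering,
  or individual-level two-stage least squares.
- No automated LD lookup or annotation queries: the LD matrix, proxy table
  and pleiotropy flags are user-supplied files, and the LD matrix must
  contain signed r (tools reporting r² leave the sign to the user).
- The F-statistic formula assumes a standardized exposure; applying it to
  unstandardized betas overstates instrument strength.
- The weighted median's bootstrap SE ignores any correlation between
  instruments, consistent with its independence requirement.
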