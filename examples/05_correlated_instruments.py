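"""Account for linkage disequilibrium between instruments with GLS.

Simulates a study whose 20 instruments include two LD blocks (within-block
r of 0.6 and 0.4). Treating correlated SNPs as independent overstates the
information: the naive fixed-effects IVW standard error is too small. The
GLS estimator weights by the full covariance built from the signed LD
matrix and restores an honest standard error.
"""

from twosample_mr import ivw, ivw_correlated, scenario, simulate_two_sample

study = simulate_two_sample(scenario("correlated-blocks", seed=3))
h = study.harmonized()

naive = ivw(h, effects_model="fixed")
gls = ivw_correlated(h.with_ld(study.ld))

print(f"true causal effect: {study.truth.theta}")
print(f"naive IVW (ignores LD):  beta={naive.beta:.4f}  se={naive.se:.4f}")
print(f"GLS IVW (uses LD):       beta={gls.beta:.4f}  se={gls.se:.4f}")
print(
    f"\nSE ratio GLS/naive = {gls.se / naive.se:.2f}: correlated instruments "
    "carry less independent information than their count suggests."
)
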