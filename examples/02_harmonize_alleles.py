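"""Harmonize exposure and outcome summary statistics onto one effect allele.

Builds a tiny exposure table and an outcome table whose rows exhibit the
four situations a harmonizer must resolve: matching alleles, swapped
alleles (sign flip), a strand-complement report, and an ambiguous
palindromic SNP with allele frequency near 0.5 (excluded under the default
frequency policy).
"""

from twosample_mr import SnpAssociation, SummaryTable, harmonize


def snp(rsid, ea, oa, beta, eaf):
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa,
        beta=beta, se=0.02, pvalue=1e-10, eaf=eaf,
    )


exposure = SummaryTable(
    "crp",
    (
        snp("rs1", "A", "G", 0.20, 0.30),   # outcome reports same alleles
        snp("rs2", "C", "T", 0.15, 0.40),   # outcome reports swapped alleles
        snp("rs3", "A", "G", 0.12, 0.25),   # outcome reports opposite strand
        snp("rs4", "A", "T", 0.10, 0.49),   # palindrome, eaf ~ 0.5
    ),
)
outcome = SummaryTable(
    "bmd",
    (
        snp("rs1", "A", "G", 0.05, 0.30),
        snp("rs2", "T", "C", 0.04, 0.60),   # swapped: beta must flip to -0.04
        snp("rs3", "T", "C", 0.03, 0.25),   # T/C is A/G on the other strand
        snp("rs4", "A", "T", 0.02, 0.51),
    ),
)

h = harmonize(exposure, outcome, palindrome_policy="frequency", eaf_window=0.08)

print("harmonized SNPs (gamma = exposure effect, Gamma = outcome effect):")
print(h.to_frame().to_string(index=False))
print("\nexcluded:")
for rsid, reason in h.exclusions:
    print(f"  {rsid}: {reason}")
print(
    "\nrs2's outcome effect was sign-flipped to match the exposure's effect "
    "allele; rs4 was dropped because a near-0.5 frequency cannot orient an "
    "A/T SNP."
)
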