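"""Instrument quality control: LD pruning, proxies, flags, F-statistics.

Starts from four correlated candidate instruments, prunes at r2 >= 0.8
keeping the smallest p-values, substitutes a proxy for a SNP missing from
the outcome GWAS, drops one SNP flagged as pleiotropic, and reports each
survivor's variance explained and F-statistic (values above 10 indicate
little weak-instrument bias).
"""

import numpy as np

from twosample_mr import (
    LdMatrix,
    PleiotropyFlags,
    ProxyRow,
    ProxyTable,
    SnpAssociation,
    SummaryTable,
    apply_proxies,
    exclude_flagged,
    ld_prune,
    strength_report,
)


def snp(rsid, beta, p):
    return SnpAssociation(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta=beta, se=0.01, pvalue=p, eaf=0.3, n=200_000,
    )


table = SummaryTable(
    "crp",
    (snp("rs1", 0.20, 1e-40), snp("rs2", 0.18, 1e-35),
     snp("rs3", 0.10, 1e-15), snp("rs4", 0.08, 1e-9)),
)
# rs1 and rs2 are near-duplicates (r = 0.95); the rest are independent
r = np.eye(4)
r[0, 1] = r[1, 0] = 0.95
ld = LdMatrix(table.rsids, r)

pruned = ld_prune(table, ld, r2_threshold=0.8)
print(f"after LD pruning: {pruned.rsids}  (rs2 dropped, r2=0.90 with rs1)")

# rs3 is absent from the outcome GWAS but has a good proxy
available = {"rs1", "rs4", "rs3_proxy"}
proxies = ProxyTable((ProxyRow("rs3", "rs3_proxy", 0.95),))
proxied, log = apply_proxies(pruned, available, proxies)
print(f"after proxy substitution: {proxied.rsids}")

flags = PleiotropyFlags({"rs4": ["obesity"]})
reduced = exclude_flagged(proxied, flags, exclude=["obesity"])
print(f"after pleiotropy exclusion: {reduced.rsids}\n")

print(strength_report(proxied).to_string(index=False))
print("\nR2 is the variance of the (standardized) exposure explained per SNP;"
      "\nF >= 10 means the instrument is strong enough for two-sample MR.")
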