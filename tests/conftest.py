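import numpy as np
import pytest

from twosample_mr import HarmonizedSet, SnpAssociation, SummaryTable


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def make_assoc(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-9, eaf=0.3, n=50_000):
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pvalue=p, eaf=eaf, n=n,
    )


def random_harmonized(rng, n_snps=8, ld=None):
    """A well-conditioned harmonized set with strong instruments."""
    gamma = rng.uniform(0.05, 0.3, n_snps) * rng.choice([-1, 1], n_snps)
    se_gamma = rng.uniform(0.005, 0.02, n_snps)
    se_Gamma = rng.uniform(0.005, 0.02, n_snps)
    Gamma = 0.3 * gamma + rng.normal(0, se_Gamma)
    return HarmonizedSet(
        tuple(f"rs{i + 1}" for i in range(n_snps)),
        gamma, se_gamma, Gamma, se_Gamma, ld=ld,
    )


@pytest.fixture
def three_snp_exposure():
    return SummaryTable(
        "crp",
        (
            make_assoc("rs1", "A", "G", beta=0.20, se=0.01, p=1e-30, eaf=0.30),
            make_assoc("rs2", "C", "T", beta=0.15, se=0.01, p=1e-20, eaf=0.40),
            make_assoc("rs3", "G", "T", beta=0.10, se=0.01, p=1e-12, eaf=0.25),
        ),
    )
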