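"""Summary-statistic containers, file I/O, and allele harmonization."""

import numpy as np
import pytest

from twosample_mr import (
    ConfigurationError,
    EmptyInstrumentSetError,
    HarmonizationError,
    LdMatrix,
    SnpAssociation,
    SummaryTable,
    ValidationError,
    harmonize,
    read_ld_matrix,
    read_summary_table,
    write_ld_matrix,
    write_summary_table,
)
from conftest import make_assoc

HEADER = "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn"


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestSnpAssociation:
    def test_alleles_uppercased_and_validated(self):
        a = SnpAssociation("rs1", "a", "g", beta=0.1, se=0.01, pvalue=0.5)
        assert (a.effect_allele, a.other_allele) == ("A", "G")
        with pytest.raises(ValidationError):
            SnpAssociation("rs1", "A", "A", beta=0.1, se=0.01, pvalue=0.5)
        with pytest.raises(ValidationError):
            SnpAssociation("rs1", "A", "N", beta=0.1, se=0.01, pvalue=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"pvalue": 0.0},
            {"pvalue": 1.5},
            {"eaf": -0.1},
            {"eaf": 1.1},
            {"n": 0},
        ],
    )
    def test_invariant_violations(self, kwargs):
        base = dict(rsid="rs1", effect_allele="A", other_allele="G",
                    beta=0.1, se=0.01, pvalue=0.5, eaf=0.3, n=100)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            SnpAssociation(**base)

    def test_palindromic_detection(self):
        assert make_assoc(ea="A", oa="T").is_palindromic
        assert make_assoc(ea="C", oa="G").is_palindromic
        assert not make_assoc(ea="A", oa="G").is_palindromic

    def test_flip_is_involution(self):
        a = make_assoc(beta=0.2, eaf=0.3)
        back = a.flipped().flipped()
        assert (back.effect_allele, back.other_allele) == ("A", "G")
        assert back.beta == a.beta
        assert back.eaf == pytest.approx(a.eaf, abs=1e-15)
        assert a.flipped().beta == -a.beta
        assert a.flipped().eaf == pytest.approx(0.7)
        # an eaf representable exactly round-trips exactly
        b = make_assoc(beta=0.2, eaf=0.25)
        assert b.flipped().flipped() == b


class TestSummaryTableIO:
    def test_read_well_formed_file(self, tmp_path):
        path = write_lines(
            tmp_path / "crp.tsv",
            [
                HEADER,
                "rs1\tA\tG\t0.3\t0.2\t0.01\t1e-30\t10000",
                "rs2\tc\tt\tNA\t-0.1\t0.02\t1e-10\tNA",
                "rs3\tG\tT\t0.25\t0.1\t0.01\t1e-12\t10000",
            ],
        )
        table = read_summary_table(path)
        assert len(table) == 3
        assert table.get("rs2").effect_allele == "C"
        assert table.get("rs2").eaf is None and table.get("rs2").n is None

    def test_duplicate_rsid_named_in_error(self, tmp_path):
        path = write_lines(
            tmp_path / "dup.tsv",
            [HEADER,
             "rs123\tA\tG\t0.3\t0.2\t0.01\t1e-30\t10000",
             "rs123\tA\tG\t0.3\t0.2\t0.01\t1e-30\t10000"],
        )
        with pytest.raises(ValidationError, match="rs123"):
            read_summary_table(path)

    def test_zero_se_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "bad.tsv",
            [HEADER, "rs1\tA\tG\t0.3\t0.2\t0\t1e-30\t10000"],
        )
        with pytest.raises(ValidationError, match="se"):
            read_summary_table(path)

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        path = write_lines(
            tmp_path / "odd.tsv",
            ["snp\tA1\tA2\tfreq\tb\tstderr\tp\tN",
             "rs1\tA\tG\t0.3\t0.2\t0.01\t1e-30\t10000"],
        )
        with pytest.raises(ConfigurationError, match="not found"):
            read_summary_table(path, column_map={"rsid": "snp", "beta": "missing"})

    def test_column_map_renames(self, tmp_path):
        path = write_lines(
            tmp_path / "odd.tsv",
            ["snp\tA1\tA2\tfreq\tb\tstderr\tp\tN",
             "rs1\tA\tG\t0.3\t0.2\t0.01\t1e-30\t10000"],
        )
        table = read_summary_table(
            path,
            column_map={
                "rsid": "snp", "effect_allele": "A1", "other_allele": "A2",
                "eaf": "freq", "beta": "b", "se": "stderr", "pvalue": "p", "n": "N",
            },
        )
        assert table.get("rs1").beta == 0.2

    def test_round_trip_preserves_numerics_exactly(self, tmp_path, rng):
        assocs = tuple(
            make_assoc(
                rsid=f"rs{i}",
                beta=float(rng.normal()),
                se=float(rng.uniform(1e-6, 1)),
                p=float(rng.uniform(1e-300, 1)),
                eaf=None if i % 3 == 0 else float(rng.uniform()),
                n=None if i % 4 == 0 else int(rng.integers(10, 10**7)),
            )
            for i in range(25)
        )
        table = SummaryTable("t", assocs)
        path = tmp_path / "rt.tsv"
        write_summary_table(table, path)
        back = read_summary_table(path, trait_name="t")
        assert back == table


class TestLdMatrix:
    def test_identity_round_trip(self, tmp_path):
        ld = LdMatrix.identity(("rs1", "rs2"))
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.rsids == ("rs1", "rs2")
        np.testing.assert_array_equal(back.r, np.eye(2))

    def test_entry_above_one_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "ld.tsv",
            ["rsid\trs1\trs2", "rs1\t1.0\t1.2", "rs2\t1.2\t1.0"],
        )
        with pytest.raises(ValidationError, match=r"\[-1, 1\]"):
            read_ld_matrix(path)

    def test_symmetric_offdiagonal_accepted(self, tmp_path):
        path = write_lines(
            tmp_path / "ld.tsv",
            ["rsid\trs1\trs2", "rs1\t1.0\t0.9", "rs2\t0.9\t1.0"],
        )
        ld = read_ld_matrix(path)
        assert ld.r[0, 1] == 0.9 == ld.r[1, 0]

    def test_tiny_asymmetry_averaged_larger_rejected(self):
        r = np.array([[1.0, 0.5 + 4e-11], [0.5, 1.0]])
        ld = LdMatrix(("rs1", "rs2"), r)
        assert ld.r[0, 1] == ld.r[1, 0]
        with pytest.raises(ValidationError, match="asymmetry"):
            LdMatrix(("rs1", "rs2"), np.array([[1.0, 0.6], [0.5, 1.0]]))

    def test_non_unit_diagonal_and_non_psd_rejected(self):
        with pytest.raises(ValidationError, match="diagonal"):
            LdMatrix(("rs1", "rs2"), np.array([[1.0, 0.0], [0.0, 0.9]]))
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValidationError, match="semi-definite"):
            LdMatrix(("rs1", "rs2", "rs3"), bad)

    def test_subset_reorders(self):
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        ld = LdMatrix(("rs1", "rs2", "rs3"), r)
        sub = ld.subset(("rs3", "rs1"))
        assert sub.rsids == ("rs3", "rs1")
        assert sub.r[0, 1] == 0.2


class TestHarmonize:
    def exposure(self, **kw):
        return SummaryTable("exp", (make_assoc("rs1", "A", "G", beta=0.1, **kw),))

    def test_identical_alleles_kept(self):
        out = SummaryTable("out", (make_assoc("rs1", "A", "G", beta=0.05),))
        h = harmonize(self.exposure(), out)
        assert h.gamma[0] == 0.1 and h.Gamma[0] == 0.05

    def test_swapped_alleles_sign_flip(self):
        out = SummaryTable("out", (make_assoc("rs1", "G", "A", beta=0.05, eaf=0.7),))
        h = harmonize(self.exposure(), out)
        assert h.Gamma[0] == -0.05

    def test_strand_complement_matched(self):
        # exposure A/G; outcome reported on the opposite strand as T/C
        out = SummaryTable("out", (make_assoc("rs1", "T", "C", beta=0.05),))
        h = harmonize(self.exposure(), out)
        assert h.Gamma[0] == 0.05

    def test_complement_swapped_sign_flip(self):
        out = SummaryTable("out", (make_assoc("rs1", "C", "T", beta=0.05, eaf=0.7),))
        h = harmonize(self.exposure(), out)
        assert h.Gamma[0] == -0.05

    def test_incompatible_alleles_excluded_not_fatal(self):
        exp = SummaryTable(
            "exp",
            (make_assoc("rs1", "A", "G"), make_assoc("rs2", "A", "C")),
        )
        out = SummaryTable(
            "out",
            (make_assoc("rs1", "A", "G", beta=0.05), make_assoc("rs2", "A", "G")),
        )
        h = harmonize(exp, out)
        assert h.rsids == ("rs1",)
        assert ("rs2", "incompatible alleles") in h.exclusions

    def test_ambiguous_palindrome_excluded_under_frequency_policy(self):
        exp = SummaryTable(
            "exp",
            (make_assoc("rs1", "A", "G"), make_assoc("rs2", "A", "T", eaf=0.49)),
        )
        out = SummaryTable(
            "out",
            (make_assoc("rs1", "A", "G"), make_assoc("rs2", "A", "T", eaf=0.51)),
        )
        h = harmonize(exp, out, palindrome_policy="frequency", eaf_window=0.08)
        assert h.rsids == ("rs1",)
        assert h.exclusions[0][0] == "rs2"
        assert "palindrome" in h.exclusions[0][1]

    def test_unambiguous_palindrome_oriented_by_frequency(self):
        # exposure eaf 0.2 vs outcome eaf 0.8: the outcome is reporting the
        # other allele, so its beta must flip
        exp = SummaryTable("exp", (make_assoc("rs1", "A", "T", eaf=0.2),))
        out = SummaryTable("out", (make_assoc("rs1", "A", "T", beta=0.05, eaf=0.8),))
        h = harmonize(exp, out, palindrome_policy="frequency")
        assert h.Gamma[0] == -0.05

    def test_palindrome_policies_drop_and_keep(self):
        exp = SummaryTable("exp", (make_assoc("rs1", "A", "T", eaf=0.2),))
        out = SummaryTable("out", (make_assoc("rs1", "A", "T", beta=0.05, eaf=0.8),))
        with pytest.raises(EmptyInstrumentSetError):
            harmonize(exp, out, palindrome_policy="drop")
        h = harmonize(exp, out, palindrome_policy="keep")
        assert h.Gamma[0] == 0.05  # trusted as already aligned

    def test_frequency_policy_requires_eaf(self):
        exp = SummaryTable("exp", (make_assoc("rs1", "A", "T", eaf=None),))
        out = SummaryTable("out", (make_assoc("rs1", "A", "T", beta=0.05),))
        with pytest.raises(ConfigurationError, match="eaf"):
            harmonize(exp, out, palindrome_policy="frequency")

    def test_no_shared_rsids_is_fatal(self):
        exp = SummaryTable("exp", (make_assoc("rs1"),))
        out = SummaryTable("out", (make_assoc("rs2"),))
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_self_harmonization_pairs_equal_effects(self, three_snp_exposure):
        h = harmonize(three_snp_exposure, three_snp_exposure, palindrome_policy="keep")
        np.testing.assert_array_equal(h.gamma, h.Gamma)
        np.testing.assert_array_equal(h.se_gamma, h.se_Gamma)
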