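"""Genotype/weight I/O, allele harmonization and coverage accounting."""

import numpy as np
import pandas as pd
import pytest

from longprs import genoio, scoring
from longprs.genoio import (CoverageReport, coverage_percent, harmonize,
                            read_vcf, read_weight_table, round_half_up,
                            write_vcf)

from conftest import make_gm

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
1\t200\trs2\tA\tG\t.\tPASS\t.\tGT:DS\t0/1:1.37\t0/0:0.12\t1/1:1.88
1\t300\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
"""


class TestReadVcf:
    @pytest.fixture()
    def gm(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_TEXT)
        return read_vcf(str(p))

    def test_gt_dosage_and_missing_mask(self, gm):
        # het -> 1, hom-alt -> 2, ./. -> masked
        np.testing.assert_array_equal(gm.dosage[:2, 0], [1.0, 2.0])
        assert np.isnan(gm.dosage[2, 0])

    def test_ds_preferred_over_gt(self, gm):
        np.testing.assert_allclose(gm.dosage[:, 1], [1.37, 0.12, 1.88],
                                   atol=1e-6)

    def test_multiallelic_skipped(self, gm):
        assert gm.n_variants == 2
        assert list(gm.variants["id"]) == ["rs1", "rs2"]

    def test_round_trip_preserves_hard_calls(self, tmp_path):
        gm = make_gm([[0, 1], [2, np.nan], [1, 0]])
        path = tmp_path / "rt.vcf"
        write_vcf(gm, str(path))
        back = read_vcf(str(path))
        np.testing.assert_array_equal(np.isnan(back.dosage), np.isnan(gm.dosage))
        ok = ~np.isnan(gm.dosage)
        np.testing.assert_array_equal(back.dosage[ok], gm.dosage[ok])

    def test_bgzipped_output_readable(self, tmp_path):
        gm = make_gm([[0, 1], [2, 1]])
        path = tmp_path / "rt.vcf.gz"
        write_vcf(gm, str(path))
        back = read_vcf(str(path))
        np.testing.assert_array_equal(back.dosage, gm.dosage)


class TestReadWeightTable:
    def test_or_column_converted_by_log(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("chrom\tpos\teffect_allele\tother_allele\tOR\n"
                     "1\t100\tG\tA\t1.5\n")
        wt = read_weight_table(str(p))
        assert wt["beta"].iloc[0] == pytest.approx(np.log(1.5))

    def test_inconsistent_beta_and_or_rejected(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("chrom\tpos\teffect_allele\tother_allele\tbeta\tOR\n"
                     "1\t100\tG\tA\t0.405465\t1.5\n"
                     "1\t200\tG\tA\t0.2\t1.5\n")
        wt = read_weight_table(str(p))
        assert len(wt) == 1
        assert wt["pos"].iloc[0] == 100

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("")
        wt = read_weight_table(str(p))
        assert len(wt) == 0

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("chrom\tpos\teffect_allele\tbeta\n1\t100\tG\t0.1\n")
        with pytest.raises(genoio.FormatError, match="other_allele"):
            read_weight_table(str(p))


def _weights(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "effect_allele",
                                       "other_allele", "beta"])


class TestHarmonize:
    # panel: one variant 1:100 with counted (ALT) G, other (REF) A
    panel = make_gm(np.array([[0.0, ], [1.0], [2.0]]))

    def _one(self, ea, oa, beta=0.5, drop_ambiguous=True):
        w = _weights([("1", 100, "x", ea, oa, beta)])
        return harmonize(w, self.panel, drop_ambiguous=drop_ambiguous)

    def test_direct_match_keeps_beta(self):
        hz, cov = self._one("G", "A")
        assert cov.n_covered == 1
        assert hz["beta"].iloc[0] == 0.5
        assert hz["effect_allele"].iloc[0] == "G"

    def test_swapped_match_flips_beta(self):
        hz, _ = self._one("A", "G")
        assert hz["beta"].iloc[0] == -0.5
        assert hz["effect_allele"].iloc[0] == "G"

    def test_strand_complement_match(self):
        # panel G/A; weights C/T complements to G/A
        hz, _ = self._one("C", "T")
        assert hz["beta"].iloc[0] == 0.5

    def test_palindromic_dropped(self):
        _, cov = self._one("A", "T")
        assert cov.n_covered == 0
        assert cov.reasons == {"ambiguous": 1}

    def test_all_sixteen_allele_pairs_against_complement_oracle(self):
        # independent oracle: explicit complement map and case analysis
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

        def oracle(ea, oa):
            if comp[ea] == oa:
                return "ambiguous"
            if (ea, oa) == ("G", "A") or (comp[ea], comp[oa]) == ("G", "A"):
                return 0.5
            if (ea, oa) == ("A", "G") or (comp[ea], comp[oa]) == ("A", "G"):
                return -0.5
            return "mismatch"

        for ea in "ACGT":
            for oa in "ACGT":
                if ea == oa:
                    continue
                hz, cov = self._one(ea, oa)
                expect = oracle(ea, oa)
                if isinstance(expect, float):
                    assert cov.n_covered == 1, (ea, oa)
                    assert hz["beta"].iloc[0] == expect, (ea, oa)
                else:
                    assert cov.n_covered == 0, (ea, oa)
                    assert list(cov.reasons) == [expect if expect != "mismatch"
                                                 else "allele_mismatch"], (ea, oa)

    def test_absent_and_duplicate_tallies(self):
        w = _weights([("1", 100, "a", "G", "A", 0.1),
                      ("1", 100, "b", "G", "A", 0.2),
                      ("2", 999, "c", "G", "A", 0.3)])
        hz, cov = harmonize(w, self.panel)
        assert cov.n_covered == 1
        assert cov.reasons == {"absent": 1, "duplicate": 1}

    def test_idempotence(self):
        w = _weights([("1", 100, "x", "A", "G", 0.7)])
        hz1, _ = harmonize(w, self.panel)
        hz2, cov2 = harmonize(hz1.drop(columns="panel_index"), self.panel)
        pd.testing.assert_frame_equal(hz1, hz2)
        assert cov2.percent == 100.0

    def test_coverage_conservation_random_tables(self):
        rng = np.random.default_rng(0)
        panel = make_gm(rng.integers(0, 3, (5, 20)).astype(float),
                        positions=np.arange(1, 21) * 10)
        alleles = np.array(list("ACGT"))
        for _ in range(20):
            k = rng.integers(1, 30)
            rows = []
            for i in range(k):
                ea, oa = rng.choice(alleles, 2, replace=False)
                rows.append(("1", int(rng.integers(1, 25)) * 10, f"r{i}",
                             ea, oa, float(rng.normal())))
            _, cov = harmonize(_weights(rows), panel)
            assert cov.n_covered + sum(cov.reasons.values()) == cov.n_input


class TestOrientationInvariance:
    def test_flipped_input_orientation_gives_same_contrasts(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, (50, 8)).astype(float),
                     positions=np.arange(1, 9) * 100)
        rows = [("1", (j + 1) * 100, f"r{j}", "G", "A", float(rng.normal()))
                for j in range(8)]
        w = _weights(rows)
        w_flip = w.copy()
        w_flip["effect_allele"], w_flip["other_allele"] = (
            w["other_allele"], w["effect_allele"])
        w_flip["beta"] = -w["beta"]
        hz1, _ = harmonize(w, gm)
        hz2, _ = harmonize(w_flip, gm)
        s1 = scoring.compute_prs(gm, hz1).score
        s2 = scoring.compute_prs(gm, hz2).score
        # identical scores: flipping orientation in the input is a no-op
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestCoveragePercent:
    @pytest.mark.parametrize("covered,total,expect", [
        (1715, 1805, 95.01),
        (161, 167, 96.41),
        (0, 100, 0.00),
        (100, 100, 100.00),
    ])
    def test_table_style_two_decimals(self, covered, total, expect):
        assert coverage_percent(covered, total) == expect

    @pytest.mark.parametrize("covered,total,expect", [
        (3414, 3966, 86.1),
        (91, 96, 94.8),
        (324, 334, 97.0),
    ])
    def test_prose_style_one_decimal(self, covered, total, expect):
        assert coverage_percent(covered, total, decimals=1) == expect

    def test_zero_input_undefined(self):
        with pytest.raises(ValueError):
            coverage_percent(0, 0)

    def test_half_up_rounding(self):
        assert round_half_up(0.005, 2) == 0.01
        assert round_half_up(0.865, 2) == 0.87

    def test_report_tallies_must_reconcile(self):
        with pytest.raises(ValueError):
            CoverageReport(n_input=10, n_covered=8, reasons={"absent": 1})


class TestPercentProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_percent_bounds_and_monotonicity(self, a, b):
        covered, total = min(a, b), max(a, b, 1)
        pct = coverage_percent(covered, total)
        assert 0.0 <= pct <= 100.0
        if covered < total:
            assert pct <= coverage_percent(covered + 1, total)
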