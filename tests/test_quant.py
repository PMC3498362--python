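"""Member-resolved quantification, fold changes and response classes."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrimir import quant
from nutrimir.preprocess import ReadTagTable

# the 20 published novel-miRNA count pairs (+N, -N) and the printed folds
TABLE3 = {
    "miRN01": (22, 18, -0.3),
    "miRN02": (6, 8, 0.4),
    "miRN03": (9, 13, 0.5),
    "miRN04": (6, 6, 0.0),
    "miRN05": (12, 28, 1.2),
    "miRN06": (17, 38, 1.2),
    "miRN07": (28, 153, 2.4),
    "miRN08": (14, 27, 0.9),
    "miRN09": (71, 226, 1.7),
    "miRN10": (21, 26, 0.3),
    "miRN11": (13, 13, 0.0),
    "miRN12": (9, 7, -0.4),
    "miRN13": (24, 9, -1.4),
    "miRN14": (1145, 82, -3.8),
    "miRN15": (9, 13, 0.5),
    "miRN16": (8, 22, 1.5),
    "miRN17": (8, 36, 2.2),
    "miRN18": (12, 11, -0.1),
    "miRN19": (5, 6, 0.3),
    "miRN20": (14, 81, 2.5),
}


def table_of(rows):
    return ReadTagTable(
        pd.DataFrame(
            {
                "sequence": [r[0] for r in rows],
                "count_A": [r[1] for r in rows],
                "count_B": [r[2] for r in rows],
            }
        )
    )


class TestGroupMembers:
    def test_identical_sequences_merge_with_letter_range(self):
        mature = {
            "miR169d": "TGAGCCAAGGATGACTTGCCG",
            "miR169e": "TGAGCCAAGGATGACTTGCCG",
            "miR169f": "TGAGCCAAGGATGACTTGCCG",
            "miR169g": "TGAGCCAAGGATGACTTGCCG",
            "miR169a": "CAGCCAAGGATGACTTGCCGA",
        }
        groups = quant.group_members(mature)
        assert set(groups) == {"miR169d-g", "miR169a"}

    def test_nonconsecutive_letters_join_with_slash(self):
        groups = quant.group_members(
            {"miR1a": "ACGTACGTACGTACGTACGT", "miR1c": "ACGTACGTACGTACGTACGT"}
        )
        assert set(groups) == {"miR1a/miR1c"}

    def test_duplicate_member_names_rejected_at_fasta_boundary(self):
        from nutrimir.io import read_fasta

        text = ">miR1\nACGTACGTACGTACGTACGT\n>miR1\nTTTTACGTACGTACGTACGT\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(text, is_text=True)


class TestMatchKnown:
    def test_exact_match_contributes(self):
        mature = {"miR169a": "TGAGCCAAGGATGACTTGCCG"}
        table = table_of([("TGAGCCAAGGATGACTTGCCG", 50, 5)])
        rec = quant.match_known(table, mature)
        assert rec.loc[0, ["count_A", "count_B"]].tolist() == [50, 5]

    def test_one_mismatch_contributes_nothing(self):
        mature = {"miR169a": "TGAGCCAAGGATGACTTGCCG"}
        table = table_of([("TGAGCCAAGGATGACTTGCCA", 50, 5)])
        rec = quant.match_known(table, mature)
        assert rec.loc[0, ["count_A", "count_B"]].tolist() == [0, 0]

    def test_two_distinct_sequences_two_groups(self):
        mature = {
            "miR9a": "ACGTACGTACGTACGTACGT",
            "miR9b": "ACGTACGTACGTACGTACGT",
            "miR9c": "TTTTACGTACGTACGTACGT",
            "miR9d": "TTTTACGTACGTACGTACGT",
        }
        rec = quant.match_known(table_of([("ACGTACGTACGTACGTACGT", 3, 4)]), mature)
        assert len(rec) == 2


class TestRPM:
    def test_direct_evaluation_on_published_totals(self):
        # 301115 reads of 9681350 total
        assert quant.rpm(301115, 9681350) == 31102.58

    def test_zero_count(self):
        assert quant.rpm(0, 1000) == 0.0

    def test_scale_invariance(self):
        assert quant.rpm(250, 10_000) == quant.rpm(500, 20_000)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            quant.rpm(1, 0)


class TestLog2FoldChange:
    @pytest.mark.parametrize("name,a,b,printed", [
        (k, *v) for k, v in TABLE3.items() if k != "miRN07"
    ])
    def test_published_fold_column_reproduces(self, name, a, b, printed):
        assert quant.log2_fold_change(a, b) == printed

    def test_mirn07_prints_differently_than_computation(self):
        # log2(153/28) = 2.45 which rounds to 2.5, not the printed 2.4
        assert quant.log2_fold_change(28, 153) == 2.5

    def test_equal_counts_zero(self):
        assert quant.log2_fold_change(10, 10) == 0.0

    def test_pseudocount_applied_to_both_when_zero(self):
        assert quant.log2_fold_change(0, 8) == 3.2  # log2(9/1)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="no_signal"):
            quant.log2_fold_change(0, 0)

    def test_rpm_mode_uses_library_totals(self):
        raw = quant.log2_fold_change(100, 100, rounded=False)
        norm = quant.log2_fold_change(
            100, 100, mode="rpm", rpm_totals=(1_000_000, 2_000_000), rounded=False
        )
        assert raw == 0.0 and norm == pytest.approx(-1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_antisymmetry_before_rounding(self, a, b):
        if a == 0 and b == 0:
            return
        assert quant.log2_fold_change(a, b, rounded=False) == pytest.approx(
            -quant.log2_fold_change(b, a, rounded=False)
        )


class TestClassifyResponse:
    def test_strong_suppression_is_nss(self):
        assert quant.classify_response(-3.8, 2) == quant.NSS

    def test_mild_change_unchanged(self):
        assert quant.classify_response(0.4, 2) == quant.UNCHANGED

    def test_strict_boundary(self):
        assert quant.classify_response(1.0, 2) == quant.UNCHANGED
        assert quant.classify_response(1.0001, 2) == quant.NSI

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            quant.classify_response(0.0, 1.0)


class TestTable3Regression:
    def test_ratio_gt2_rule_yields_exactly_nine_responsive(self):
        pairs = [(a, b) for a, b, _ in TABLE3.values()]
        assert quant.count_responsive(pairs, ratio_threshold=2.0) == 9

    def test_fold_column_reproduced_for_at_least_18_of_20(self):
        hits = sum(
            quant.log2_fold_change(a, b) == printed
            for a, b, printed in TABLE3.values()
        )
        assert hits >= 18


class TestFamilyAggregate:
    def test_member_sum_matches_published_mir158_counts(self):
        rec = pd.DataFrame(
            {"id": ["miR158a", "miR158b"], "count_A": [331232, 3383], "count_B": [115256, 2850]}
        )
        agg = quant.family_aggregate(rec, {"miR158a": "miR158", "miR158b": "miR158"})
        assert agg.loc[0, "count_A"] == 334615

    def test_single_member_family(self):
        rec = pd.DataFrame({"id": ["m1"], "count_A": [5], "count_B": [7]})
        agg = quant.family_aggregate(rec, {"m1": "fam"})
        assert agg.loc[0, ["count_A", "count_B"]].tolist() == [5, 7]

    def test_order_invariance(self):
        rec = pd.DataFrame(
            {"id": ["a", "b", "c"], "count_A": [1, 2, 3], "count_B": [4, 5, 6]}
        )
        fam = {"a": "f", "b": "f", "c": "g"}
        agg1 = quant.family_aggregate(rec, fam)
        agg2 = quant.family_aggregate(rec.iloc[::-1].reset_index(drop=True), fam)
        assert agg1.equals(agg2)

    def test_unmapped_member_errors(self):
        rec = pd.DataFrame({"id": ["a"], "count_A": [1], "count_B": [1]})
        with pytest.raises(ValueError):
            quant.family_aggregate(rec, {})


class TestExpressionTable:
    def test_low_count_rows_get_no_response_call(self):
        rec = pd.DataFrame({"id": ["lo", "hi"], "count_A": [1, 100], "count_B": [2, 900]})
        out = quant.expression_table(rec, 1000, 1000, ratio_threshold=3.0)
        assert bool(out.loc[0, "low_count"]) and pd.isna(out.loc[0, "response"])
        assert out.loc[1, "response"] == quant.NSI

    def test_noise_free_planted_effects_recovered_exactly(self, noise_free_study):
        """With dispersion 0 every planted effect beyond the threshold is
        called in the right direction and null effects stay unchanged."""
        from nutrimir.synthio import known_mature_fasta

        mature = known_mature_fasta(noise_free_study.truth)
        rec = quant.match_known(noise_free_study.mapped_table, mature)
        out = quant.expression_table(
            rec,
            noise_free_study.mapped_table.total_A,
            noise_free_study.mapped_table.total_B,
            ratio_threshold=3.0,
        )
        truth_by_name = {m.name: m for m in noise_free_study.truth.known}
        for row in out.itertuples(index=False):
            planted = truth_by_name[row.id].log2fc
            if abs(planted) > math.log2(3.0):
                expected = quant.NSI if planted > 0 else quant.NSS
                assert row.response == expected
            elif planted == 0.0:
                assert row.response == quant.UNCHANGED
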