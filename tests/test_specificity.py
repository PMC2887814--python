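import numpy as np
import pandas as pd
import pytest

from conftest import make_sheet
from ecrestrict.canonical import CANONICAL_MARKERS
from ecrestrict.data_model import ExpressionMatrix
from ecrestrict.errors import UsageError
from ecrestrict.specificity import (enrichment_score, outlier_analysis,
                                    present_absent_calls, rank_score,
                                    ref_fold, select_restricted,
                                    specificity_table)

# independently verified products of the published fold-change pairs
EXPECTED_RANKS = {
    "MMRN1": 11157.50625,
    "CLDN5": 5933.421875,
    "VWF": 4772.862931,
    "ECSCR": 646.6127586,
    "SHE": 9.851707317,
}


def reference_pair(levels):
    """Matrix with one target reference cell (first) and the rest
    background, one gene."""
    n = len(levels)
    rows = [("ec", "EC", "target", "", 1)]
    rows += [(f"c{i}", f"cell{i}", "background", "", 1) for i in range(1, n)]
    sheet = make_sheet(rows)
    matrix = ExpressionMatrix(("g0",), sheet.sample_ids,
                              np.array([levels], dtype=float))
    return matrix, sheet


class TestPresentAbsentCalls:
    def test_strict_50_percent_boundary(self):
        matrix, sheet = reference_pair([100.0, 51.0, 50.0, 49.0])
        calls = present_absent_calls(matrix, sheet)
        assert calls.loc["g0", "c1"]          # 51 > 50 -> present
        assert not calls.loc["g0", "c2"]      # 50 -> absent
        assert not calls.loc["g0", "c3"]

    def test_silent_target_level(self):
        matrix, sheet = reference_pair([0.0, 5.0, 0.0])
        calls = present_absent_calls(matrix, sheet)
        assert calls.loc["g0", "c1"]          # any positive value present
        assert not calls.loc["g0", "c2"]      # zero stays absent

    def test_max_level_statistic(self):
        rows = [("ec1", "EC", "target", "", 1), ("ec2", "EC", "target", "", 2),
                ("c1", "cell", "background", "", 1)]
        sheet = make_sheet(rows)
        matrix = ExpressionMatrix(("g0",), sheet.sample_ids,
                                  np.array([[100.0, 300.0, 110.0]]))
        mean_calls = present_absent_calls(matrix, sheet, "mean")
        max_calls = present_absent_calls(matrix, sheet, "max")
        assert mean_calls.loc["g0", "c1"]     # 110 > 0.5*200
        assert not max_calls.loc["g0", "c1"]  # 110 < 0.5*300


class TestEnrichmentScore:
    @pytest.mark.parametrize("present, expected", [
        ([False, False, False], 1.0),
        ([True, True, True, True], 0.0),
        ([True, False, False, False], 0.75),
    ])
    def test_absent_fraction(self, present, expected):
        assert enrichment_score(present) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(UsageError):
            enrichment_score([])

    def test_permutation_invariance(self):
        calls = pd.DataFrame([[True, False, False, True]],
                             index=["g0"], columns=list("abcd"))
        base = enrichment_score(calls)["g0"]
        for perm in (["b", "a", "d", "c"], ["d", "c", "b", "a"]):
            assert enrichment_score(calls[perm])["g0"] == pytest.approx(base)


class TestOutlierAnalysis:
    def test_constant_row_has_no_outliers(self):
        matrix, sheet = reference_pair([5.0] * 7)
        row = matrix.to_frame().loc["g0"]
        outliers, klass = outlier_analysis(row, sheet)
        assert outliers == set() and klass == "none"

    def test_two_sigma_arithmetic(self):
        """[1,1,1,1,1,1,10]: mu = 16/7, s = 3.4017, only the 10 deviates
        more than 2s (7.714 > 6.803)."""
        matrix, sheet = reference_pair([10.0, 1, 1, 1, 1, 1, 1])
        row = matrix.to_frame().loc["g0"]
        outliers, klass = outlier_analysis(row, sheet)
        assert outliers == {"ec"}
        assert klass == "target_only"

    def test_background_outlier_flags_mixed(self):
        matrix, sheet = reference_pair([1.0, 10, 1, 1, 1, 1, 1])
        row = matrix.to_frame().loc["g0"]
        outliers, klass = outlier_analysis(row, sheet)
        assert outliers == {"c1"}
        assert klass == "mixed"

    def test_needs_three_samples(self):
        matrix, sheet = reference_pair([1.0, 2.0])
        with pytest.raises(UsageError):
            outlier_analysis(matrix.to_frame().loc["g0"], sheet)


class TestRefFold:
    def test_ratio_of_reference_means(self):
        matrix, sheet = reference_pair([64.625 * 10, 10.0, 10.0, 10.0])
        assert ref_fold(matrix, sheet)["g0"] == pytest.approx(64.625)

    def test_equal_means_give_one(self):
        matrix, sheet = reference_pair([10.0, 10.0, 10.0])
        assert ref_fold(matrix, sheet)["g0"] == pytest.approx(1.0)


class TestRankScore:
    @pytest.mark.parametrize("marker", CANONICAL_MARKERS,
                             ids=[m.gene for m in CANONICAL_MARKERS])
    def test_reproduces_published_marker_ranks(self, marker):
        assert rank_score(marker.fc, marker.ref_fold) == pytest.approx(
            EXPECTED_RANKS[marker.gene], rel=1e-6)

    def test_identity_when_fc_is_one(self):
        assert rank_score(1.0, 17.5) == pytest.approx(17.5)

    @pytest.mark.parametrize("fc, rf", [(0.0, 1.0), (1.0, -2.0)])
    def test_non_positive_inputs_rejected(self, fc, rf):
        with pytest.raises(UsageError):
            rank_score(fc, rf)

    def test_vectorized(self):
        out = rank_score(np.array([2.0, 3.0]), np.array([5.0, 7.0]))
        np.testing.assert_allclose(out, [10.0, 21.0])


def candidate_records(n_pool, n_other=0):
    rows = []
    for i in range(n_pool):
        rows.append((f"p{i:02d}", 5.0, 1.0, "target_only", 4.0,
                     100.0 - i))
    for i in range(n_other):
        rows.append((f"q{i:02d}", 5.0, 0.5, "none", 4.0, 1000.0))
    return pd.DataFrame(rows, columns=["gene_id", "fc", "ecs",
                                       "outlier_class", "ref_fold",
                                       "rank_score"])


class TestSelectRestricted:
    def test_top_fraction_uses_ceiling(self):
        table = select_restricted(candidate_records(10))
        assert int(table["selected"].sum()) == 6  # ceil(0.6 * 10)

    def test_low_ref_fold_excluded_regardless_of_rank(self):
        records = candidate_records(5)
        records.loc[0, "ref_fold"] = 2.9  # the top-ranked candidate
        table = select_restricted(records)
        assert not table.set_index("gene_id").loc["p00", "selected"]

    def test_gate_requires_ecs_one_and_target_only(self):
        table = select_restricted(candidate_records(5, n_other=3),
                                  top_fraction=1.0)
        selected = set(table.loc[table["selected"], "gene_id"])
        assert selected == {f"p{i:02d}" for i in range(5)}

    def test_rank_ties_break_lexicographically(self):
        records = candidate_records(4)
        records["rank_score"] = 50.0
        table = select_restricted(records, top_fraction=0.5)
        selected = list(table.loc[table["selected"], "gene_id"])
        assert selected == ["p00", "p01"]

    def test_deny_and_allow_lists_apply_last(self):
        records = candidate_records(10)
        table = select_restricted(records, denylist=["p00"],
                                  allowlist=["p09"])
        by_gene = table.set_index("gene_id")["selected"]
        assert not by_gene["p00"]   # denied despite top rank
        assert by_gene["p09"]       # retained despite the 60% trim

    def test_allowlist_cannot_rescue_non_candidates(self):
        table = select_restricted(candidate_records(3, n_other=1),
                                  allowlist=["q00"])
        assert not table.set_index("gene_id").loc["q00", "selected"]

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning, match="empty candidate pool"):
            table = select_restricted(candidate_records(0, n_other=2))
        assert not table["selected"].any()


class TestSpecificityTable:
    def test_rank_is_product_and_gates_work(self, small_matrix, small_sheet,
                                            reference_matrix, reference_sheet):
        table = specificity_table(small_matrix, small_sheet,
                                  reference_matrix, reference_sheet)
        np.testing.assert_allclose(table["rank_score"],
                                   table["fc"] * table["ref_fold"],
                                   rtol=1e-12)
        by_gene = table.set_index("gene_id")
        assert by_gene.loc["g0", "ecs"] == 1.0
        assert by_gene.loc["g0", "outlier_class"] == "target_only"
        assert by_gene.loc["g3", "ecs"] < 1.0

    def test_monotone_in_nontarget_reference_level(self, reference_matrix,
                                                   reference_sheet):
        """Lowering one non-target reference cell can only push ECS and
        REF_FOLD up (or leave them unchanged)."""
        calls = present_absent_calls(reference_matrix, reference_sheet)
        ecs_before = enrichment_score(calls)
        rf_before = ref_fold(reference_matrix, reference_sheet)
        lowered = reference_matrix.values.copy()
        lowered[:, 3] *= 0.1  # a background reference cell
        lowered_matrix = ExpressionMatrix(reference_matrix.gene_ids,
                                          reference_matrix.sample_ids, lowered)
        ecs_after = enrichment_score(
            present_absent_calls(lowered_matrix, reference_sheet))
        rf_after = ref_fold(lowered_matrix, reference_sheet)
        assert (ecs_after >= ecs_before - 1e-12).all()
        assert (rf_after >= rf_before - 1e-12).all()
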