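from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecrestrict.data_model import GeneSet, GeneSetCollection, SequenceRecord
from ecrestrict.enrichment import (bh_fdr, count_sites, ease_score,
                                   fisher_overrepresentation,
                                   genes_with_sites, gmt_overrepresentation,
                                   mirna_enrichment, mirna_seed_match,
                                   seed_site, site_enrichment_gate,
                                   total_sites)
from ecrestrict.errors import UsageError


def exact_tail(overlap, background, set_size, study):
    """Exhaustive hypergeometric upper tail as an exact fraction."""
    total = Fraction(0)
    for i in range(overlap, min(set_size, study) + 1):
        total += Fraction(comb(set_size, i)
                          * comb(background - set_size, study - i),
                          comb(background, study))
    return float(total)


def gene_universe(n):
    return [f"g{i:03d}" for i in range(n)]


class TestFisherOverrepresentation:
    def test_perfect_overlap_closed_form(self):
        background = gene_universe(20)
        study = background[:5]
        result = fisher_overrepresentation(study, study, background)
        assert result.p_value == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert result.overlap == 5

    def test_zero_overlap_gives_one(self):
        background = gene_universe(20)
        result = fisher_overrepresentation(background[:5], background[10:15],
                                           background[:10] + background[15:])
        assert result.p_value == pytest.approx(1.0)

    def test_study_equals_background_gives_one(self):
        background = gene_universe(12)
        result = fisher_overrepresentation(background, background[:4],
                                           background)
        assert result.overlap == 4
        assert result.p_value == pytest.approx(1.0)

    def test_study_outside_background_rejected(self):
        with pytest.raises(UsageError):
            fisher_overrepresentation(["x"], ["x"], gene_universe(5))

    def test_empty_background_rejected(self):
        with pytest.raises(UsageError):
            fisher_overrepresentation([], [], [])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_bg = int(rng.integers(5, 31))
        background = gene_universe(n_bg)
        study = list(rng.choice(background, rng.integers(1, n_bg + 1),
                                replace=False))
        members = list(rng.choice(background, rng.integers(1, n_bg + 1),
                                  replace=False))
        result = fisher_overrepresentation(study, members, background)
        expected = exact_tail(result.overlap, n_bg, len(members), len(study))
        assert result.p_value == pytest.approx(expected, rel=1e-9)


class TestEaseScore:
    def test_singleton_overlap_collapses_to_one(self):
        background = gene_universe(20)
        assert ease_score(background[:5], background[4:6], background) == 1.0

    def test_penalized_overlap_matches_closed_form(self):
        background = gene_universe(20)
        study = background[:5]
        ease = ease_score(study, study, background)
        assert ease == pytest.approx(exact_tail(4, 20, 5, 4), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_ease_never_below_fisher(self, seed):
        rng = np.random.default_rng(seed)
        background = gene_universe(25)
        study = list(rng.choice(background, 8, replace=False))
        members = list(rng.choice(background, 10, replace=False))
        result = fisher_overrepresentation(study, members, background)
        assert result.ease_p >= result.p_value - 1e-12


class TestBhFdr:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_input_order(self, ps):
        adjusted = bh_fdr(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(adjusted)[order]) >= -1e-12).all()
        assert ((0 <= adjusted) & (adjusted <= 1)).all()
        assert (adjusted >= np.asarray(ps) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            bh_fdr([0.5, 1.5])


class TestGmtOverrepresentation:
    def test_table_sorted_and_adjusted(self):
        background = gene_universe(30)
        study = background[:6]
        collection = GeneSetCollection({
            "hit": GeneSet("hit", "planted", tuple(background[:6])),
            "miss": GeneSet("miss", "unrelated", tuple(background[20:26])),
        })
        table = gmt_overrepresentation(study, collection, background)
        assert list(table["set_id"]) == ["hit", "miss"]
        assert (table["adjusted_p"] >= table["p_value"] - 1e-12).all()


class TestSiteEnrichmentGate:
    def test_unit_ratio_fails_gate(self):
        result = site_enrichment_gate(20, 40, 20, 40)
        assert result.ratio == pytest.approx(1.0)
        assert not result.passes_gate

    def test_weak_p_fails_gate(self):
        result = site_enrichment_gate(3, 40, 2, 40)
        assert result.p_value > 0.01
        assert not result.passes_gate

    def test_strong_enrichment_passes_and_matches_enumeration(self):
        result = site_enrichment_gate(30, 40, 10, 40)
        assert result.p_value == pytest.approx(exact_tail(30, 80, 40, 40),
                                               rel=1e-9)
        assert result.ratio == pytest.approx(3.0)
        assert result.passes_gate

    def test_zero_no_density_decided_by_p(self):
        with pytest.warns(UserWarning, match="ratio undefined"):
            result = site_enrichment_gate(10, 40, 0, 40)
        assert np.isinf(result.ratio)
        assert result.passes_gate == (result.p_value < 0.01)

    def test_hits_beyond_promoters_rejected(self):
        with pytest.raises(UsageError):
            site_enrichment_gate(50, 40, 1, 40)


class TestSeedMatching:
    def test_seed_site_is_reverse_complement_of_positions_2_to_8(self):
        mirna = SequenceRecord("mir", "UGGAAUGUAAAGAAGUAUGUAU")  # 5'->3'
        # positions 2-8 = GGAAUGU -> DNA GGAATGT -> revcomp ACATTCC
        assert seed_site(mirna) == "ACATTCC"

    def test_exact_site_found_at_offset_zero(self):
        mirna = SequenceRecord("mir", "UGGAAUGUAAAGAAGUAUGUAU")
        utr = SequenceRecord("utr", "ACATTCC")
        (match,) = mirna_seed_match([utr], [mirna])
        assert match.n_sites == 1
        assert match.site_positions == (0,)

    def test_no_complementary_site_counts_zero(self):
        mirna = SequenceRecord("mir", "UGGAAUGUAAAGAAGUAUGUAU")
        utr = SequenceRecord("utr", "GGGGGGGGGGGGGGGG")
        (match,) = mirna_seed_match([utr], [mirna])
        assert match.n_sites == 0

    def test_tandem_sites_with_spacer(self):
        mirna = SequenceRecord("mir", "UGGAAUGUAAAGAAGUAUGUAU")
        utr = SequenceRecord("utr", "ACATTCC" + "G" + "ACATTCC")
        (match,) = mirna_seed_match([utr], [mirna])
        assert match.n_sites == 2
        assert match.site_positions == (0, 8)

    def test_short_utr_has_no_sites(self):
        mirna = SequenceRecord("mir", "UGGAAUGUAAAGAAGUAUGUAU")
        (match,) = mirna_seed_match([SequenceRecord("utr", "ACAT")], [mirna])
        assert match.n_sites == 0

    def test_case_and_ut_encoding_invariance(self):
        site = "ACATTCC"
        for variant in ("acattcc", "ACAUUCC", "AcAuUcC"):
            assert count_sites(variant, site) == [0]

    def test_greedy_counting_matches_exhaustive_scan(self):
        """Greedy non-overlapping counts vs a brute-force offset scan on
        random 200-nt UTRs."""
        rng = np.random.default_rng(8)
        site = "ACATTCC"
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            # exhaustive scan: all offsets, then greedy left-to-right
            offsets = [i for i in range(len(seq) - 6)
                       if seq[i:i + 7] == site]
            greedy, last_end = [], -1
            for off in offsets:
                if off > last_end:
                    greedy.append(off)
                    last_end = off + 6
            assert count_sites(seq, site) == greedy
            assert count_sites(seq, site, allow_overlap=True) == offsets


class TestMirnaEnrichment:
    def test_concentrated_hits_reach_minimal_tail(self):
        table = mirna_enrichment({"mir-1": 5}, {"mir-1": 5}, 5, 20)
        assert table.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5),
                                                        rel=1e-9)

    def test_proportional_hits_are_unremarkable(self):
        # study 5 of 20; background hits 8 -> expected study hits = 2
        table = mirna_enrichment({"mir-1": 2}, {"mir-1": 8}, 5, 20)
        assert table.loc[0, "p_value"] > 0.3

    def test_empty_study_gives_one(self):
        table = mirna_enrichment({}, {"mir-1": 4}, 5, 20)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_background_hits_give_one(self):
        table = mirna_enrichment({"mir-1": 0}, {"mir-1": 0}, 5, 20)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_study_hits_beyond_background_rejected(self):
        with pytest.raises(UsageError):
            mirna_enrichment({"mir-1": 6}, {"mir-1": 2}, 10, 20)

    def test_site_count_helpers(self):
        mirna = SequenceRecord("mir", "UGGAAUGUAAAGAAGUAUGUAU")
        utrs = [SequenceRecord("u1", "ACATTCCGACATTCC"),
                SequenceRecord("u2", "GGGGGGGG")]
        matches = mirna_seed_match(utrs, [mirna])
        assert genes_with_sites(matches) == {"mir": 1}
        assert total_sites(matches) == {"mir": 2}
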