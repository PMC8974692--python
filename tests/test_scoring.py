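"""Weighted evidence scoring and candidate-gene selection rules."""

import pytest
from hypothesis import given, settings, strategies as st

from gwas2genes.io import (
    UB_CATEGORIES,
    EvidenceCategory,
    EvidenceRecord,
    ValidationError,
    load_fixture,
)
from gwas2genes.scoring import (
    AmbiguousFallbackError,
    RULE_FALLBACK,
    RULE_OVERRIDE,
    RULE_THRESHOLD,
    ScoreCard,
    WeightScheme,
    cards_from_published,
    filter_significant,
    max_possible_score,
    score_evidence,
    score_pair,
    select_candidates,
)


def records_for(categories, signal="rs1", gene="G"):
    out = []
    for cat in categories:
        out.append(EvidenceRecord(signal, gene, cat, p_value=0.01))
    return out


ALL_CATEGORIES = list(EvidenceCategory)


class TestWeightScheme:
    def test_default_weights_eleven_singles_three_doubles(self):
        scheme = WeightScheme()
        assert sum(1 for c in ALL_CATEGORIES if scheme.weights[c] == 2) == 3
        assert set(c for c in ALL_CATEGORIES if scheme.weights[c] == 2) == UB_CATEGORIES
        assert sum(1 for c in ALL_CATEGORIES if scheme.weights[c] == 1) == 11

    def test_max_possible_is_the_weight_sum(self):
        # eleven singles + three doubles; the published table's printed
        # total (16) mis-sums its own weights, see docs/methods.md
        assert max_possible_score(WeightScheme()) == 17
        all_ones = WeightScheme(weights={c: 1 for c in ALL_CATEGORIES})
        assert max_possible_score(all_ones) == 14

    def test_missing_category_rejected(self):
        weights = {c: 1 for c in ALL_CATEGORIES}
        weights.pop(EvidenceCategory.LITERATURE)
        with pytest.raises(ValidationError):
            WeightScheme(weights=weights)


class TestScorePair:
    def test_all_categories_present_reach_the_maximum(self):
        card = score_pair(records_for(ALL_CATEGORIES))
        assert card.total == max_possible_score()
        assert card.ub_count == 3
        assert card.weight2_consistent

    def test_single_weight1_hit_scores_one(self):
        card = score_pair(records_for([EvidenceCategory.GTEX_RESP_EQTL]))
        assert (card.base_score, card.ub_count, card.total) == (1, 0, 1)

    def test_worked_pair_eleven_singles_one_ub_compartment(self):
        cats = [c for c in ALL_CATEGORIES if c not in UB_CATEGORIES]
        cats.append(EvidenceCategory.UB_BIOPSY_EQTL)
        card = score_pair(records_for(cats))
        assert (card.base_score, card.ub_count, card.total) == (11, 1, 13)

    def test_empty_evidence_disallowed(self):
        with pytest.raises(ValidationError):
            score_pair([])

    def test_mixed_pairs_rejected(self):
        recs = records_for([EvidenceCategory.LITERATURE], gene="A")
        recs += records_for([EvidenceCategory.LITERATURE], gene="B")
        with pytest.raises(ValidationError):
            score_pair(recs)

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.sampled_from(ALL_CATEGORIES), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_order_invariant_and_duplication_idempotent(self, cats, rnd):
        """Within-category multiplicity never changes the score."""
        recs = records_for(cats)
        card = score_pair(recs)
        shuffled = list(recs)
        rnd.shuffle(shuffled)
        assert score_pair(shuffled) == card
        assert score_pair(recs + recs) == card
        assert card.total == score_pair(records_for(set(cats))).total

    @settings(derandomize=True, max_examples=150)
    @given(
        st.sets(st.sampled_from(ALL_CATEGORIES), min_size=1),
        st.sampled_from(ALL_CATEGORIES),
    )
    def test_adding_a_category_never_decreases_total(self, cats, extra):
        base = score_pair(records_for(cats)).total
        grown = score_pair(records_for(cats | {extra})).total
        assert grown >= base
        assert 0 <= grown <= max_possible_score()


class TestFilterSignificant:
    def test_rules_per_category(self):
        keep_p = EvidenceRecord("rs1", "G", EvidenceCategory.GTEX_RESP_EQTL, p_value=0.01)
        drop_p = EvidenceRecord("rs1", "G", EvidenceCategory.GTEX_RESP_EQTL, p_value=0.2)
        keep_h4 = EvidenceRecord("rs1", "G", EvidenceCategory.OTG_COLOC, h4=0.95)
        drop_h4 = EvidenceRecord("rs1", "G", EvidenceCategory.OTG_COLOC, h4=0.8)
        presence = EvidenceRecord("rs1", "G", EvidenceCategory.LITERATURE)
        kept = filter_significant([keep_p, drop_p, keep_h4, drop_h4, presence])
        assert kept == [keep_p, keep_h4, presence]


class TestPublishedTable:
    def test_weight2_consistent_rows_reproduce_published_totals(self):
        rows = load_fixture("evidence_scores")
        consistent = [r for r in rows if r.weight2_consistent]
        assert consistent, "fixture must contain weight-2-consistent rows"
        for row in consistent:
            assert row.base_score + 2 * row.ub_column == row.published_total

    def test_inconsistent_rows_confined_to_one_signal(self):
        rows = load_fixture("evidence_scores")
        odd = {r.signal_rsid for r in rows if not r.weight2_consistent}
        assert odd == {"rs776111176"}

    def test_signal_split_21_threshold_4_fallback(self):
        cards = cards_from_published()
        selected = select_candidates(cards, overrides={"rs61816761": "FLG"})
        assert len(selected.per_signal) == 25
        assert selected.n_threshold_signals == 21
        assert selected.n_fallback_signals == 4

    def test_candidate_set_is_published_37_plus_annotated_extra(self):
        selected = select_candidates(
            cards_from_published(), overrides={"rs61816761": "FLG"}
        )
        assert len(selected.unique_genes) == 38
        assert selected.annotations == {"HLA-DOB": "published-set mismatch"}
        for gene in ("FLG", "IL1RL1", "MUC5AC", "ZNF652", "GATA3"):
            assert gene in selected.unique_genes


class TestSelectCandidates:
    def test_threshold_rule(self):
        cards = [
            ScoreCard("rs7523907", "CD247", 7, 0, 7),
            ScoreCard("rs7523907", "BRP44", 0, 1, 2),
            ScoreCard("rs7523907", "CREG1", 0, 1, 2),
        ]
        sel = select_candidates(cards)
        assert sel.per_signal["rs7523907"] == [("CD247", RULE_THRESHOLD)]

    def test_fallback_highest_rule(self):
        cards = [
            ScoreCard("rs1837253", "TSLP", 2, 0, 2),
            ScoreCard("rs1837253", "WDR36", 1, 0, 1),
        ]
        sel = select_candidates(cards)
        assert sel.per_signal["rs1837253"] == [("TSLP", RULE_FALLBACK)]

    def test_literature_override_replaces_selection(self):
        cards = [
            ScoreCard("rs61816761", "FLG", 2, 0, 2),
            ScoreCard("rs61816761", "TUFT1", 0, 1, 2),
        ]
        sel = select_candidates(cards, overrides={"rs61816761": "FLG"})
        assert sel.per_signal["rs61816761"] == [("FLG", RULE_OVERRIDE)]

    def test_tied_fallback_without_override_is_ambiguous(self):
        cards = [
            ScoreCard("rsX", "A", 2, 0, 2),
            ScoreCard("rsX", "B", 2, 0, 2),
        ]
        with pytest.raises(AmbiguousFallbackError) as exc:
            select_candidates(cards)
        assert set(exc.value.tied) == {"A", "B"}

    def test_override_must_reference_a_scored_gene(self):
        cards = [ScoreCard("rsX", "A", 1, 0, 1)]
        with pytest.raises(ValidationError):
            select_candidates(cards, overrides={"rsX": "NOT_THERE"})

    def test_unique_genes_keep_first_appearance_order(self):
        cards = [
            ScoreCard("rs_a", "G2", 3, 0, 3),
            ScoreCard("rs_a", "G1", 4, 0, 4),
            ScoreCard("rs_b", "G1", 5, 0, 5),
            ScoreCard("rs_b", "G3", 3, 0, 3),
        ]
        sel = select_candidates(cards)
        assert sel.unique_genes == ["G2", "G1", "G3"]


def test_score_evidence_groups_by_pair():
    recs = records_for([EvidenceCategory.GTEX_RESP_EQTL, EvidenceCategory.LITERATURE], gene="A")
    recs += records_for([EvidenceCategory.UB_NASAL_EQTL], gene="B")
    cards = score_evidence(recs)
    assert [(c.gene, c.total) for c in cards] == [("A", 2), ("B", 2)]
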