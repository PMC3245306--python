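from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from azohgt.ancestry import (
    ClassifierConfig,
    Neighborhood,
    UnresolvableSubjectError,
    build_neighborhood,
    classify_ancestry,
    classify_genome,
    classify_membership_sequence,
    summarize_proportions,
)

from _oracles import first_occurrence_scan, literal_ancestry, literal_conditions
from conftest import SELF, neighborhood_from_letters, make_hit


class TestBuildNeighborhood:
    def test_self_exclusion_and_first_occurrence_dedup(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        subjects = [
            SELF.replace(" ", "_"),
            "Rhodospirillum_rubrum",
            "Rhodospirillum_rubrum",
            "Escherichia_coli",
        ]
        hits = [make_hit("q1", s, i + 1) for i, s in enumerate(subjects)]
        nb = build_neighborhood(hits, small_taxonomy, cfg)
        assert [s[0] for s in nb.species_seq] == ["Rhodospirillum rubrum", "Escherichia coli"]

    def test_all_self_hits_give_empty_sequence(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        hits = [make_hit("q1", SELF.replace(" ", "_"), i + 1) for i in range(3)]
        nb = build_neighborhood(hits, small_taxonomy, cfg)
        assert nb.species_seq == ()

    def test_matches_independent_one_pass_scan_on_50_hits(self, small_taxonomy):
        import numpy as np

        cfg = ClassifierConfig(self_species=SELF)
        rng = np.random.default_rng(5)
        keys = list(small_taxonomy)
        subjects = [keys[int(rng.integers(len(keys)))] for _ in range(50)]
        hits = [make_hit("q1", s, i + 1) for i, s in enumerate(subjects)]
        nb = build_neighborhood(hits, small_taxonomy, cfg)
        expected = first_occurrence_scan(
            [small_taxonomy[s].species for s in subjects], SELF
        )
        assert [s[0] for s in nb.species_seq] == expected

    def test_unresolvable_subject_lists_offenders(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        hits = [make_hit("q1", "NOSUCH_1", 1), make_hit("q1", "NOSUCH_2", 2)]
        with pytest.raises(UnresolvableSubjectError, match="NOSUCH_1, NOSUCH_2"):
            build_neighborhood(hits, small_taxonomy, cfg)
        nb = build_neighborhood(hits, small_taxonomy, cfg, lenient=True)
        assert nb.species_seq == ()


CLASSIFY_CASES = [
    # six family species in the top eight -> ancestral high
    ("FFFFFFXX", ("ancestral", "high")),
    # ten species all outside the focal order -> hgt high
    ("XXXXXXXXXX", ("hgt", "high")),
    # short list: all but one in the order -> ancestral high
    ("OOOX", ("ancestral", "high")),
    # family species at rank 6: hgt-medium and ancestral-low conflict
    ("XXXXXFXX", ("unassigned", "none")),
    # four family in the top eight -> ancestral medium
    ("FFFFXXXX", ("ancestral", "medium")),
    # family only at rank 10: fails hgt-high and ancestral-low -> hgt medium
    ("XXXXXXXXXF", ("hgt", "medium")),
    # no family in the genus-removed top 8, but order members block hgt-high/med
    ("OXXXXXXXXX", ("hgt", "low")),
    # empty neighborhood -> unassigned
    ("", ("unassigned", "none")),
    # hits only to other focal-genus genomes -> unassigned
    ("GG", ("unassigned", "none")),
]


class TestClassifyAncestry:
    @pytest.mark.parametrize("letters,expected", CLASSIFY_CASES)
    def test_rule_table_on_hand_evaluated_neighborhoods(self, cfg, letters, expected):
        call = classify_ancestry(neighborhood_from_letters(letters), cfg)
        assert (call.category, call.confidence) == expected

    def test_unassigned_iff_confidence_none(self, cfg):
        for letters, _ in CLASSIFY_CASES:
            call = classify_ancestry(neighborhood_from_letters(letters), cfg)
            assert (call.category == "unassigned") == (call.confidence == "none")

    def test_genus_counts_toward_ancestral_tallies_by_default(self):
        on = ClassifierConfig(self_species=SELF, count_focal_genus_in_ancestral=True)
        off = ClassifierConfig(self_species=SELF, count_focal_genus_in_ancestral=False)
        letters = list("GGFFXXXX")  # 4 family members only when genus counts
        assert classify_membership_sequence(letters, on)[0:2] == ("ancestral", "medium")
        assert classify_membership_sequence(letters, off)[0:2] != ("ancestral", "medium")

    def test_inwindow_genus_exclusion_lets_genus_consume_window_slots(self):
        pre = ClassifierConfig(self_species=SELF, genus_exclusion="prefilter")
        inw = ClassifierConfig(self_species=SELF, genus_exclusion="inwindow")
        # leading genus hits shift the family species within the
        # medium-hgt window only under prefilter semantics
        letters = list("GGXXXFXXXXXX")
        assert classify_membership_sequence(letters, pre)[0:2] == ("ancestral", "low")
        # inwindow: genus occupies slots; top-5 xg window sees no order -> but
        # family at rank 6 is still inside the low-anc top 8 -> conflict
        assert classify_membership_sequence(letters, inw)[0:2] == ("unassigned", "none")


class TestExhaustiveSmall:
    def test_low_tier_rules_are_mutually_exclusive(self, cfg):
        """Ancestral-low and hgt-low read the same genus-removed top-8 window
        for >=1 vs 0 family species, so both can never hold; the high tier is
        exclusive on full-length windows given the database's two other
        focal-genus genomes."""
        for n in range(0, 9):
            for letters in itertools.product("GFOX", repeat=n):
                c = literal_conditions(letters)
                assert not (c["anc_low"] and c["hgt_low"])
                if n >= 8 and letters.count("G") <= 2:
                    assert not (c["anc_high"] and c["hgt_high"])

    def test_classifier_matches_literal_oracle_up_to_length_8(self, cfg):
        for n in range(0, 9):
            for letters in itertools.product("GFOX", repeat=n):
                got = classify_membership_sequence(letters, cfg)[:2]
                assert got == literal_ancestry(letters), letters


@st.composite
def membership_seq(draw):
    return draw(st.lists(st.sampled_from("GFOX"), min_size=0, max_size=14))


_RANK = {"hgt": 0, "unassigned": 1, "ancestral": 2}


class TestProperties:
    @given(membership_seq())
    @settings(max_examples=300, deadline=None)
    def test_prepending_family_never_moves_call_toward_hgt(self, cfg, seq):
        before = classify_membership_sequence(seq, cfg)[0]
        after = classify_membership_sequence(["F"] + seq, cfg)[0]
        assert _RANK[after] >= _RANK[before]

    @given(membership_seq())
    @settings(max_examples=200, deadline=None)
    def test_deterministic(self, cfg, seq):
        assert classify_membership_sequence(seq, cfg) == classify_membership_sequence(
            seq, cfg
        )


class TestClassifyGenome:
    def test_three_archetype_queries(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        family_keys = [
            k for k, t in small_taxonomy.items()
            if t.family == "Rhodospirillaceae" and t.species != SELF
        ]
        hit_tables = {
            "anc": [make_hit("anc", k, i + 1) for i, k in enumerate(family_keys[:6])],
            "out": [make_hit("out", "Escherichia_coli", 1)],
            "none": [],
        }
        calls = {c.query_id: c for c in classify_genome(hit_tables, small_taxonomy, cfg)}
        assert (calls["anc"].category, calls["anc"].confidence) == ("ancestral", "high")
        assert calls["out"].category == "hgt"
        assert calls["none"].category == "unassigned"

    def test_queries_without_hit_tables_are_unassigned(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        calls = classify_genome({}, small_taxonomy, cfg, all_queries=["orphan"])
        assert [(c.query_id, c.category) for c in calls] == [("orphan", "unassigned")]

    def test_empty_input_gives_empty_call_list(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        assert classify_genome({}, small_taxonomy, cfg) == []

    def test_result_independent_of_query_order(self, small_taxonomy):
        cfg = ClassifierConfig(self_species=SELF)
        tables = {
            "q1": [make_hit("q1", "Escherichia_coli", 1)],
            "q2": [make_hit("q2", "Rhodospirillum_rubrum", 1)],
        }
        reversed_tables = dict(reversed(list(tables.items())))
        assert classify_genome(tables, small_taxonomy, cfg) == classify_genome(
            reversed_tables, small_taxonomy, cfg
        )


class TestSummarizeProportions:
    def test_exact_counts_and_fraction_sum(self, cfg):
        calls = [
            classify_ancestry(neighborhood_from_letters(s, f"q{i}"), cfg)
            for i, s in enumerate(["FFFFFFXX", "XXXXXXXXXX", "FFFFXXXX", ""])
        ]
        summary = summarize_proportions(calls)
        assert summary.counts[("ancestral", "high")] == 1
        assert summary.counts[("hgt", "high")] == 1
        assert summary.counts[("ancestral", "medium")] == 1
        assert summary.counts[("unassigned", "none")] == 1
        assert sum(summary.counts.values()) == 4
        assert abs(sum(summary.fractions.values()) - 1.0) < 1e-12
        assert summary.high_confidence_only() == {"ancestral": 1, "hgt": 1}

    def test_all_unassigned(self, cfg):
        calls = [
            classify_ancestry(neighborhood_from_letters("", f"q{i}"), cfg) for i in range(3)
        ]
        summary = summarize_proportions(calls)
        assert summary.category_fractions() == {
            "ancestral": 0.0,
            "hgt": 0.0,
            "unassigned": 1.0,
        }

    def test_fractions_match_counting_oracle_on_simulated_calls(self, cfg):
        from collections import Counter

        from azohgt.synthetic_data import SimConfig, simulate_hit_tables, simulate_taxonomy

        sim = SimConfig(seed=3, n_genes=500)
        tax = simulate_taxonomy(sim)
        tables, _labels = simulate_hit_tables(sim)
        calls = classify_genome(tables, tax, cfg)
        summary = summarize_proportions(calls)
        brute = Counter((c.category, c.confidence) for c in calls)
        assert summary.counts == dict(brute)
        assert summary.n_total == 500

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_proportions([])
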