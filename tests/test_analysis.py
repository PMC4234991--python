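"""Descendant-closed gene sets, intersections and the resampling null."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

import phenolink as pl
from phenolink.errors import UnsupportedSizeError

from conftest import FOUR_GENES, FOUR_PHENOTYPES


def _kb(obo_text, rows):
    """Tiny knowledge base from (record_id, gene, text, concept_id) rows."""
    onto = pl.parse_obo(obo_text)
    records = [
        pl.AssociationRecord(rid, gene, text, pl.Source.GAD)
        for rid, gene, text, _ in rows
    ]
    table = pl.AssociationTable(records=records, source=pl.Source.GAD)
    links = pl.LinkSet(
        [pl.Link(cid, rid, "matched") for rid, _, _, cid in rows if cid],
        source=pl.Source.GAD,
    )
    return pl.build_knowledgebase(onto, [table], [links])


CHAIN = (
    "[Term]\nid: T:1\nname: parent\n\n"
    "[Term]\nid: T:2\nname: childterm\nis_a: T:1\n\n"
    "[Term]\nid: T:3\nname: otherterm\nis_a: T:1\n"
)


class TestConceptGeneSet:
    def test_descendant_genes_roll_up_to_parent(self):
        kb = _kb(CHAIN, [("r1", "COMT", "childterm x", "T:2")])
        assert pl.concept_gene_set(kb, "T:2") == {"COMT"}
        assert pl.concept_gene_set(kb, "T:1") == {"COMT"}

    def test_unlinked_leaf_is_empty(self):
        kb = _kb(CHAIN, [("r1", "COMT", "childterm x", "T:2")])
        assert pl.concept_gene_set(kb, "T:3") == set()

    def test_multipath_record_counted_once(self):
        diamond = (
            "[Term]\nid: T:1\nname: topterm\n\n"
            "[Term]\nid: T:2\nname: lefterm\nis_a: T:1\n\n"
            "[Term]\nid: T:3\nname: rightterm\nis_a: T:1\n\n"
            "[Term]\nid: T:4\nname: bottomterm\nis_a: T:2\nis_a: T:3\n"
        )
        kb = _kb(
            diamond,
            [("r1", "COMT", "bottomterm a", "T:4"), ("r2", "COMT", "x", "T:2")],
        )
        assert pl.concept_gene_set(kb, "T:1") == {"COMT"}

    def test_monotone_under_ancestor_relation(self, worked_kb):
        onto = worked_kb.ontology
        for cid in list(onto.graph.nodes):
            child_genes = pl.concept_gene_set(worked_kb, cid)
            for anc in pl.ancestors(onto, cid):
                assert pl.concept_gene_set(worked_kb, anc) >= child_genes


class TestIntersectGenes:
    def test_planted_four_gene_overlap(self, worked_kb):
        res = pl.intersect_genes(worked_kb, FOUR_PHENOTYPES)
        assert res.common_genes == FOUR_GENES
        assert res.k_observed == 4
        for cid in FOUR_PHENOTYPES:
            assert len(res.per_concept_genes[cid]) == 100
            assert res.common_genes <= res.per_concept_genes[cid]

    def test_single_concept_is_identity(self, worked_kb):
        cid = FOUR_PHENOTYPES[0]
        res = pl.intersect_genes(worked_kb, [cid])
        assert res.common_genes == pl.concept_gene_set(worked_kb, cid)

    def test_disjoint_concepts_give_empty(self):
        kb = _kb(
            CHAIN,
            [("r1", "COMT", "a", "T:2"), ("r2", "HTR2A", "b", "T:3")],
        )
        res = pl.intersect_genes(kb, ["T:2", "T:3"])
        assert res.common_genes == set() and res.k_observed == 0

    def test_permutation_invariant(self, worked_kb):
        fwd = pl.intersect_genes(worked_kb, FOUR_PHENOTYPES)
        rev = pl.intersect_genes(worked_kb, FOUR_PHENOTYPES[::-1])
        assert fwd.common_genes == rev.common_genes
        assert fwd.per_concept_genes == rev.per_concept_genes

    def test_adding_a_concept_never_grows_the_overlap(self, worked_kb):
        partial = pl.intersect_genes(worked_kb, FOUR_PHENOTYPES[:2])
        full = pl.intersect_genes(worked_kb, FOUR_PHENOTYPES)
        assert full.common_genes <= partial.common_genes

    def test_argument_errors(self, worked_kb):
        with pytest.raises(ValueError):
            pl.intersect_genes(worked_kb, [])
        with pytest.raises(ValueError):
            pl.intersect_genes(worked_kb, [FOUR_PHENOTYPES[0]] * 2)


class TestExactOverlapNull:
    def test_k_zero_is_certain(self):
        assert pl.exact_overlap_null([3, 5, 2], 12, 0) == 1.0

    def test_two_set_closed_form(self):
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        assert pl.exact_overlap_null([5, 5], 10, 5) == pytest.approx(1 / 252)

    def test_three_set_enumeration_matches_hand_value(self):
        # chain of hypergeometric overlaps computed by hand: 49/225
        assert pl.exact_overlap_null([2, 2, 2], 6, 1) == pytest.approx(49 / 225)

    def test_enumeration_consistent_with_closed_form_at_m2(self):
        for sizes, u, k in [((3, 4), 8, 2), ((5, 5), 10, 3), ((2, 6), 9, 1)]:
            brute = _enumerate_two(sizes, u, k)
            assert pl.exact_overlap_null(list(sizes), u, k) == pytest.approx(brute)

    def test_refuses_large_universe_for_many_sets(self):
        with pytest.raises(UnsupportedSizeError):
            pl.exact_overlap_null([5, 5, 5], 13, 2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pl.exact_overlap_null([], 10, 1)
        with pytest.raises(ValueError):
            pl.exact_overlap_null([11], 10, 1)
        with pytest.raises(ValueError):
            pl.exact_overlap_null([2, 2], 10, -1)


def _enumerate_two(sizes, u, k):
    from itertools import combinations

    hits = total = 0
    for s1 in combinations(range(u), sizes[0]):
        for s2 in combinations(range(u), sizes[1]):
            total += 1
            if len(set(s1) & set(s2)) >= k:
                hits += 1
    return hits / total


class TestEmpiricalPValue:
    def test_zero_overlap_succeeds_immediately(self):
        kb = _kb(
            CHAIN,
            [("r1", "COMT", "a", "T:2"), ("r2", "HTR2A", "b", "T:3")],
        )
        res = pl.empirical_pvalue(kb, ["T:2", "T:3"], pl.PValueParams(seed=0))
        assert res.k_observed == 0
        assert res.trials_run == 1 and res.p_estimate == 1.0
        assert not res.is_bound

    def test_worked_example_bound(self, worked_kb):
        params = pl.PValueParams(max_trials=1000, seed=5)
        res = pl.empirical_pvalue(worked_kb, FOUR_PHENOTYPES, params)
        assert res.k_observed == 4
        assert res.is_bound and res.successes == 0
        assert res.trials_run == 1000
        assert res.p_estimate == pytest.approx(0.001)

    def test_same_seed_identical_result(self, worked_kb):
        params = pl.PValueParams(max_trials=50, seed=9, early_stop=False)
        a = pl.empirical_pvalue(worked_kb, FOUR_PHENOTYPES[:2], params)
        b = pl.empirical_pvalue(worked_kb, FOUR_PHENOTYPES[:2], params)
        assert a == b

    def test_result_invariants(self, worked_kb):
        for seed in (1, 2, 3):
            params = pl.PValueParams(max_trials=30, seed=seed, early_stop=False)
            res = pl.empirical_pvalue(worked_kb, FOUR_PHENOTYPES[:2], params)
            assert 0 <= res.successes <= res.trials_run <= 30
            assert 0 < res.p_estimate <= 1

    def test_early_stop_reports_one_over_trials(self):
        # k_observed = 1 with two identical singleton sets out of 3 genes:
        # success probability 1/3 per trial, so a success arrives quickly
        kb = _kb(
            CHAIN,
            [
                ("r1", "COMT", "a", "T:2"),
                ("r2", "COMT", "b", "T:3"),
                ("r3", "HTR2A", "c", None),
                ("r4", "SLC6A3", "d", None),
            ],
        )
        res = pl.empirical_pvalue(
            kb, ["T:2", "T:3"], pl.PValueParams(max_trials=1000, seed=1)
        )
        assert not res.is_bound
        assert res.p_estimate == pytest.approx(1 / res.trials_run)

    def test_sample_size_larger_than_universe_rejected(self):
        kb = _kb(
            CHAIN,
            [("r1", "COMT", "a", "T:2"), ("r2", "COMT", "b", "T:2")],
        )
        # closure of T:1 has 1 distinct gene; universe has 1 gene -> fine
        pl.empirical_pvalue(kb, ["T:1"], pl.PValueParams(max_trials=2, seed=0))
        # association_rows mode wants 2 rows from a 2-row pool -> fine too
        pl.empirical_pvalue(
            kb,
            ["T:1"],
            pl.PValueParams(max_trials=2, seed=0, sampling_unit="association_rows"),
        )

    def test_calibration_m2_against_hypergeometric(self):
        # sets of 6 and 5 genes sharing exactly 2, out of a 12-gene universe
        kb = overlap_kb(CHAIN, {"T:2": range(6), "T:3": range(4, 9)}, 12)
        exact = pl.exact_overlap_null([6, 5], 12, 2)
        n_trials = 4000
        res = pl.empirical_pvalue(
            kb,
            ["T:2", "T:3"],
            pl.PValueParams(max_trials=n_trials, seed=17, early_stop=False),
        )
        assert res.k_observed == 2
        freq = res.successes / res.trials_run
        se = math.sqrt(exact * (1 - exact) / n_trials)
        assert abs(freq - exact) <= 3 * se

    def test_calibration_m3_against_enumeration(self):
        # sets of 4, 4, 3 genes sharing exactly 2, out of a 10-gene universe
        obo = CHAIN + "\n[Term]\nid: T:4\nname: fourthterm\nis_a: T:1\n"
        kb = overlap_kb(
            obo,
            {"T:2": [0, 1, 2, 3], "T:3": [0, 1, 4, 5], "T:4": [0, 1, 6]},
            10,
        )
        exact = pl.exact_overlap_null([4, 4, 3], 10, 2)
        n_trials = 4000
        res = pl.empirical_pvalue(
            kb,
            ["T:2", "T:3", "T:4"],
            pl.PValueParams(max_trials=n_trials, seed=23, early_stop=False),
        )
        assert res.k_observed == 2
        freq = res.successes / res.trials_run
        se = math.sqrt(exact * (1 - exact) / n_trials)
        assert abs(freq - exact) <= 3 * se


def overlap_kb(obo_text, assignment, universe_size):
    """KB whose leaf concepts carry exactly the given gene-index sets."""
    rows = []
    rid = 0
    for cid, idxs in assignment.items():
        for i in idxs:
            rows.append((f"r{rid}", f"G{i:03d}", f"t{rid}", cid))
            rid += 1
    linked = {i for idxs in assignment.values() for i in idxs}
    for i in range(universe_size):
        if i not in linked:
            rows.append((f"r{rid}", f"G{i:03d}", f"t{rid}", None))
            rid += 1
    return _kb(obo_text, rows)
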