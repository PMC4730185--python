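"""Consensus filter, combined metric, overlaps, and pathway-group ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirnet.gsea import GseaResult
from mirnet.integrate import (
    PathwayGroupRow,
    combined_metric,
    consensus_filter,
    consolidate_pathways,
    normalize_scores,
    order_categories,
    rank_pathway_groups,
    select_relevant_targets,
    target_overlaps,
)
from mirnet.io_core import PathwayHierarchy, ValidationError


class TestConsensusFilter:
    def test_significant_in_both_selected(self):
        decisions = consensus_filter(
            {"A": {"m": 5e-4}, "B": {"m": 6e-4}}, threshold=1e-3)
        assert decisions[0].selected

    def test_significant_in_one_rejected(self):
        decisions = consensus_filter(
            {"A": {"m": 5e-4}, "B": {"m": 0.22}}, threshold=1e-3)
        assert not decisions[0].selected

    def test_threshold_strict(self):
        decisions = consensus_filter(
            {"A": {"m": 1e-3}, "B": {"m": 1e-4}}, threshold=1e-3)
        assert not decisions[0].selected

    def test_empty_candidates(self):
        assert consensus_filter({"A": {}, "B": {}}) == []

    def test_one_sided_reporting_rejected(self):
        with pytest.raises(ValidationError, match="one program only"):
            consensus_filter({"A": {"m": 0.1}, "B": {}})

    @given(st.floats(min_value=1e-6, max_value=1e-3, exclude_max=True))
    def test_monotone_in_threshold(self, thr):
        qmaps = {"A": {"m": 4e-4, "n": 2e-5}, "B": {"m": 9e-4, "n": 1e-6}}
        tight = {d.mirna_id for d in consensus_filter(qmaps, thr) if d.selected}
        loose = {d.mirna_id for d in consensus_filter(qmaps, 1e-3) if d.selected}
        assert tight <= loose


class TestNormalizeScores:
    def test_subtract_minimum(self):
        assert normalize_scores({"a": -5.0, "b": -2.0, "c": 0.0}) == {
            "a": 0.0, "b": 3.0, "c": 5.0}

    def test_all_equal_become_zero(self):
        assert normalize_scores({"a": 7.0, "b": 7.0}) == {"a": 0.0, "b": 0.0}

    def test_single_gene(self):
        assert normalize_scores({"a": 3.0}) == {"a": 0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            normalize_scores({})


class TestCombinedMetric:
    def test_product_values(self):
        lst = combined_metric({"a": 0.5, "b": -0.5, "c": 0.9},
                              {"a": 2.0, "b": 2.0})
        scores = dict(zip(lst.genes, lst.scores))
        assert scores == {"a": 1.0, "b": -1.0, "c": 0.0}

    def test_missing_prediction_scores_zero_metric(self):
        lst = combined_metric({"a": 0.99}, {"a": 0.0})
        assert lst.scores[0] == 0.0

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            combined_metric({"a": 0.5}, {"zzz": 1.0})

    def test_order_invariant_to_constant_score_shift(self):
        rng = np.random.default_rng(0)
        neg_corr = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        raw = {f"g{i}": float(v) for i, v in
               enumerate(rng.normal(100, 10, size=30))}
        shifted = {g: s + 55.5 for g, s in raw.items()}
        a = combined_metric(neg_corr, normalize_scores(raw))
        b = combined_metric(neg_corr, normalize_scores(shifted))
        assert list(a.genes) == list(b.genes)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)


class TestSelectRelevantTargets:
    de = pd.DataFrame(
        {
            "fold_change": [-2.0, 2.0, -2.0, -1.2],
            "q": [0.01, 0.01, 0.2, 0.01],
            "is_de": [True, True, False, False],
        },
        index=["down_de", "up_de", "down_weak", "small_fc"],
    )

    def test_up_mirna_keeps_down_regulated_de_core_genes(self):
        out = select_relevant_targets("up", self.de,
                                      ["down_de", "up_de", "down_weak", "small_fc"])
        assert out == ["down_de"]

    def test_down_mirna_keeps_up_regulated(self):
        out = select_relevant_targets("down", self.de, ["down_de", "up_de"])
        assert out == ["up_de"]

    def test_non_de_core_gene_excluded(self):
        assert select_relevant_targets("up", self.de, ["down_weak"]) == []

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValidationError):
            select_relevant_targets("sideways", self.de, [])


class TestTargetOverlaps:
    def test_two_list_hand_example(self):
        res = target_overlaps({"m1": ["A", "B"], "m2": ["B", "C"]})
        assert res.count("m1") == 1
        assert res.count("m2") == 1
        assert res.count("m1", "m2") == 1
        assert res.union_size == 3

    def test_three_identical_lists(self):
        genes = [f"g{i}" for i in range(7)]
        res = target_overlaps({"a": genes, "b": genes, "c": genes})
        assert res.count("a", "b", "c") == 7
        assert res.count("a") == res.count("a", "b") == 0

    def test_random_lists_match_set_algebra_oracle(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(60)]
        lists = {m: list(rng.choice(universe, size=25, replace=False))
                 for m in ("x", "y", "z")}
        res = target_overlaps(lists)
        sx, sy, sz = (set(lists[m]) for m in ("x", "y", "z"))
        assert res.count("x", "y", "z") == len(sx & sy & sz)
        assert res.count("x", "y") == len((sx & sy) - sz)
        assert res.count("x") == len(sx - sy - sz)
        assert sum(res.regions.values()) == res.union_size == len(sx | sy | sz)


def _result(set_id, q):
    return GseaResult(set_id, 10, 0.5, 1.5, 0.01, q, ("g1",))


HIER = PathwayHierarchy(pd.DataFrame({
    "pathway_id": ["p1", "p2", "p3", "p4"],
    "group_id": ["G1", "G1", "G2", "G3"],
    "category_id": ["C1", "C1", "C1", "C2"],
}))


class TestConsolidatePathways:
    def test_count_and_fdr_range(self):
        rows = consolidate_pathways(
            {"m1": [_result("p1", 0.01), _result("p2", 0.11)]}, HIER, 0.2)
        assert len(rows) == 1
        count, qmin, qmax = rows[0].per_mirna["m1"]
        assert (count, qmin, qmax) == (2, 0.01, 0.11)

    def test_above_threshold_not_counted(self):
        rows = consolidate_pathways({"m1": [_result("p1", 0.25)]}, HIER, 0.2)
        assert rows == []

    def test_unknown_pathway_rejected_by_name(self):
        with pytest.raises(ValidationError, match="ghost"):
            consolidate_pathways({"m1": [_result("ghost", 0.01)]}, HIER)

    def test_no_results_empty(self):
        assert consolidate_pathways({"m1": []}, HIER) == []


class TestRankPathwayGroups:
    def _row(self, group, per_mirna, category="C"):
        return PathwayGroupRow(group, category, per_mirna)

    def test_totals_order_descending(self):
        rows = [
            self._row("g_small", {"m1": (12, 0.01, 0.1)}),
            self._row("g_big", {"m1": (32, 0.01, 0.1)}),
            self._row("g_mid", {"m1": (26, 0.01, 0.1)}),
        ]
        ranked = rank_pathway_groups(rows, ["m1"])
        assert [r.group_id for r in ranked] == ["g_big", "g_mid", "g_small"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_all_panel_flag_breaks_ties(self):
        rows = [
            self._row("g_partial", {"m1": (3, 0.01, 0.1)}),
            self._row("g_all", {"m1": (1, 0.05, 0.05), "m2": (1, 0.05, 0.05),
                                "m3": (1, 0.05, 0.05)}),
        ]
        ranked = rank_pathway_groups(rows, ["m1", "m2", "m3"])
        assert ranked[0].group_id == "g_all"

    def test_min_fdr_breaks_remaining_ties(self):
        rows = [
            self._row("g_late", {"m1": (2, 0.10, 0.15)}),
            self._row("g_early", {"m1": (2, 0.01, 0.15)}),
        ]
        ranked = rank_pathway_groups(rows, ["m1"])
        assert ranked[0].group_id == "g_early"

    def test_lexicographic_final_tiebreak_total_order(self):
        rows = [
            self._row("zzz", {"m1": (2, 0.05, 0.05)}),
            self._row("aaa", {"m1": (2, 0.05, 0.05)}),
        ]
        ranked = rank_pathway_groups(rows, ["m1"])
        assert [r.group_id for r in ranked] == ["aaa", "zzz"]
        assert len({r.rank for r in ranked}) == len(ranked)

    def test_stable_across_repeated_runs(self):
        rng = np.random.default_rng(8)
        rows = [
            self._row(f"g{i}", {"m1": (int(rng.integers(1, 5)),
                                       float(rng.uniform(0, 0.2)), 0.2)})
            for i in range(12)
        ]
        first = [r.group_id for r in rank_pathway_groups(rows, ["m1"])]
        for _ in range(5):
            rng.shuffle(rows)
            assert [r.group_id for r in rank_pathway_groups(rows, ["m1"])] == first

    def test_categories_ordered_by_best_group(self):
        rows = [
            PathwayGroupRow("g1", "catB", {"m1": (5, 0.01, 0.1)}),
            PathwayGroupRow("g2", "catA", {"m1": (2, 0.01, 0.1)}),
            PathwayGroupRow("g3", "catB", {"m1": (1, 0.01, 0.1)}),
        ]
        ranked = rank_pathway_groups(rows, ["m1"])
        assert order_categories(ranked) == ["catB", "catA"]
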