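from __future__ import annotations

import itertools

import numpy as np
import pytest

from tfbranch.branch_finder import (
    agglomerate,
    export_newick,
    find_branches,
    flag_heterogeneous_tfs,
)
from tfbranch.similarity_metrics import MetricConfig

from conftest import single_motif_tf
from test_similarity_metrics import _tf, _scores_for


def _units3():
    a = single_motif_tf("A", "1.1.1")
    b = single_motif_tf("B", "1.1.2")
    c = single_motif_tf("C", "1.1.3")
    scores = _scores_for({("A", "B"): 5.0, ("A", "C"): 1.0, ("B", "C"): 1.5})
    return [("1.1.1", [a]), ("1.1.2", [b]), ("1.1.3", [c])], scores


class TestAgglomerate:
    def test_two_units_single_join(self):
        units, scores = _units3()
        tree = agglomerate(units[:2], scores, MetricConfig())
        assert tree.root.height == 5.0
        assert sorted(tree.leaf_labels()) == ["1.1.1", "1.1.2"]
        assert len(tree.merge_log) == 1

    def test_three_units_recomputed_linkage(self):
        # hand enumeration: first join (A,B) at 5; then the {A,B} vs C
        # distribution is {AC=1.0, BC=1.5}, median 1.25 — not an average of
        # previous linkage values
        units, scores = _units3()
        tree = agglomerate(units, scores, MetricConfig())
        assert [s.q2 for s in tree.merge_log] == [5.0, 1.25]
        first = tree.merge_log[0]
        assert set(first.unit_a + first.unit_b) == {"1.1.1", "1.1.2"}

    def test_duplicate_units_join_first(self):
        units, _ = _units3()
        scores = _scores_for({("A", "B"): 2.0, ("A", "C"): 9.0, ("B", "C"): 2.0})
        tree = agglomerate(units, scores, MetricConfig())
        first = tree.merge_log[0]
        assert set(first.unit_a + first.unit_b) == {"1.1.1", "1.1.3"}
        assert first.q2 == 9.0

    def test_all_na_errors(self):
        a = single_motif_tf("A", "1.1.1")
        b = single_motif_tf("B", "1.1.2")
        scores = _scores_for({("A", "B"): float("nan")})
        with pytest.raises(ValueError, match="undefined"):
            agglomerate([("1.1.1", [a]), ("1.1.2", [b])], scores, MetricConfig())


class TestFindBranches:
    def test_whole_class_is_one_branch(self):
        tfs = [single_motif_tf(n, p) for n, p in
               [("A", "3.5.1"), ("B", "3.5.1"), ("C", "3.5.2")]]
        scores = _scores_for({("A", "B"): 4.0, ("A", "C"): 3.5, ("B", "C"): 3.2})
        part = find_branches(tfs, scores, MetricConfig())
        assert len(part.branches) == 1
        b = part.branches[0]
        assert b.level == "class" and b.members == ("3.5",)
        assert b.internal_q2 == pytest.approx(3.5)

    def test_greedy_family_merging(self):
        # four single-TF families; f1-f2 and f3-f4 similar, cross pairs not
        tfs = [single_motif_tf(f"T{i}", f"1.1.{i}") for i in range(1, 5)]
        vals = {("T1", "T2"): 6.0, ("T3", "T4"): 5.0}
        for a, b in itertools.combinations("1234", 2):
            vals.setdefault((f"T{a}", f"T{b}"), 1.0)
        part = find_branches(tfs, _scores_for(vals), MetricConfig())
        members = sorted(b.members for b in part.branches)
        assert members == [("1.1.1", "1.1.2"), ("1.1.3", "1.1.4")]
        assert all(b.level == "family" for b in part.branches)
        assert all(s.q2 > 3.0 for s in part.merge_log)

    def test_internally_similar_family_still_merges(self):
        # a family above threshold internally joins an even more similar
        # sister instead of being finalized early
        f1 = [single_motif_tf("A", "1.1.1"), single_motif_tf("B", "1.1.1")]
        f2 = [single_motif_tf("C", "1.1.2")]
        f3 = [single_motif_tf("D", "1.1.3")]
        scores = _scores_for(
            {
                ("A", "B"): 3.99,  # f1 internal, already above thr
                ("A", "C"): 6.0,
                ("B", "C"): 5.0,  # f1-f2 inter Q2 = 5.5
                ("A", "D"): 0.1,
                ("B", "D"): 0.1,
                ("C", "D"): 0.1,
            }
        )
        # class intra Q2 = median{3.99, 6, 5, 0.1, 0.1, 0.1} = 2.045 < 3
        part = find_branches(f1 + f2 + f3, scores, MetricConfig())
        members = sorted(b.members for b in part.branches)
        assert ("1.1.1", "1.1.2") in members
        assert part.merge_log[0].q2 == pytest.approx(5.5)

    def test_all_dissimilar_gives_singletons(self):
        tfs = [single_motif_tf(f"T{i}", "1.1.1.1") for i in range(4)]
        vals = {(f"T{i}", f"T{j}"): 0.0 for i in range(4) for j in range(i + 1, 4)}
        part = find_branches(tfs, _scores_for(vals), MetricConfig())
        assert len(part.branches) == 4
        assert all(b.level == "tf" and b.size == 1 for b in part.branches)

    def test_branches_never_span_classes(self):
        tfs = [single_motif_tf("A", "1.1.1"), single_motif_tf("B", "1.2.1")]
        scores = _scores_for({("A", "B"): 9.0})
        part = find_branches(tfs, scores, MetricConfig())
        assert len(part.branches) == 2

    def test_partition_covers_every_tf_once(self, planted, planted_table):
        coll, _ = planted
        part = find_branches(coll.tfs, planted_table, MetricConfig())
        part.validate(coll.tfs)  # raises on violation
        assignment = part.as_partition()
        assert len(assignment) == len(coll.tfs)

    def test_merge_log_all_above_threshold(self, planted, planted_table):
        coll, _ = planted
        cfg = MetricConfig()
        part = find_branches(coll.tfs, planted_table, cfg)
        multi = [b for b in part.branches if len(b.members) > 1]
        assert multi, "expected at least one merged branch"
        assert all(s.q2 > cfg.thr for s in part.merge_log)

    def test_determinism(self, planted, planted_table):
        coll, _ = planted
        p1 = find_branches(coll.tfs, planted_table, MetricConfig())
        p2 = find_branches(list(reversed(coll.tfs)), planted_table, MetricConfig())
        as_sets = lambda p: sorted(sorted(b.tf_names) for b in p.branches)
        assert as_sets(p1) == as_sets(p2)

    def test_class_annotation_required(self):
        tf = single_motif_tf("A", "1")
        with pytest.raises(ValueError, match="class level"):
            find_branches([tf], _scores_for({}), MetricConfig())

    def test_na_blocks_merge_but_keeps_singleton(self):
        # two sister families, one with a lone single-motif TF: inter is a
        # real value, intra of the singleton is NA; partition still covers it
        a = single_motif_tf("A", "1.1.1")
        b = single_motif_tf("B", "1.1.2")
        scores = _scores_for({("A", "B"): 0.5})
        part = find_branches([a, b], scores, MetricConfig())
        assert sorted(t for b_ in part.branches for t in b_.tf_names) == ["A", "B"]


class TestHeterogeneousTfs:
    def test_similar_motifs_not_flagged(self):
        x = _tf("X", 2)
        scores = _scores_for({("X.m0", "X.m1"): 8.0})
        assert flag_heterogeneous_tfs([x], scores, MetricConfig()) == []

    def test_dissimilar_motifs_flagged(self):
        x = _tf("X", 2)
        scores = _scores_for({("X.m0", "X.m1"): 1.2})
        assert flag_heterogeneous_tfs([x], scores, MetricConfig()) == [("X", 1.2)]

    def test_single_motif_never_flagged(self):
        assert flag_heterogeneous_tfs([_tf("X", 1)], _scores_for({}), MetricConfig()) == []

    def test_sorted_ascending(self):
        x, y = _tf("X", 2), _tf("Y", 2)
        scores = _scores_for({("X.m0", "X.m1"): 2.0, ("Y.m0", "Y.m1"): 0.5})
        assert flag_heterogeneous_tfs([x, y], scores, MetricConfig()) == [
            ("Y", 0.5),
            ("X", 2.0),
        ]


class TestNewick:
    def test_two_leaf_tree(self):
        units, scores = _units3()
        text = export_newick(agglomerate(units[:2], scores, MetricConfig()))
        assert text.endswith(";")
        assert "1.1.1" in text and "1.1.2" in text

    def test_round_trip_parse(self):
        import dendropy

        units, scores = _units3()
        text = export_newick(agglomerate(units, scores, MetricConfig()))
        tree = dendropy.Tree.get(data=text.replace("[&&reversal]", ""),
                                 schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            "1.1.1", "1.1.2", "1.1.3"
        }

    def test_edge_lengths_nonnegative(self):
        units, scores = _units3()
        text = export_newick(agglomerate(units, scores, MetricConfig()))
        import re

        lengths = [float(x) for x in re.findall(r":([\d.eE+-]+)", text)]
        assert all(x >= 0 for x in lengths)

    def test_reversal_clamped_and_flagged(self):
        # children merge at a Q2 above one child's internal Q2
        a = [_tf("A1", 1, "1.1.1"), _tf("A2", 1, "1.1.1")]
        b = [_tf("B1", 1, "1.1.2")]
        scores = _scores_for(
            {
                ("A1.m0", "A2.m0"): 3.99,  # internal Q2 of unit 1
                ("A1.m0", "B1.m0"): 6.0,
                ("A2.m0", "B1.m0"): 5.0,  # merge Q2 = 5.5 > 3.99
            }
        )
        tree = agglomerate([("1.1.1", a), ("1.1.2", b)], scores, MetricConfig())
        assert tree.root.reversal
        text = export_newick(tree)
        assert "[&&reversal]" in text
        assert "1.1.1:0" in text  # clamped edge


# --------------------------------------------------------------------------- #
# Greedy vs exhaustive merge-order oracle
# --------------------------------------------------------------------------- #


def _exhaustive_partitions(unit_scores: dict, labels: list[str], thr: float):
    """All final partitions reachable by repeatedly merging an argmax pair
    (exploring every argmax tie), recomputing the median over the full
    value multiset between clusters after each merge."""

    def inter(ca, cb):
        vals = [
            unit_scores[frozenset((x, y))]
            for x in ca
            for y in cb
        ]
        return float(np.median(vals))

    results = set()

    def step(clusters):
        pairs = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                q2 = inter(clusters[i], clusters[j])
                if q2 > thr:
                    pairs.append((q2, i, j))
        if not pairs:
            results.add(frozenset(frozenset(c) for c in clusters))
            return
        best = max(p[0] for p in pairs)
        for q2, i, j in pairs:
            if q2 == best:
                merged = [c for k, c in enumerate(clusters) if k not in (i, j)]
                merged.append(clusters[i] | clusters[j])
                step(merged)

    step([frozenset([l]) for l in labels])
    return results


@pytest.mark.parametrize("n_units,seed", [(4, 0), (5, 1), (6, 2), (6, 3), (5, 4)])
def test_greedy_matches_exhaustive_without_ties(n_units, seed):
    rng = np.random.default_rng(seed)
    labels = [f"1.1.{i}" for i in range(1, n_units + 1)]
    names = [f"T{i}" for i in range(1, n_units + 1)]
    # distinct random values => no ties
    vals = rng.permutation(np.linspace(0.5, 6.5, n_units * (n_units - 1) // 2))
    unit_scores = {}
    pair_scores = {}
    for k, (a, b) in enumerate(itertools.combinations(names, 2)):
        unit_scores[frozenset((a, b))] = float(vals[k])
        pair_scores[(a, b)] = float(vals[k])
    tfs = [single_motif_tf(n, p) for n, p in zip(names, labels)]
    # keep the class from resolving as a single branch: push median below thr
    part = find_branches(tfs, _scores_for(pair_scores), MetricConfig())
    got = frozenset(frozenset(b.tf_names) for b in part.branches)
    class_q2 = float(np.median(list(unit_scores.values())))
    if class_q2 > 3.0:
        assert got == frozenset({frozenset(names)})
        return
    expected = _exhaustive_partitions(unit_scores, names, 3.0)
    assert len(expected) == 1, "tie-free input must have a unique outcome"
    assert got == next(iter(expected))
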