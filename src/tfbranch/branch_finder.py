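"""Branch decomposition of the TF hierarchy and similarity trees.

A branch is a maximal union of sister hierarchy units whose TFs are
mostly pairwise similar: starting at the class level, units whose
internal median (Q2) TF-pair similarity exceeds the threshold stand as
branches; otherwise their child units are merged greedily — repeatedly
joining the pair of current clusters with the highest inter-cluster Q2
while it exceeds the threshold, recomputing Q2 over the full TF-pair
distribution after every merge — and unresolved units recurse one level
down (families, then subfamilies, then single TFs).  The result is a
partition: every TF lands in exactly one branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from tfbranch.motif_io import TFRecord
from tfbranch.motif_compare import ScoreTable
from tfbranch.similarity_metrics import (
    MetricConfig,
    set_similarity,
    tf_heterogeneity,
)

__all__ = [
    "Branch",
    "BranchPartition",
    "SimilarityTree",
    "TreeNode",
    "agglomerate",
    "find_branches",
    "flag_heterogeneous_tfs",
    "export_newick",
]

LEVEL_OF_DEPTH = {2: "class", 3: "family", 4: "subfamily", 5: "tf"}


@dataclass
class Branch:
    """A maximal set of sister units with internally similar motifs."""

    members: tuple[str, ...]  # unit labels (dotted paths, or "tf:NAME")
    tf_names: tuple[str, ...]
    internal_q2: float  # nan when undefined
    level: str  # "class" | "family" | "subfamily" | "tf"

    @property
    def size(self) -> int:
        return len(self.tf_names)


@dataclass
class MergeStep:
    level: str
    parent: str
    unit_a: tuple[str, ...]
    unit_b: tuple[str, ...]
    q2: float


@dataclass
class BranchPartition:
    branches: list[Branch]
    merge_log: list[MergeStep] = field(default_factory=list)

    def tf_names(self) -> list[str]:
        return [name for b in self.branches for name in b.tf_names]

    def as_partition(self) -> dict[str, int]:
        """Map every TF name to the index of its branch."""
        out: dict[str, int] = {}
        for i, b in enumerate(self.branches):
            for name in b.tf_names:
                if name in out:
                    raise ValueError(f"TF {name!r} appears in two branches")
                out[name] = i
        return out

    def validate(self, records: Sequence[TFRecord]) -> None:
        got = sorted(self.tf_names())
        want = sorted(tf.name for tf in records)
        if got != want:
            raise ValueError("branches do not partition the TF universe")


# --------------------------------------------------------------------------- #
# Agglomerative similarity tree
# --------------------------------------------------------------------------- #


@dataclass
class TreeNode:
    label: str
    height: float  # merge Q2 for internal nodes, internal Q2 for leaves
    children: tuple["TreeNode", ...] = ()
    reversal: bool = False  # child was internally less similar than the merge

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class SimilarityTree:
    root: TreeNode
    merge_log: list[MergeStep] = field(default_factory=list)

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]


def _sort_key(labels: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(sorted(labels))


def _inter_q2(
    a: Sequence[TFRecord], b: Sequence[TFRecord], scores: ScoreTable, cfg: MetricConfig
) -> float:
    return set_similarity(a, b, scores, cfg).q2


def agglomerate(
    units: Sequence[tuple[str, Sequence[TFRecord]]],
    scores: ScoreTable,
    cfg: MetricConfig,
) -> SimilarityTree:
    """Build the full similarity tree over labelled TF sets.

    The scheme is agglomerative pairing of the currently most similar
    clusters, but the linkage is the median (Q2) of the full TF-pair score
    distribution between the merged sets, recomputed after every merge —
    not an average of previous linkage values.  Ties break lexicographically
    on member labels.  The tree is completed regardless of any threshold.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units to agglomerate")
    clusters: list[tuple[tuple[str, ...], list[TFRecord], TreeNode]] = []
    for label, tfs in units:
        tfs = list(tfs)
        intra = set_similarity(tfs, None, scores, cfg).q2
        clusters.append(([label], tfs, TreeNode(label=label, height=intra)))
    clusters = [(tuple(ls), tfs, node) for ls, tfs, node in clusters]

    log: list[MergeStep] = []
    any_defined = False
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                q2 = _inter_q2(clusters[i][1], clusters[j][1], scores, cfg)
                key = (
                    -(q2 if not math.isnan(q2) else -math.inf),
                    _sort_key(clusters[i][0]),
                    _sort_key(clusters[j][0]),
                )
                if best is None or key < best[0]:
                    best = (key, i, j, q2)
        assert best is not None
        _, i, j, q2 = best
        if not math.isnan(q2):
            any_defined = True
        la, tfa, na = clusters[i]
        lb, tfb, nb = clusters[j]
        merged = TreeNode(
            label=",".join(sorted(la + lb)),
            height=q2,
            children=(na, nb),
            reversal=any(
                not math.isnan(c.height) and not math.isnan(q2) and c.height < q2
                for c in (na, nb)
            ),
        )
        log.append(MergeStep("tree", "", la, lb, q2))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((la + lb, tfa + tfb, merged))
    if not any_defined:
        raise ValueError("all inter-unit similarities are undefined")
    return SimilarityTree(root=clusters[0][2], merge_log=log)


# --------------------------------------------------------------------------- #
# Branch search
# --------------------------------------------------------------------------- #


def _group_children(
    tfs: Sequence[TFRecord], depth: int
) -> dict[str, list[TFRecord]]:
    """Group TFs by their hierarchy prefix of ``depth`` numerals.

    TFs not annotated that deep fall into a pseudo-unit with numeral 0
    appended (the "unclassified" bucket convention).
    """
    out: dict[str, list[TFRecord]] = {}
    for tf in tfs:
        if tf.path.depth >= depth:
            key = tf.path.prefix(depth).dotted
        else:
            key = tf.path.dotted + ".0" * (depth - tf.path.depth)
        out.setdefault(key, []).append(tf)
    return out


def _greedy_merge(
    units: dict[str, list[TFRecord]],
    scores: ScoreTable,
    cfg: MetricConfig,
    level: str,
    parent: str,
    log: list[MergeStep],
) -> list[tuple[tuple[str, ...], list[TFRecord]]]:
    """Merge sister units while the best inter-cluster Q2 exceeds the threshold.

    Undefined (nan) similarities never allow a merge.  Ties break
    lexicographically on sorted member labels, making the procedure
    deterministic.
    """
    clusters: list[tuple[tuple[str, ...], list[TFRecord]]] = [
        ((label,), list(tfs)) for label, tfs in sorted(units.items())
    ]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                q2 = _inter_q2(clusters[i][1], clusters[j][1], scores, cfg)
                if math.isnan(q2) or q2 <= cfg.thr:
                    continue
                key = (-q2, _sort_key(clusters[i][0]), _sort_key(clusters[j][0]))
                if best is None or key < best[0]:
                    best = (key, i, j, q2)
        if best is None:
            break
        _, i, j, q2 = best
        la, tfa = clusters[i]
        lb, tfb = clusters[j]
        log.append(MergeStep(level, parent, la, lb, q2))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((tuple(sorted(la + lb)), tfa + tfb))
    return clusters


def _resolve_unit(
    label: str,
    tfs: list[TFRecord],
    depth: int,
    scores: ScoreTable,
    cfg: MetricConfig,
    log: list[MergeStep],
) -> list[Branch]:
    level = LEVEL_OF_DEPTH[min(depth, 5)]
    intra = set_similarity(tfs, None, scores, cfg)
    q2 = intra.q2
    if not math.isnan(q2) and q2 > cfg.thr:
        return [
            Branch(
                members=(label,),
                tf_names=tuple(tf.name for tf in tfs),
                internal_q2=q2,
                level=level,
            )
        ]
    if depth >= 5 or len(tfs) == 1:
        # a single TF (or a unit we cannot subdivide) becomes a singleton
        # branch; its internal value is the TF motif heterogeneity
        return [
            Branch(
                members=(label,) if len(tfs) > 1 else (f"tf:{tfs[0].name}",),
                tf_names=tuple(tf.name for tf in tfs),
                internal_q2=q2,
                level=level if len(tfs) > 1 else "tf",
            )
        ]
    if depth == 4:
        # descend from subfamily to single TFs
        children = {f"tf:{tf.name}": [tf] for tf in tfs}
        child_depth = 5
    else:
        children = _group_children(tfs, depth + 1)
        child_depth = depth + 1
    if len(children) == 1:
        only_label, only_tfs = next(iter(children.items()))
        return _resolve_unit(only_label, only_tfs, child_depth, scores, cfg, log)
    child_level = LEVEL_OF_DEPTH[min(child_depth, 5)]
    clusters = _greedy_merge(children, scores, cfg, child_level, label, log)
    branches: list[Branch] = []
    for labels, cluster_tfs in clusters:
        if len(labels) > 1:
            branches.append(
                Branch(
                    members=labels,
                    tf_names=tuple(tf.name for tf in cluster_tfs),
                    internal_q2=set_similarity(cluster_tfs, None, scores, cfg).q2,
                    level=child_level,
                )
            )
        else:
            branches.extend(
                _resolve_unit(labels[0], cluster_tfs, child_depth, scores, cfg, log)
            )
    return branches


def find_branches(
    records: Sequence[TFRecord],
    scores: ScoreTable,
    cfg: MetricConfig,
) -> BranchPartition:
    """Partition all TFs into branches, class by class.

    Branches never span classes: the search starts at the class level (a
    superclass never forms a branch) and recurses through families,
    subfamilies, and single TFs.
    """
    records = list(records)
    for tf in records:
        if tf.path.depth < 2:
            raise ValueError(f"TF {tf.name!r} is not annotated to class level")
    log: list[MergeStep] = []
    branches: list[Branch] = []
    for class_label, class_tfs in sorted(_group_children(records, 2).items()):
        branches.extend(_resolve_unit(class_label, class_tfs, 2, scores, cfg, log))
    part = BranchPartition(branches=branches, merge_log=log)
    part.validate(records)
    return part


def flag_heterogeneous_tfs(
    records: Sequence[TFRecord],
    scores: ScoreTable,
    cfg: MetricConfig,
) -> list[tuple[str, float]]:
    """TFs carrying significantly different motifs.

    Returns ``(tf_name, heterogeneity)`` for every multi-motif TF whose
    median within-TF motif-pair score does not exceed the threshold,
    sorted ascending by heterogeneity.
    """
    flagged = []
    for tf in records:
        if tf.n_motifs < 2:
            continue
        het = tf_heterogeneity(tf, scores, cfg)
        if het <= cfg.thr:
            flagged.append((tf.name, het))
    return sorted(flagged, key=lambda x: (x[1], x[0]))


# --------------------------------------------------------------------------- #
# Newick export
# --------------------------------------------------------------------------- #


def _newick_label(label: str) -> str:
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_to_newick(node: TreeNode, parent_height: float | None) -> str:
    height = node.height
    if parent_height is None:
        length = None
    else:
        if math.isnan(height):
            length = 0.0
        else:
            length = max(height - parent_height, 0.0)
    if node.is_leaf:
        body = _newick_label(node.label)
    else:
        inner = ",".join(_node_to_newick(c, height) for c in node.children)
        body = f"({inner})"
        if node.reversal:
            body += "[&&reversal]"
    return body if length is None else f"{body}:{length:.6g}"


def export_newick(tree: SimilarityTree) -> str:
    """Render the similarity tree as Newick text.

    Edge lengths are the drop in Q2 from child to parent, clamped at zero;
    a clamped (reversed) internal edge is annotated with a
    ``[&&reversal]`` comment.
    """
    return _node_to_newick(tree.root, None) + ";"
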