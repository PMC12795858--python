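"""TF-pair, per-TF, and set-level similarity metrics.

Motif-pair scores are aggregated in three stages:

* TF pair: an aggregator (default: max) over the ``N_X x N_Y`` motif-pair
  score distribution of two TFs.
* single TF: motif heterogeneity, the median of its ``N (N - 1) / 2``
  within-TF motif-pair scores (undefined for single-motif TFs).
* TF set pair: the five order statistics Min, Q1, Q2 (median), Q3, Max of
  the TF-pair score distribution, within one set or across two sets.

Undefined values are represented as ``nan`` and never compare above or
below the similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tfbranch.motif_io import TFRecord
from tfbranch.motif_compare import ScoreTable

__all__ = [
    "MetricConfig",
    "SetSimilarity",
    "tf_pair_score",
    "tf_heterogeneity",
    "set_similarity",
    "similarity_matrix",
]

AGGREGATORS = ("max", "median", "min", "q1", "q3")
SET_METRICS = ("min", "q1", "q2", "q3", "max")


@dataclass(frozen=True)
class MetricConfig:
    """Similarity threshold and aggregation choices.

    ``thr`` is the significance threshold on ``-log10(p)`` scores; a value
    is "similar" only under strict ``> thr``.
    """

    thr: float = 3.0
    tf_pair_aggregator: str = "max"
    set_metric: str = "q2"

    def __post_init__(self) -> None:
        if self.thr <= 0:
            raise ValueError("thr must be positive")
        if self.tf_pair_aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.tf_pair_aggregator!r}")
        if self.set_metric not in SET_METRICS:
            raise ValueError(f"unknown set metric {self.set_metric!r}")


@dataclass(frozen=True)
class SetSimilarity:
    """Min/Q1/Q2/Q3/Max of a TF-pair score distribution."""

    min: float
    q1: float
    q2: float
    q3: float
    max: float
    n_pairs: int
    kind: str  # "intra" | "inter"

    @classmethod
    def undefined(cls, kind: str) -> "SetSimilarity":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, 0, kind)

    @classmethod
    def from_values(cls, values: Sequence[float], kind: str) -> "SetSimilarity":
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            return cls.undefined(kind)
        mn, q1, q2, q3, mx = np.percentile(vals, [0, 25, 50, 75, 100])
        return cls(float(mn), float(q1), float(q2), float(q3), float(mx), int(vals.size), kind)

    @property
    def is_defined(self) -> bool:
        return self.n_pairs > 0

    def metric(self, name: str) -> float:
        if name not in SET_METRICS:
            raise ValueError(f"unknown set metric {name!r}")
        return getattr(self, name)


def _aggregate(values: np.ndarray, aggregator: str) -> float:
    if values.size == 0:
        raise ValueError("cannot aggregate an empty score distribution")
    if aggregator == "max":
        return float(values.max())
    if aggregator == "min":
        return float(values.min())
    q = {"q1": 25, "median": 50, "q3": 75}[aggregator]
    return float(np.percentile(values, q))


def tf_pair_score(
    x: TFRecord, y: TFRecord, scores: ScoreTable, cfg: MetricConfig
) -> float:
    """Similarity of two TFs: aggregator over their N_X x N_Y motif-pair scores."""
    return _aggregate(scores.tf_pair_values(x, y), cfg.tf_pair_aggregator)


def tf_heterogeneity(x: TFRecord, scores: ScoreTable, cfg: MetricConfig) -> float:
    """Median of the within-TF motif-pair scores; ``nan`` for a single motif.

    A TF whose heterogeneity does not exceed ``cfg.thr`` carries
    significantly different binding-site motifs.
    """
    if x.n_motifs < 2:
        return float("nan")
    return float(np.median(scores.intra_tf_values(x)))


def set_similarity(
    a: Sequence[TFRecord],
    b: Sequence[TFRecord] | None,
    scores: ScoreTable,
    cfg: MetricConfig,
) -> SetSimilarity:
    """Five-number similarity of one TF set (``b is None``) or two sets.

    Intra-set distributions run over all unordered TF pairs within ``a``
    (``K (K - 1) / 2`` values); inter-set over all ``K x T`` cross pairs.
    A one-TF intra set falls back to that TF's motif heterogeneity
    distribution; with a single motif it is undefined.
    """
    a = list(a)
    if not a:
        raise ValueError("set A must be non-empty")
    if b is None:
        if len(a) == 1:
            tf = a[0]
            if tf.n_motifs < 2:
                return SetSimilarity.undefined("intra")
            return SetSimilarity.from_values(scores.intra_tf_values(tf), "intra")
        vals = [
            tf_pair_score(a[i], a[j], scores, cfg)
            for i in range(len(a))
            for j in range(i + 1, len(a))
        ]
        return SetSimilarity.from_values(vals, "intra")
    b = list(b)
    if not b:
        raise ValueError("set B must be non-empty")
    vals = [tf_pair_score(x, y, scores, cfg) for x in a for y in b]
    return SetSimilarity.from_values(vals, "inter")


def similarity_matrix(
    units: Sequence[Sequence[TFRecord]],
    scores: ScoreTable,
    cfg: MetricConfig,
) -> list[list[SetSimilarity]]:
    """Square symmetric matrix of set similarities.

    Diagonal cells hold intra-set metrics, off-diagonal cells inter-set
    metrics.  Units must be pairwise disjoint in TF names.
    """
    units = [list(u) for u in units]
    seen: set[str] = set()
    for u in units:
        names = {tf.name for tf in u}
        if names & seen:
            raise ValueError(f"units overlap in TFs: {sorted(names & seen)}")
        seen |= names
    n = len(units)
    mat: list[list[SetSimilarity | None]] = [[None] * n for _ in range(n)]
    for i in range(n):
        mat[i][i] = set_similarity(units[i], None, scores, cfg)
        for j in range(i + 1, n):
            s = set_similarity(units[i], units[j], scores, cfg)
            mat[i][j] = mat[j][i] = s
    return mat  # type: ignore[return-value]
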