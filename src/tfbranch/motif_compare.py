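"""Pairwise motif comparison.

Two motifs are aligned gaplessly over all offsets (and optionally both
strands) with overlap >= ``min_overlap``; each aligned column pair is
scored by the Pearson correlation of the two frequency 4-vectors and the
alignment score is the sum over overlapping columns.  Significance of the
best alignment is assessed against a null of motifs assembled from
database columns, either by Monte-Carlo permutation or by an exact
discretized convolution, and reported as ``score = -log10(p)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from tfbranch.motif_io import Motif, MotifCollection, TFRecord

__all__ = [
    "CompareConfig",
    "PairScore",
    "column_score",
    "reverse_complement",
    "best_alignment",
    "motif_pvalue",
    "motif_score",
    "ScoreTable",
    "compare_all_pairs",
]


@dataclass(frozen=True)
class CompareConfig:
    """Settings for motif-pair comparison.

    ``null_mode='permutation'`` caps attainable scores at
    ``log10(n_null + 1)``; scores beyond ~3 need ``dp_exact`` or a very
    large ``n_null``.
    """

    min_overlap: int = 4
    strands: str = "both"  # "both" | "forward"
    null_mode: str = "permutation"  # "permutation" | "dp_exact"
    n_null: int = 1000
    n_bins: int = 100
    seed: int = 0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.strands not in ("both", "forward"):
            raise ValueError(f"unknown strands setting {self.strands!r}")
        if self.null_mode not in ("permutation", "dp_exact"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")
        if self.null_mode == "permutation" and self.n_null < 100:
            raise ValueError("permutation null needs n_null >= 100")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class PairScore:
    """Result of comparing two motifs.

    ``score`` is ``-log10(p_value)``; ``offset`` is the position of the
    target's first column relative to the query's first column, on the
    reported ``orientation`` (for '-', relative to the reverse-complemented
    target); ``raw`` is the summed Pearson column score of that alignment.
    """

    score: float
    p_value: float
    offset: int
    orientation: str
    raw: float
    n_offsets: int

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if abs(self.score + np.log10(self.p_value)) > 1e-9:
            raise ValueError("score and p_value disagree")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")


# --------------------------------------------------------------------------- #
# Column-level primitives
# --------------------------------------------------------------------------- #


def column_score(p: Sequence[float], q: Sequence[float]) -> float:
    """Pearson correlation of two frequency 4-vectors.

    Returns 0.0 when either column has zero variance (a uniform column
    carries no similarity evidence, and the correlation is undefined).
    """
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.shape != (4,) or qa.shape != (4,):
        raise ValueError("columns must be 4-vectors")
    if np.any(pa < 0) or np.any(qa < 0):
        raise ValueError("column entries must be nonnegative")
    pc = pa - pa.mean()
    qc = qa - qa.mean()
    np_, nq = np.linalg.norm(pc), np.linalg.norm(qc)
    if np_ == 0 or nq == 0:
        return 0.0
    return float(np.clip(pc @ qc / (np_ * nq), -1.0, 1.0))


def _standardize(freqs: np.ndarray) -> np.ndarray:
    """Center and L2-normalize each column; zero-variance columns map to 0.

    With both motifs standardized, ``Z_a.T @ Z_b`` is the matrix of Pearson
    column scores (including the zero-variance guard).
    """
    z = freqs - freqs.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(z, axis=0, keepdims=True)
    np.divide(z, norms, out=z, where=norms > 0)
    z[:, (norms == 0).ravel()] = 0.0
    return z


def reverse_complement(m: Motif) -> Motif:
    """Reverse-complement a motif: reverse columns, swap A<->T and C<->G."""
    return Motif(
        id=m.id + "_rc",
        matrix=m.matrix[::-1, ::-1].copy(),
        tf_name=m.tf_name,
        source=m.source,
        kind=m.kind,
    )


def _offset_range(lq: int, lt: int, min_overlap: int) -> range:
    # offset d: target column j aligns with query column d + j
    return range(-(lt - min_overlap), lq - min_overlap + 1)


def _overlap_slice(d: int, lq: int, lt: int) -> tuple[int, int]:
    """Query-column range [i0, i1) overlapping the target at offset d."""
    return max(0, d), min(lq, lt + d)


def _diagonal_sums(s: np.ndarray, offsets: range) -> np.ndarray:
    """Summed column scores for each offset; s is the Lq x Lt score matrix."""
    return np.array([np.trace(s, offset=-d) for d in offsets])


def best_alignment(
    query: Motif, target: Motif, cfg: CompareConfig
) -> tuple[float, int, str, int]:
    """Best gapless alignment of two motifs.

    Returns ``(raw, offset, orientation, n_offsets)`` where ``raw`` is the
    maximal summed Pearson column score over all admissible offsets and
    strands, and ``n_offsets`` counts every configuration enumerated.
    """
    lq, lt = query.length, target.length
    if lq < cfg.min_overlap or lt < cfg.min_overlap:
        raise ValueError(
            f"motifs too short: lengths {lq}, {lt} < min_overlap {cfg.min_overlap}"
        )
    zq = _standardize(query.frequencies(cfg.pseudocount))
    offsets = _offset_range(lq, lt, cfg.min_overlap)
    strands = ("+", "-") if cfg.strands == "both" else ("+",)
    best: tuple[float, int, str] | None = None
    n_offsets = 0
    for orientation in strands:
        t = target if orientation == "+" else reverse_complement(target)
        zt = _standardize(t.frequencies(cfg.pseudocount))
        raws = _diagonal_sums(zq.T @ zt, offsets)
        n_offsets += len(raws)
        k = int(np.argmax(raws))
        cand = (float(raws[k]), offsets[k], orientation)
        if best is None or cand[0] > best[0]:
            best = cand
    assert best is not None
    return best[0], best[1], best[2], n_offsets


# --------------------------------------------------------------------------- #
# Null models
# --------------------------------------------------------------------------- #


def _as_pool(pool: np.ndarray | MotifCollection | Sequence) -> np.ndarray:
    if isinstance(pool, MotifCollection):
        return pool.pool_columns()
    arr = np.asarray(pool, dtype=float)
    if arr.ndim == 2 and arr.shape[0] != 4 and arr.shape[1] == 4:
        arr = arr.T
    if arr.ndim != 2 or arr.shape[0] != 4 or arr.shape[1] == 0:
        raise ValueError("pool must be a non-empty 4 x M column array")
    return arr


def _permutation_pvalue(
    query: Motif, target: Motif, pool_cols: np.ndarray, cfg: CompareConfig
) -> PairScore:
    raw, off, orient, n_off = best_alignment(query, target, cfg)
    lq, lt = query.length, target.length
    zq = _standardize(query.frequencies(cfg.pseudocount))
    zpool = _standardize(pool_cols / pool_cols.sum(axis=0, keepdims=True))
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, zpool.shape[1], size=(cfg.n_null, lt))
    zd = zpool[:, idx]  # 4 x n_null x Lt
    offsets = _offset_range(lq, lt, cfg.min_overlap)
    # score tensor: (Lq, n_null, Lt) -> per-offset diagonal sums
    s_fwd = np.einsum("bi,bnj->nij", zq, zd)
    decoy_raw = _strip_max(s_fwd, offsets)
    if cfg.strands == "both":
        # reverse complement of a decoy: complement = flip base axis,
        # reverse = flip the column axis
        s_rev = np.einsum("bi,bnj->nij", zq, zd[::-1, :, ::-1])
        decoy_raw = np.maximum(decoy_raw, _strip_max(s_rev, offsets))
    k = int(np.sum(decoy_raw >= raw - 1e-12))
    p = (1 + k) / (1 + cfg.n_null)
    return PairScore(
        score=float(-np.log10(p)),
        p_value=p,
        offset=off,
        orientation=orient,
        raw=raw,
        n_offsets=n_off,
    )


def _strip_max(s: np.ndarray, offsets: range) -> np.ndarray:
    """Max over offsets of diagonal-strip sums, per decoy.

    ``s`` has shape (n_null, Lq, Lt).
    """
    sums = np.stack(
        [np.trace(s, offset=-d, axis1=1, axis2=2) for d in offsets], axis=1
    )
    return sums.max(axis=1)


def _bin_scores(scores: np.ndarray, n_bins: int) -> np.ndarray:
    """Map Pearson scores in [-1, 1] onto integer bins 0..n_bins."""
    return np.clip(np.rint((scores + 1.0) * (n_bins / 2.0)), 0, n_bins).astype(int)


def _dp_exact_pvalue(
    query: Motif, target: Motif, pool_cols: np.ndarray, cfg: CompareConfig
) -> PairScore:
    lq, lt = query.length, target.length
    if lq < cfg.min_overlap or lt < cfg.min_overlap:
        raise ValueError(
            f"motifs too short: lengths {lq}, {lt} < min_overlap {cfg.min_overlap}"
        )
    zq = _standardize(query.frequencies(cfg.pseudocount))
    zpool = _standardize(pool_cols / pool_cols.sum(axis=0, keepdims=True))
    offsets = _offset_range(lq, lt, cfg.min_overlap)
    strands = ("+", "-") if cfg.strands == "both" else ("+",)
    n_offsets = len(offsets) * len(strands)

    best_p = 1.0
    best_key: tuple[float, int, str] | None = None
    for orientation in strands:
        t = target if orientation == "+" else reverse_complement(target)
        zt = _standardize(t.frequencies(cfg.pseudocount))
        obs_bins = _bin_scores(zq.T @ zt, cfg.n_bins)  # Lq x Lt
        # per-query-column null pmf over bins; '-' strand nulls use the
        # complemented pool, equivalent to complementing the query column
        zq_eff = zq if orientation == "+" else zq[::-1]
        col_bins = _bin_scores(zq_eff.T @ zpool, cfg.n_bins)  # Lq x M
        pmfs = [
            np.bincount(col_bins[i], minlength=cfg.n_bins + 1)
            / col_bins.shape[1]
            for i in range(lq)
        ]
        cache: dict[tuple[int, int], np.ndarray] = {}
        for d in offsets:
            i0, i1 = _overlap_slice(d, lq, lt)
            pmf = _range_pmf(pmfs, i0, i1, cache)
            obs = int(sum(obs_bins[i, i - d] for i in range(i0, i1)))
            p_off = float(pmf[obs:].sum())
            p_off = min(max(p_off, 1e-300), 1.0)
            raw_here = float(np.trace(zq.T @ zt, offset=-d))
            key = (raw_here, d, orientation)
            if p_off < best_p or (p_off == best_p and (best_key is None or key > best_key)):
                best_p = p_off
                best_key = key
    assert best_key is not None
    # independence correction across enumerated offsets
    p_total = -np.expm1(n_offsets * np.log1p(-best_p)) if best_p < 1.0 else 1.0
    p_total = float(min(max(p_total, 1e-300), 1.0))
    return PairScore(
        score=float(-np.log10(p_total)),
        p_value=p_total,
        offset=best_key[1],
        orientation=best_key[2],
        raw=best_key[0],
        n_offsets=n_offsets,
    )


def _range_pmf(pmfs: list[np.ndarray], i0: int, i1: int, cache: dict) -> np.ndarray:
    """PMF of the summed bin score over query columns [i0, i1)."""
    if (i0, i1) in cache:
        return cache[(i0, i1)]
    if i1 - i0 == 1:
        out = pmfs[i0]
    else:
        out = np.convolve(_range_pmf(pmfs, i0, i1 - 1, cache), pmfs[i1 - 1])
    cache[(i0, i1)] = out
    return out


def motif_pvalue(
    query: Motif,
    target: Motif,
    pool: np.ndarray | MotifCollection,
    cfg: CompareConfig,
) -> PairScore:
    """Significance of the best query/target alignment against a column null.

    Permutation mode assembles ``n_null`` decoy targets from pool columns and
    uses the add-one estimator ``p = (1 + k) / (1 + n_null)`` (never zero).
    ``dp_exact`` mode convolves discretized per-column score distributions
    for an exact per-offset p-value, corrected for the number of offsets by
    ``1 - (1 - p_min)^n_offsets``.
    """
    pool_cols = _as_pool(pool)
    if cfg.null_mode == "permutation":
        return _permutation_pvalue(query, target, pool_cols, cfg)
    return _dp_exact_pvalue(query, target, pool_cols, cfg)


def motif_score(
    a: Motif,
    b: Motif,
    pool: np.ndarray | MotifCollection,
    cfg: CompareConfig,
) -> PairScore:
    """Symmetrized similarity of two motifs: the better of the two
    query/target directions."""
    ab = motif_pvalue(a, b, pool, cfg)
    ba = motif_pvalue(b, a, pool, cfg)
    return ab if ab.score >= ba.score else ba


# --------------------------------------------------------------------------- #
# Bulk scoring
# --------------------------------------------------------------------------- #


def _pair_seed(seed: int, id_a: str, id_b: str) -> int:
    """Deterministic per-pair seed, independent of evaluation order."""
    h = hashlib.sha256(f"{seed}|{id_a}|{id_b}".encode()).digest()
    return int.from_bytes(h[:8], "little")


class ScoreTable:
    """Symmetric lookup of motif-pair :class:`PairScore` values.

    Scores are computed lazily and cached; every pair draws its own
    deterministic seed from ``(seed, id_a, id_b)`` so evaluation order
    cannot change results.
    """

    def __init__(
        self,
        collection: MotifCollection,
        cfg: CompareConfig,
        pool: np.ndarray | None = None,
    ):
        self.collection = collection
        self.cfg = cfg
        self.pool = pool if pool is not None else collection.pool_columns(cfg.pseudocount)
        self._by_id = {m.id: m for m in collection}
        self._cache: dict[tuple[str, str], PairScore] = {}

    def score(self, id_a: str, id_b: str) -> PairScore:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        hit = self._cache.get(key)
        if hit is None:
            a, b = self._by_id[key[0]], self._by_id[key[1]]
            cfg = replace(self.cfg, seed=_pair_seed(self.cfg.seed, key[0], key[1]))
            hit = self._cache[key] = motif_score(a, b, self.pool, cfg)
        return hit

    def value(self, id_a: str, id_b: str) -> float:
        return self.score(id_a, id_b).score

    def tf_pair_values(self, x: TFRecord, y: TFRecord) -> np.ndarray:
        """The N_X x N_Y motif-pair score distribution for two TFs."""
        return np.array(
            [self.value(ma.id, mb.id) for ma in x.motifs for mb in y.motifs]
        )

    def intra_tf_values(self, x: TFRecord) -> np.ndarray:
        """The N(N-1)/2 within-TF motif-pair scores."""
        ms = x.motifs
        return np.array(
            [
                self.value(ms[i].id, ms[j].id)
                for i in range(len(ms))
                for j in range(i + 1, len(ms))
            ]
        )

    def items(self) -> Iterable[tuple[tuple[str, str], PairScore]]:
        return self._cache.items()


def compare_all_pairs(
    collection: MotifCollection, cfg: CompareConfig
) -> Mapping[tuple[str, str], PairScore]:
    """Eagerly score every unordered motif pair in the collection."""
    table = ScoreTable(collection, cfg)
    ids = [m.id for m in collection]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            table.score(a, b)
    return dict(table.items())
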