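"""Synthetic motif collections with planted hierarchical similarity.

Each planted branch gets one consensus frequency matrix; member TFs draw
their motifs column-wise from a Dirichlet centred on the consensus, with
optional small column shifts and reverse complementation.  The Dirichlet
concentration ``alpha_i = 1 + (kappa_in - 1) * 4 * c_i`` interpolates
between the flat Dirichlet(1,1,1,1) at ``kappa_in = 1`` (member motifs
statistically indistinguishable from unrelated ones) and the consensus
itself as ``kappa_in -> inf``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.metrics import adjusted_rand_score

from tfbranch.motif_io import (
    HierarchyPath,
    Motif,
    MotifCollection,
    TFRecord,
)

__all__ = ["SynthConfig", "generate_planted_collection", "recovery_score"]


@dataclass(frozen=True)
class SynthConfig:
    """Layout and noise parameters for a planted collection.

    By default every family is one planted branch; ``planted_branches``
    may instead map family paths (dotted text) to shared branch labels.
    TFs of families mapped to ``None`` get independent random motifs.
    """

    n_classes: int = 2
    families_per_class: int = 2
    subfamilies_per_family: int = 1
    tfs_per_subfamily: int = 3
    motifs_per_tf: tuple[float, ...] = (0.7, 0.2, 0.07, 0.03)  # P(N = 1..4)
    motif_length: tuple[int, int] = (8, 12)
    kappa_in: float = 32.0
    consensus_alpha: float = 0.35  # sharpness of planted consensus columns
    shift_prob: float = 0.2
    revcomp_prob: float = 0.3
    heterogeneous_tf_rate: float = 0.0  # multi-motif TFs drawing from 2 branches
    planted_branches: Mapping[str, str | None] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa_in <= 0:
            raise ValueError("kappa_in must be positive")
        for p in (self.shift_prob, self.revcomp_prob, self.heterogeneous_tf_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.motifs_per_tf) - 1) > 1e-9:
            raise ValueError("motifs_per_tf must sum to 1")
        if not 1 <= self.motif_length[0] <= self.motif_length[1]:
            raise ValueError("bad motif_length range")


def _consensus(rng: np.random.Generator, length: int, alpha: float) -> np.ndarray:
    return rng.dirichlet(np.full(4, alpha), size=length).T


def _member_motif(
    rng: np.random.Generator, consensus: np.ndarray, cfg: SynthConfig
) -> np.ndarray:
    cols = []
    for c in consensus.T:
        a = 1.0 + (cfg.kappa_in - 1.0) * 4.0 * c
        cols.append(rng.dirichlet(a))
    mat = np.array(cols).T
    if rng.random() < cfg.shift_prob:
        shift = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
        pad = rng.dirichlet(np.ones(4), size=abs(shift)).T
        if shift > 0:
            mat = np.hstack([pad, mat[:, :-shift]])
        else:
            mat = np.hstack([mat[:, -shift:], pad])
    if rng.random() < cfg.revcomp_prob:
        mat = mat[::-1, ::-1].copy()
    return mat


def _random_motif(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.dirichlet(np.ones(4), size=length).T


def generate_planted_collection(
    cfg: SynthConfig,
) -> tuple[MotifCollection, dict[str, str]]:
    """Generate a collection plus the true TF -> branch-label partition.

    Returns ``(collection, truth)`` where the collection carries fully
    annotated :class:`~tfbranch.motif_io.TFRecord` entries and ``truth``
    maps each TF name to its planted branch label (unplanted TFs get a
    unique singleton label).
    """
    rng = np.random.default_rng(cfg.seed)
    family_paths = [
        (1, c + 1, f + 1)
        for c in range(cfg.n_classes)
        for f in range(cfg.families_per_class)
    ]
    plan = dict(cfg.planted_branches or {})
    branch_of_family: dict[tuple[int, ...], str | None] = {}
    for path in family_paths:
        dotted = ".".join(map(str, path))
        branch_of_family[path] = plan.get(dotted, f"branch_{dotted}")

    labels = sorted({b for b in branch_of_family.values() if b is not None})
    consensus: dict[str, np.ndarray] = {}
    for label in labels:
        length = int(rng.integers(cfg.motif_length[0], cfg.motif_length[1] + 1))
        consensus[label] = _consensus(rng, length, cfg.consensus_alpha)

    motifs: list[Motif] = []
    tfs: list[TFRecord] = []
    truth: dict[str, str] = {}
    n_choices = np.arange(1, len(cfg.motifs_per_tf) + 1)
    for path in family_paths:
        branch = branch_of_family[path]
        for s in range(cfg.subfamilies_per_family):
            sub_path = HierarchyPath(path + (s + 1,))
            for t in range(cfg.tfs_per_subfamily):
                name = f"TF_{sub_path.dotted.replace('.', '_')}_{t + 1}"
                n_motifs = int(rng.choice(n_choices, p=cfg.motifs_per_tf))
                rec = TFRecord(name=name, path=sub_path)
                hetero = (
                    n_motifs >= 2
                    and branch is not None
                    and rng.random() < cfg.heterogeneous_tf_rate
                )
                for k in range(n_motifs):
                    if branch is None:
                        length = int(
                            rng.integers(cfg.motif_length[0], cfg.motif_length[1] + 1)
                        )
                        mat = _random_motif(rng, length)
                    elif hetero and k == n_motifs - 1:
                        # emulate a TF with two structurally unrelated motifs
                        other = labels[
                            (labels.index(branch) + 1 + int(rng.integers(len(labels) - 1)))
                            % len(labels)
                        ] if len(labels) > 1 else None
                        mat = (
                            _member_motif(rng, consensus[other], cfg)
                            if other is not None
                            else _random_motif(rng, consensus[branch].shape[1])
                        )
                    else:
                        mat = _member_motif(rng, consensus[branch], cfg)
                    motif = Motif(
                        id=f"{name}.m{k + 1}",
                        matrix=mat,
                        tf_name=name,
                        source="synthetic",
                        kind="frequencies",
                    )
                    motifs.append(motif)
                    rec.motifs.append(motif)
                tfs.append(rec)
                truth[name] = branch if branch is not None else f"noise_{name}"
    coll = MotifCollection(motifs=motifs, tfs=tfs, name="synthetic")
    return coll, truth


def recovery_score(found, truth: Mapping[str, str]) -> float:
    """Adjusted Rand Index between a found branch partition and the truth.

    ``found`` is a :class:`~tfbranch.branch_finder.BranchPartition` or any
    mapping of TF name to cluster label.  Raises if the TF universes differ.
    """
    if hasattr(found, "as_partition"):
        found = found.as_partition()
    if set(found) != set(truth):
        raise ValueError("partitions cover different TF universes")
    names = sorted(found)
    return float(
        adjusted_rand_score([truth[n] for n in names], [found[n] for n in names])
    )
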