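from __future__ import annotations

import numpy as np
import pytest

from tfbranch.motif_io import HierarchyPath, Motif, TFRecord
from tfbranch.motif_compare import CompareConfig, ScoreTable
from tfbranch.similarity_metrics import MetricConfig
from tfbranch.synthetic_motifs import SynthConfig, generate_planted_collection


def make_motif(mid: str, length: int = 8, seed: int = 0, tf_name: str = "") -> Motif:
    """A random peaked frequency motif (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    return Motif(
        id=mid,
        matrix=rng.dirichlet(np.full(4, 0.4), size=length).T,
        tf_name=tf_name,
        kind="frequencies",
    )


class FakeScores:
    """ScoreTable stand-in fed with preset motif-pair score values.

    Keys are frozensets of motif ids; metrics and branch-finding code only
    consume ``value``/``tf_pair_values``/``intra_tf_values``.
    """

    def __init__(self, values: dict[frozenset, float]):
        self._values = values

    def value(self, id_a: str, id_b: str) -> float:
        return self._values[frozenset((id_a, id_b))]

    def tf_pair_values(self, x: TFRecord, y: TFRecord) -> np.ndarray:
        return np.array(
            [self.value(ma.id, mb.id) for ma in x.motifs for mb in y.motifs]
        )

    def intra_tf_values(self, x: TFRecord) -> np.ndarray:
        ms = x.motifs
        return np.array(
            [
                self.value(ms[i].id, ms[j].id)
                for i in range(len(ms))
                for j in range(i + 1, len(ms))
            ]
        )


def single_motif_tf(name: str, path: str) -> TFRecord:
    m = Motif(
        id=name,
        matrix=np.array([[1.0], [0.0], [0.0], [0.0]]),
        tf_name=name,
        kind="frequencies",
    )
    return TFRecord(name=name, path=HierarchyPath.parse(path), motifs=[m])


@pytest.fixture(scope="session")
def planted():
    """A kappa=32 planted collection with its true partition.

    Families 1.1.1 and 1.1.2 share one planted branch, so branch search
    must perform at least one above-threshold family merge.
    """
    cfg = SynthConfig(
        seed=11,
        kappa_in=32.0,
        families_per_class=3,
        tfs_per_subfamily=2,
        planted_branches={"1.1.1": "shared", "1.1.2": "shared"},
    )
    return generate_planted_collection(cfg)


@pytest.fixture(scope="session")
def planted_table(planted):
    coll, _ = planted
    return ScoreTable(coll, CompareConfig(n_null=2000, seed=11))


@pytest.fixture()
def metric_cfg():
    return MetricConfig()
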