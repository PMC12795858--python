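"""End-to-end pipeline orchestration and tabular reports.

``run_pipeline`` loads a motif collection and its hierarchy annotation,
scores every motif pair (cached to TSV so reruns and downstream stages
are bit-identical), emits similarity matrices per hierarchy level, the
branch partition with its merge log, per-class similarity trees in
Newick form, the heterogeneous-TF report, and a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

import tfbranch
from tfbranch.motif_io import (
    TFRecord,
    parse_hierarchy_annotation,
    parse_motif_collection,
)
from tfbranch.motif_compare import CompareConfig, PairScore, ScoreTable
from tfbranch.similarity_metrics import MetricConfig, set_similarity
from tfbranch.branch_finder import (
    agglomerate,
    export_newick,
    find_branches,
    flag_heterogeneous_tfs,
)

log = logging.getLogger("tfbranch")

__all__ = ["RunConfig", "run_pipeline", "save_scores_tsv", "load_scores_tsv"]


@dataclass
class RunConfig:
    motifs_path: str
    annotation_path: str
    out_dir: str
    dialect: str = "jaspar_pfm"
    compare: CompareConfig = field(default_factory=CompareConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for p in (self.motifs_path, self.annotation_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def save_scores_tsv(table: ScoreTable, path: Path) -> None:
    rows = [
        {
            "motif_a": a,
            "motif_b": b,
            "raw": ps.raw,
            "offset": ps.offset,
            "orientation": ps.orientation,
            "p_value": ps.p_value,
            "score": ps.score,
            "n_offsets": ps.n_offsets,
        }
        for (a, b), ps in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_scores_tsv(table: ScoreTable, path: Path) -> int:
    """Preload a score cache written by :func:`save_scores_tsv`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    n = 0
    for row in df.itertuples(index=False):
        key = (row.motif_a, row.motif_b)
        table._cache[key] = PairScore(
            score=float(row.score),
            p_value=float(row.p_value),
            offset=int(row.offset),
            orientation=str(row.orientation),
            raw=float(row.raw),
            n_offsets=int(row.n_offsets),
        )
        n += 1
    return n


def _level_scopes(
    records: list[TFRecord], depth: int
) -> dict[str, dict[str, list[TFRecord]]]:
    """Units of a given depth, grouped under their parent scope."""
    scopes: dict[str, dict[str, list[TFRecord]]] = {}
    for tf in records:
        if tf.path.depth < depth:
            continue
        parent = tf.path.prefix(depth - 1).dotted if depth > 1 else "all"
        unit = tf.path.prefix(depth).dotted
        scopes.setdefault(parent, {}).setdefault(unit, []).append(tf)
    return scopes


def metrics_table(
    records: list[TFRecord],
    table: ScoreTable,
    cfg: MetricConfig,
    depth: int,
) -> pd.DataFrame:
    """Long-format similarity metrics for all unit pairs at one level."""
    rows = []
    for parent, units in sorted(_level_scopes(records, depth).items()):
        labels = sorted(units)
        for i, a in enumerate(labels):
            for b in labels[i:]:
                if a == b:
                    s = set_similarity(units[a], None, table, cfg)
                else:
                    s = set_similarity(units[a], units[b], table, cfg)
                rows.append(
                    {
                        "scope": parent,
                        "unit_a": a,
                        "unit_b": b,
                        "kind": s.kind,
                        "min": s.min,
                        "q1": s.q1,
                        "q2": s.q2,
                        "q3": s.q3,
                        "max": s.max,
                        "n_pairs": s.n_pairs,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``cfg.out_dir``.

    Returns the manifest dictionary.  Any stage failure raises with the
    stage name in the message.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        coll = parse_motif_collection(cfg.motifs_path, cfg.dialect)
        records = parse_hierarchy_annotation(cfg.annotation_path, coll)
        covered = {m.id for rec in records for m in rec.motifs}
        unannotated = [m.id for m in coll if m.id not in covered]
        if unannotated:
            raise ValueError(f"motifs without annotation: {unannotated[:5]}")

        stage = "compare"
        compare_cfg = replace(cfg.compare, seed=cfg.seed)
        table = ScoreTable(coll, compare_cfg)
        cache = out / "scores.tsv"
        if cache.exists():
            n = load_scores_tsv(table, cache)
            log.info("reloaded %d cached pair scores", n)
        ids = [m.id for m in coll]
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                table.score(a, b)
        save_scores_tsv(table, cache)

        stage = "metrics"
        for depth, level in ((2, "class"), (3, "family"), (4, "subfamily")):
            df = metrics_table(records, table, cfg.metric, depth)
            df.to_csv(out / f"metrics_{level}.tsv", sep="\t", index=False)

        stage = "branches"
        partition = find_branches(records, table, cfg.metric)
        pd.DataFrame(
            [
                {
                    "branch_id": i,
                    "level": b.level,
                    "members": ";".join(b.members),
                    "tfs": ";".join(b.tf_names),
                    "n_tfs": b.size,
                    "internal_q2": b.internal_q2,
                }
                for i, b in enumerate(partition.branches)
            ]
        ).to_csv(out / "branches.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "level": s.level,
                    "parent": s.parent,
                    "unit_a": ";".join(s.unit_a),
                    "unit_b": ";".join(s.unit_b),
                    "q2": s.q2,
                }
                for s in partition.merge_log
            ]
        ).to_csv(out / "merge_log.tsv", sep="\t", index=False)

        stage = "trees"
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        n_trees = 0
        for class_label, units in sorted(_level_scopes(records, 3).items()):
            if len(units) < 2:
                continue
            try:
                tree = agglomerate(sorted(units.items()), table, cfg.metric)
            except ValueError:
                continue
            (tree_dir / f"class_{class_label}.nwk").write_text(export_newick(tree) + "\n")
            n_trees += 1

        stage = "heterogeneity"
        flagged = flag_heterogeneous_tfs(records, table, cfg.metric)
        pd.DataFrame(flagged, columns=["tf_name", "heterogeneity"]).to_csv(
            out / "heterogeneous_tfs.tsv", sep="\t", index=False
        )

        stage = "manifest"
        manifest = {
            "inputs": {
                "motifs": str(cfg.motifs_path),
                "annotation": str(cfg.annotation_path),
                "dialect": cfg.dialect,
            },
            "seed": cfg.seed,
            "compare": asdict(compare_cfg),
            "metric": asdict(cfg.metric),
            "n_motifs": len(coll),
            "n_tfs": len(records),
            "n_branches": len(partition.branches),
            "n_trees": n_trees,
            "n_heterogeneous_tfs": len(flagged),
            "versions": {
                "tfbranch": tfbranch.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": platform.python_version(),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
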