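"""One-time extraction of the JASPAR2024 Drosophila melanogaster CORE
collection (all matrix versions) into plain-text files under data/.

Requires the ``pyjaspar`` package (bundles the JASPAR2024 sqlite release);
the generated files are committed, so normal use of the repository never
runs this script.

Hierarchy paths are assigned from the JASPAR class/family annotation via
the numeral mapping below; families without an established numeral fall
into the ``<class>.0`` bucket, and classes outside the mapped set are
parked under pseudo-superclass 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from tfbranch.motif_io import (
    HierarchyPath,
    Motif,
    MotifCollection,
    TFRecord,
    write_annotation,
    write_motif_collection,
)

CLASS_NUMERALS = {
    "Basic leucine zipper factors (bZIP)": (1, 1),
    "Basic helix-loop-helix factors (bHLH)": (1, 2),
    "Nuclear receptors with C4 zinc fingers": (2, 1),
    "C2H2 zinc finger factors": (2, 3),
    "Homeo domain factors": (3, 1),
    "Fork head/winged helix factors": (3, 3),
    "Tryptophan cluster factors": (3, 5),
}

FAMILY_NUMERALS = {
    (1, 1): {
        "Jun-related": 1,
        "Fos-related": 2,
        "Maf-related": 3,
        "XBP-1-related factors": 5,
        "ATF-4-related factors": 6,
        "CREB-related factors": 7,
        "CEBP-related": 8,
    },
    (1, 2): {
        "Tal-related": 3,
        "PAS domain factors": 5,
        "bHLH-ZIP": 6,
    },
    (2, 1): {
        "Steroid hormone receptors (NR3)": 1,
        "Thyroid hormone receptor-related factors (NR1)": 2,
        "RXR-related receptors (NR2)": 3,
        "GCNF-related receptors (NR6)": 6,
    },
    (2, 3): {
        "Three-zinc finger Kruppel-related": 1,
        "Other factors with up to three adjacent zinc fingers": 2,
        "More than 3 adjacent zinc fingers": 3,
        "Factors with multiple dispersed zinc fingers": 4,
        "BED zinc finger factors": 5,
    },
    (3, 1): {
        "HOX": 1,
        "NK": 2,
        "Paired-related HD factors": 3,
        "TALE-type HD": 4,
        "TALE-type homeo domain factors": 4,
        "HD-LIM": 5,
        "HD-SINE": 6,
        "HD-CUT": 9,
        "POU domain factors": 10,
    },
    (3, 3): {
        "FOX": 1,
        "RFX-related factors": 3,
    },
    (3, 5): {
        "Ets-related": 2,
    },
}


def assign_path(tf_class: str, tf_family: str, other_classes: dict[str, int]) -> HierarchyPath:
    if tf_class in CLASS_NUMERALS:
        sc, cl = CLASS_NUMERALS[tf_class]
        fam = FAMILY_NUMERALS.get((sc, cl), {}).get(tf_family, 0)
        return HierarchyPath((sc, cl, fam))
    idx = other_classes.setdefault(tf_class, len(other_classes) + 1)
    return HierarchyPath((0, idx))


def main() -> None:
    from pyjaspar import jaspardb

    jdb = jaspardb(release="JASPAR2024")
    raw = jdb.fetch_motifs(collection="CORE", species=7227, all_versions=True)
    raw.sort(key=lambda m: m.matrix_id)

    other_classes: dict[str, int] = {}
    motifs: list[Motif] = []
    meta: list[tuple[str, str, HierarchyPath, int]] = []
    for jm in raw:
        counts = np.array([jm.counts[b] for b in "ACGT"], dtype=float)
        tf_class = (jm.tf_class or ["?"])[0]
        tf_family = (jm.tf_family or ["?"])[0]
        path = assign_path(tf_class, tf_family, other_classes)
        version = int(jm.matrix_id.split(".")[1])
        motifs.append(
            Motif(id=jm.matrix_id, matrix=counts, tf_name=jm.name, source="JASPAR2024")
        )
        meta.append((jm.matrix_id, jm.name, path, version))

    # one path per TF: if versions disagree, keep the newest version's path
    by_tf: dict[str, TFRecord] = {}
    best_version: dict[str, int] = {}
    for (mid, name, path, version), motif in zip(meta, motifs):
        if name not in by_tf or version > best_version[name]:
            if name in by_tf:
                by_tf[name].path = path
            else:
                by_tf[name] = TFRecord(name=name, path=path)
            best_version[name] = version
    for (mid, name, path, version), motif in zip(meta, motifs):
        by_tf[name].motifs.append(motif)

    coll = MotifCollection(motifs=motifs, tfs=list(by_tf.values()), name="JASPAR2024_dmel")
    out = Path(__file__).resolve().parent.parent / "data"
    out.mkdir(exist_ok=True)
    write_motif_collection(coll, out / "jaspar2024_dmel_core.pfm", "jaspar_pfm")
    write_annotation(coll.tfs, out / "jaspar2024_dmel_annotation.tsv")
    print(f"wrote {len(motifs)} motifs, {len(by_tf)} TFs")


if __name__ == "__main__":
    main()
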