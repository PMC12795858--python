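"""Reading and writing motif collections and hierarchy annotations.

Supported motif dialects
------------------------
``jaspar_pfm``
    JASPAR position frequency matrices: a ``>`` header per motif followed
    by four base rows (``A [ 10 0 ... ]``); values are counts.
``meme_minimal``
    MEME minimal motif format; the letter-probability matrix holds
    frequencies, one position per line.
``hocomoco_pcm``
    Hocomoco position count matrices: a ``>`` header followed by one line
    per position with four counts in A, C, G, T order.

Whatever the dialect, matrices are canonicalized to a 4 x L array with
row order A, C, G, T and columns indexed by motif position.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
DIALECTS = ("jaspar_pfm", "meme_minimal", "hocomoco_pcm")


class MotifParseError(ValueError):
    """Raised when a motif file or annotation table is malformed."""


# --------------------------------------------------------------------------- #
# Core types
# --------------------------------------------------------------------------- #


def normalize_counts(matrix: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Normalize a 4 x L nonnegative matrix to column-stochastic frequencies.

    Column ``j`` becomes ``(c_ij + pseudocount) / (sum_i c_ij + 4 * pseudocount)``.

    Raises
    ------
    ValueError
        If the matrix is not 4 x L, has negative entries, or contains an
        all-zero column while ``pseudocount`` is zero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != 4:
        raise ValueError(f"expected a 4 x L matrix, got shape {m.shape}")
    if m.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    if np.any(m < 0):
        raise ValueError("matrix entries must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    totals = m.sum(axis=0) + 4.0 * pseudocount
    if np.any(totals == 0):
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"column {bad} sums to zero and pseudocount is 0")
    return (m + pseudocount) / totals


@dataclass
class Motif:
    """One binding-site motif: an identifier plus a 4 x L matrix.

    ``matrix`` is stored as parsed (counts or frequencies, see ``kind``);
    :meth:`frequencies` returns the column-stochastic form.
    """

    id: str
    matrix: np.ndarray
    tf_name: str = ""
    source: str = ""
    kind: str = "counts"  # "counts" | "frequencies"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise MotifParseError(
                f"motif {self.id!r}: expected 4 rows, got shape {self.matrix.shape}"
            )
        if self.matrix.shape[1] < 1:
            raise MotifParseError(f"motif {self.id!r}: zero-length matrix")
        if np.any(self.matrix < 0):
            raise MotifParseError(f"motif {self.id!r}: negative matrix entry")
        if self.kind not in ("counts", "frequencies"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Column-stochastic 4 x L matrix (idempotent on frequency input)."""
        return normalize_counts(self.matrix, pseudocount)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Motif):
            return NotImplemented
        return self.id == other.id and np.allclose(self.matrix, other.matrix)

    def __hash__(self) -> int:
        return hash(self.id)


_PATH_RE = re.compile(r"^\{?(\d+(?:\.\d+){0,3})\}?$")


@dataclass(frozen=True, order=True)
class HierarchyPath:
    """Dotted-numeral position in the structural TF hierarchy.

    Levels are superclass, class, family, subfamily; deeper levels may be
    absent but the prefix must be consistent.  ``HierarchyPath.parse("1.1.1.1")``
    renders back as ``"{1.1.1.1}"``.
    """

    numerals: tuple[int, ...]

    LEVELS = ("superclass", "class", "family", "subfamily")

    def __post_init__(self) -> None:
        if not (1 <= len(self.numerals) <= 4):
            raise ValueError(f"hierarchy path needs 1-4 numerals, got {self.numerals}")
        if any(n < 0 for n in self.numerals):
            raise ValueError("hierarchy numerals must be nonnegative")

    @classmethod
    def parse(cls, text: str) -> "HierarchyPath":
        m = _PATH_RE.match(text.strip())
        if not m:
            raise MotifParseError(f"malformed hierarchy path {text!r}")
        return cls(tuple(int(x) for x in m.group(1).split(".")))

    @property
    def superclass(self) -> int:
        return self.numerals[0]

    @property
    def class_(self) -> tuple[int, ...] | None:
        return self.numerals[:2] if len(self.numerals) >= 2 else None

    @property
    def family(self) -> tuple[int, ...] | None:
        return self.numerals[:3] if len(self.numerals) >= 3 else None

    @property
    def subfamily(self) -> tuple[int, ...] | None:
        return self.numerals[:4] if len(self.numerals) >= 4 else None

    @property
    def depth(self) -> int:
        return len(self.numerals)

    @property
    def level(self) -> str:
        return self.LEVELS[len(self.numerals) - 1]

    def prefix(self, depth: int) -> "HierarchyPath":
        if depth < 1 or depth > len(self.numerals):
            raise ValueError(f"cannot take prefix of depth {depth} from {self}")
        return HierarchyPath(self.numerals[:depth])

    def startswith(self, other: "HierarchyPath") -> bool:
        return self.numerals[: len(other.numerals)] == other.numerals

    @property
    def dotted(self) -> str:
        return ".".join(str(n) for n in self.numerals)

    def __str__(self) -> str:
        return "{" + self.dotted + "}"


@dataclass
class TFRecord:
    """A transcription factor: name, hierarchy path, and its motifs (N >= 1)."""

    name: str
    path: HierarchyPath
    motifs: list[Motif] = field(default_factory=list)

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    def validate(self) -> None:
        if not self.motifs:
            raise ValueError(f"TF {self.name!r} has no motifs")
        for m in self.motifs:
            if m.tf_name and m.tf_name != self.name:
                raise ValueError(
                    f"motif {m.id!r} annotated to TF {m.tf_name!r}, "
                    f"attached to {self.name!r}"
                )


@dataclass
class MotifCollection:
    """A motif set plus optional TF grouping and a background composition."""

    motifs: list[Motif] = field(default_factory=list)
    tfs: list[TFRecord] = field(default_factory=list)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = ""

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a 4-vector summing to 1")
        seen: set[str] = set()
        for m in self.motifs:
            if m.id in seen:
                raise MotifParseError(f"duplicate motif id {m.id!r}")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def get(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def pool_columns(self, pseudocount: float = 0.0) -> np.ndarray:
        """All frequency columns of the collection, as a 4 x M array.

        This is the null pool for the comparison p-value machinery.
        """
        return np.hstack([m.frequencies(pseudocount) for m in self.motifs])

    def tf_by_name(self, name: str) -> TFRecord:
        for tf in self.tfs:
            if tf.name == name:
                return tf
        raise KeyError(name)


# --------------------------------------------------------------------------- #
# Parsers
# --------------------------------------------------------------------------- #


def _tokens_to_floats(tokens: Sequence[str], where: str) -> list[float]:
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise MotifParseError(f"{where}: non-numeric value in {tokens!r}") from exc


def _parse_jaspar(text: str, source: str) -> list[Motif]:
    motifs: list[Motif] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(BASES):
            raise MotifParseError(
                f"motif {header!r}: expected rows A,C,G,T, got {sorted(rows)}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise MotifParseError(f"motif {header!r}: ragged rows, lengths {lengths}")
        mat = np.array([rows[b] for b in BASES])
        hid, _, rest = header.partition(" ")
        motifs.append(Motif(id=hid, matrix=mat, tf_name=rest.strip(), source=source))
        header, rows = None, {}

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            continue
        m = re.match(r"^([ACGTacgt])\s*[\[|]?\s*([-\d.eE+\s]*?)\s*\]?$", line)
        if header is None or not m:
            raise MotifParseError(f"unexpected line in JASPAR input: {line!r}")
        base = m.group(1).upper()
        if base in rows:
            raise MotifParseError(f"motif {header!r}: duplicate {base} row")
        rows[base] = _tokens_to_floats(m.group(2).split(), f"motif {header!r}")
    flush()
    if not motifs:
        raise MotifParseError("no motifs found in JASPAR input")
    return motifs


def _parse_hocomoco(text: str, source: str) -> list[Motif]:
    motifs: list[Motif] = []
    header: str | None = None
    cols: list[list[float]] = []

    def flush() -> None:
        nonlocal header, cols
        if header is None:
            return
        if not cols:
            raise MotifParseError(f"motif {header!r}: empty matrix")
        widths = {len(c) for c in cols}
        if widths != {4}:
            raise MotifParseError(
                f"motif {header!r}: each position needs 4 values, got widths {widths}"
            )
        hid = header.split()[0]
        motifs.append(Motif(id=hid, matrix=np.array(cols).T, source=source))
        header, cols = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            continue
        if header is None:
            raise MotifParseError(f"matrix row before any header: {line!r}")
        cols.append(_tokens_to_floats(line.split(), f"motif {header!r}"))
    flush()
    if not motifs:
        raise MotifParseError("no motifs found in PCM input")
    return motifs


def _parse_meme(text: str, source: str) -> tuple[list[Motif], np.ndarray | None]:
    motifs: list[Motif] = []
    background: np.ndarray | None = None
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j].upper(): float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq[b] for b in BASES])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"MOTIF line without identifier: {line!r}")
            mid = parts[1]
            alt = parts[2] if len(parts) > 2 else ""
            i += 1
            while i < len(lines) and not lines[i].strip().lower().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(f"motif {mid!r}: missing probability matrix")
                i += 1
            if i >= len(lines):
                raise MotifParseError(f"motif {mid!r}: missing probability matrix")
            w_match = re.search(r"w=\s*(\d+)", lines[i])
            declared_w = int(w_match.group(1)) if w_match else None
            i += 1
            cols: list[list[float]] = []
            while i < len(lines):
                row = lines[i].strip()
                if not row or row.startswith(("MOTIF", "URL")) or row.lower().startswith(
                    "letter-probability"
                ):
                    break
                vals = _tokens_to_floats(row.split(), f"motif {mid!r}")
                if len(vals) != 4:
                    raise MotifParseError(
                        f"motif {mid!r}: expected 4 frequencies per position, "
                        f"got {len(vals)}"
                    )
                cols.append(vals)
                i += 1
            if declared_w is not None and declared_w != len(cols):
                raise MotifParseError(
                    f"motif {mid!r}: declared w={declared_w} but parsed {len(cols)} positions"
                )
            if not cols:
                raise MotifParseError(f"motif {mid!r}: empty matrix")
            motifs.append(
                Motif(
                    id=mid,
                    matrix=np.array(cols).T,
                    tf_name=alt,
                    source=source,
                    kind="frequencies",
                )
            )
            continue
        i += 1
    if not motifs:
        raise MotifParseError("no motifs found in MEME input")
    return motifs, background


def parse_motif_collection(
    path: str | Path | io.StringIO, dialect: str, name: str = ""
) -> MotifCollection:
    """Parse a motif file into a :class:`MotifCollection`.

    Parameters
    ----------
    path
        File path, or a ``StringIO`` with the raw text.
    dialect
        One of ``jaspar_pfm``, ``meme_minimal``, ``hocomoco_pcm``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if isinstance(path, io.StringIO):
        text = path.getvalue()
        src = name or dialect
    else:
        p = Path(path)
        text = p.read_text()
        src = name or p.stem
    if not text.strip():
        raise MotifParseError(f"empty motif file ({src})")
    background = None
    if dialect == "jaspar_pfm":
        motifs = _parse_jaspar(text, src)
    elif dialect == "hocomoco_pcm":
        motifs = _parse_hocomoco(text, src)
    else:
        motifs, background = _parse_meme(text, src)
    coll = MotifCollection(motifs=motifs, name=src)
    if background is not None:
        coll.background = background
    return coll


def parse_hierarchy_annotation(
    path: str | Path | io.StringIO, collection: MotifCollection
) -> list[TFRecord]:
    """Read a TSV of (motif_id, tf_name, hierarchy path) and group motifs by TF.

    The table is attached to ``collection.tfs`` and returned.  A header row
    is accepted if its first field is ``motif_id``.

    Raises
    ------
    MotifParseError
        If a motif_id is absent from the collection, or one TF is given two
        distinct paths.
    """
    text = path.getvalue() if isinstance(path, io.StringIO) else Path(path).read_text()
    by_tf: dict[str, TFRecord] = {}
    assigned: set[str] = set()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise MotifParseError(f"annotation line {ln}: expected 3 columns: {line!r}")
        motif_id, tf_name, path_text = (p.strip() for p in parts[:3])
        if ln == 1 and motif_id.lower() == "motif_id":
            continue
        try:
            motif = collection.get(motif_id)
        except KeyError:
            raise MotifParseError(
                f"annotation line {ln}: motif {motif_id!r} not in collection"
            ) from None
        if motif_id in assigned:
            raise MotifParseError(f"motif {motif_id!r} annotated twice")
        assigned.add(motif_id)
        hpath = HierarchyPath.parse(path_text)
        rec = by_tf.get(tf_name)
        if rec is None:
            rec = by_tf[tf_name] = TFRecord(name=tf_name, path=hpath)
        elif rec.path != hpath:
            raise MotifParseError(
                f"TF {tf_name!r} has conflicting paths {rec.path} and {hpath}"
            )
        motif.tf_name = tf_name
        rec.motifs.append(motif)
    records = list(by_tf.values())
    for rec in records:
        rec.validate()
    collection.tfs = records
    return records


# --------------------------------------------------------------------------- #
# Writers
# --------------------------------------------------------------------------- #


def write_motif_collection(
    collection: MotifCollection, path: str | Path | io.StringIO, dialect: str
) -> None:
    """Write a collection in the given dialect (counts for JASPAR/PCM,
    frequencies for MEME minimal)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    out: list[str] = []
    if dialect == "jaspar_pfm":
        for m in collection:
            title = f">{m.id}" + (f" {m.tf_name}" if m.tf_name else "")
            out.append(title)
            for b, row in zip(BASES, m.matrix):
                vals = " ".join(_fmt(v) for v in row)
                out.append(f"{b} [ {vals} ]")
    elif dialect == "hocomoco_pcm":
        for m in collection:
            out.append(f">{m.id}")
            for col in m.matrix.T:
                out.append("\t".join(_fmt(v) for v in col))
    else:
        out.append("MEME version 4\n")
        out.append("ALPHABET= ACGT\n")
        out.append("strands: + -\n")
        bg = collection.background
        out.append("Background letter frequencies")
        out.append(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)) + "\n")
        for m in collection:
            alt = f" {m.tf_name}" if m.tf_name else ""
            out.append(f"MOTIF {m.id}{alt}")
            freqs = m.frequencies()
            total = m.matrix.sum(axis=0).mean() if m.kind == "counts" else 20.0
            out.append(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= {max(int(round(total)), 1)} E= 0"
            )
            for col in freqs.T:
                out.append(" " + " ".join(f"{v:.6f}" for v in col))
            out.append("")
    text = "\n".join(out) + "\n"
    if isinstance(path, io.StringIO):
        path.write(text)
    else:
        Path(path).write_text(text)


def write_annotation(records: Iterable[TFRecord], path: str | Path | io.StringIO) -> None:
    """Write the (motif_id, tf_name, path) TSV consumed by
    :func:`parse_hierarchy_annotation`."""
    lines = ["motif_id\ttf_name\tpath"]
    for rec in records:
        for m in rec.motifs:
            lines.append(f"{m.id}\t{rec.name}\t{rec.path.dotted}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.StringIO):
        path.write(text)
    else:
        Path(path).write_text(text)


def dump_collection_tsv(collection: MotifCollection, path: str | Path) -> None:
    """Debug dump: one row per motif column with frequencies."""
    lines = ["motif_id\ttf_name\tposition\tA\tC\tG\tT"]
    for m in collection:
        freqs = m.frequencies()
        for j in range(m.length):
            vals = "\t".join(f"{v:.6g}" for v in freqs[:, j])
            lines.append(f"{m.id}\t{m.tf_name}\t{j}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}"
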