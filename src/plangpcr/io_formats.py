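"""Readers and writers for the on-disk artifacts the pipeline touches.

Formats: FASTA/FASTQ sequence collections, the tab-separated receptor
annotation table, three-column similarity edge lists, and Newick trees.
All tables are UTF-8 TSV with ``NA`` for missing optional fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

DNA_CHARS = set("ACGTN-")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*-")

#: in situ hybridization pattern codes used in the annotation table
INSITU_CODES = frozenset({"BR", "INT", "TE", "OV", "OVD", "VIT", "SPD", "CO", "NE"})

#: fixed column order of the annotation table (a repo convention)
ANNOTATION_COLUMNS = (
    "clone_id",
    "gene_name",
    "cluster",
    "orf_confident",
    "n_term_ok",
    "c_term_ok",
    "n_tm_domains",
    "max_control_rpkm",
    "norm_log2fc",
    "insitu_pattern",
)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str
    alphabet: str  # "dna" or "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        if self.alphabet not in ("dna", "protein"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_CHARS if self.alphabet == "dna" else PROTEIN_CHARS
        bad = set(self.seq.upper()) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationRow:
    """One curated receptor entry of the annotation table.

    ``norm_log2fc`` may carry the division-by-zero sentinel value
    (log2 of the sentinel ratio, 13.29 for ratio 10000); it is written
    out as its numeric value, never as a marker string.
    """

    clone_id: str
    gene_name: str | None = None
    cluster: str | None = None
    orf_confident: bool = False
    n_term_ok: bool = False
    c_term_ok: bool = False
    n_tm_domains: int = 0
    max_control_rpkm: float = 0.0
    norm_log2fc: float | None = None
    insitu_pattern: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_tm_domains < 0:
            raise FormatError("n_tm_domains must be >= 0")
        if self.max_control_rpkm < 0:
            raise FormatError("max_control_rpkm must be >= 0")
        bad = set(self.insitu_pattern) - INSITU_CODES
        if bad:
            raise FormatError(f"unknown in situ codes: {sorted(bad)}")


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`, order preserved.

    Duplicate ids and header-only (empty) records are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), alphabet))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ reads; base qualities are ignored throughout the pipeline."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper(), "dna")
        for rec in SeqIO.parse(str(Path(path)), "fastq")
    ]
    if not records:
        raise FormatError(f"no FASTQ records in {path}")
    return records


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return repr(value)
    if isinstance(value, list):
        return ",".join(value) if value else "NA"
    if isinstance(value, (str, int)):
        return str(value) if value != "" else "NA"
    raise FormatError(f"unserializable annotation field of type {type(value).__name__}")


def write_annotation_table(rows: Sequence[AnnotationRow], path: str | Path) -> None:
    """Write annotation rows as a UTF-8 TSV in the fixed documented column order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for row in rows:
            cells = [_format_cell(getattr(row, col)) for col in ANNOTATION_COLUMNS]
            fh.write("\t".join(cells) + "\n")


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_COLUMNS:
            raise FormatError(f"unexpected annotation header in {path}")
        rows = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(ANNOTATION_COLUMNS):
                raise FormatError(f"wrong field count in {path}: {line!r}")
            d = dict(zip(ANNOTATION_COLUMNS, cells))
            rows.append(
                AnnotationRow(
                    clone_id=d["clone_id"],
                    gene_name=None if d["gene_name"] == "NA" else d["gene_name"],
                    cluster=None if d["cluster"] == "NA" else d["cluster"],
                    orf_confident=d["orf_confident"] == "TRUE",
                    n_term_ok=d["n_term_ok"] == "TRUE",
                    c_term_ok=d["c_term_ok"] == "TRUE",
                    n_tm_domains=int(d["n_tm_domains"]),
                    max_control_rpkm=float(d["max_control_rpkm"]),
                    norm_log2fc=None if d["norm_log2fc"] == "NA" else float(d["norm_log2fc"]),
                    insitu_pattern=[] if d["insitu_pattern"] == "NA" else d["insitu_pattern"].split(","),
                )
            )
    return rows


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 3-column (node_i, node_j, p_value) edge list.

    Edges are undirected: self-edges are dropped and duplicate pairs keep
    the smaller p-value.  p must lie in (0, 1].
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, p_str = parts
            try:
                p = float(p_str)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric p-value {p_str!r}") from None
            if not (0.0 < p <= 1.0):
                raise FormatError(f"{path}:{lineno}: p-value {p} outside (0, 1]")
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in best:
                best[key] = p
                order.append(key)
            else:
                best[key] = min(best[key], p)
    return [(a, b, best[(a, b)]) for a, b in order]


def write_edge_list(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b, p in edges:
            fh.write(f"{a}\t{b}\t{p:.6g}\n")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick, with supports as internal node labels.

    Every leaf must be labeled; labels containing Newick metacharacters
    are quoted by the serializer.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError("tree contains an unlabeled leaf")
    with Path(path).open("w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(Path(path)), schema="newick")
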