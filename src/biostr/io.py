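"""Readers and writers for the plain-text formats the library touches.

All readers are gzip-transparent (detected by the magic bytes, not the file
name) and streaming.  Every writer's output is accepted by its reader.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ParseError, TreeError
from .model import Hit, HitKind, TaxonomyNode

__all__ = [
    "FastaRecord",
    "open_text",
    "read_fasta",
    "write_fasta",
    "read_hits",
    "write_hits",
    "read_taxonomy",
    "write_taxonomy",
    "to_zero_based",
    "to_one_based",
    "HIT_COLUMNS",
]

PathLike = Union[str, Path]

# Fixed column order of the similarity-hit table: BLAST outfmt-6-like,
# extended with the Smith-Waterman gross score and per-side gap counts.
HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "sw_score",
    "bit_score",
    "e_value",
    "pct_identity",
    "aln_length",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "q_gaps",
    "s_gaps",
)


def open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file transparently (UTF-8)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode, encoding="utf-8")
    elif path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record; ``header`` is the full line after '>'."""

    header: str
    residues: str

    @property
    def id(self) -> str:
        return self.header.split(None, 1)[0]

    @property
    def description(self) -> str:
        parts = self.header.split(None, 1)
        return parts[1] if len(parts) > 1 else ""


def read_fasta(path: PathLike) -> Iterator[FastaRecord]:
    """Stream FASTA records in file order; multi-line sequences concatenated,
    blank lines ignored.  An empty file yields nothing; any other content
    before the first '>' is a ParseError."""
    with open_text(path) as fh:
        started = False
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(f"expected FASTA header '>', got {line.strip()[:20]!r}")
            started = True
            break
        if not started:
            return
        fh.seek(0)
        for header, seq in SimpleFastaParser(fh):
            if not header.strip():
                raise ParseError("empty FASTA header")
            yield FastaRecord(header=header, residues=seq.upper())


def write_fasta(records: Iterable[FastaRecord], path: PathLike, wrap: int = 60) -> int:
    """Write records; ``wrap`` is the sequence line width (0 = single line).
    Returns the number of records written."""
    if wrap < 0:
        raise ValueError("wrap must be >= 0")
    n = 0
    with open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.header}\n")
            s = rec.residues
            if wrap == 0 or not s:
                fh.write(s + "\n")
            else:
                for i in range(0, len(s), wrap):
                    fh.write(s[i : i + wrap] + "\n")
            n += 1
    return n


def read_hits(path: PathLike, kind: HitKind = HitKind.PP) -> Iterator[Hit]:
    """Stream typed Hit records from a 13-column TSV (no header by default;
    lines starting with '#' are tolerated and skipped)."""
    int_cols = {
        "query_id", "subject_id", "sw_score", "aln_length",
        "q_start", "q_end", "s_start", "s_end", "q_gaps", "s_gaps",
    }
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise ParseError(
                    f"expected {len(HIT_COLUMNS)} columns, got {len(fields)}", lineno
                )
            kwargs: dict[str, float | int] = {}
            for name, value in zip(HIT_COLUMNS, fields):
                try:
                    kwargs[name] = int(value) if name in int_cols else float(value)
                except ValueError:
                    raise ParseError(f"non-numeric value {value!r} in column {name}", lineno)
            try:
                yield Hit(kind=kind, **kwargs)  # type: ignore[arg-type]
            except ValueError as exc:
                raise ParseError(str(exc), lineno)


def write_hits(hits: Iterable[Hit], path: PathLike) -> int:
    """Write hits as 13-column TSV; e-values in repr precision so reading
    them back is lossless."""
    n = 0
    with open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, col)) if col not in ("bit_score", "e_value", "pct_identity")
                    else repr(float(getattr(h, col)))
                    for col in HIT_COLUMNS
                )
                + "\n"
            )
            n += 1
    return n


def read_taxonomy(path: PathLike, dialect: str = "tsv") -> list[TaxonomyNode]:
    """Load and tree-validate taxonomy nodes.

    ``tsv`` dialect: ``taxonomy_id<TAB>parent_id<TAB>name<TAB>rank`` with an
    empty parent_id marking the root.  ``nodes_dmp`` dialect: the NCBI
    pipe-delimited nodes.dmp layout (id | parent | rank | ...), where a
    self-parenting row marks the root and names are left empty.
    Raises TreeError on a cycle, multiple roots, or a missing parent.
    """
    if dialect not in ("tsv", "nodes_dmp"):
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    nodes: list[TaxonomyNode] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                if dialect == "tsv":
                    fields = line.split("\t")
                    if len(fields) < 2:
                        raise ParseError("expected at least taxonomy_id and parent_id", lineno)
                    tax_id = int(fields[0])
                    parent = int(fields[1]) if fields[1].strip() else None
                    name = fields[2] if len(fields) > 2 else ""
                    rank = fields[3] if len(fields) > 3 else ""
                else:
                    fields = [f.strip() for f in line.split("|")]
                    if len(fields) < 3:
                        raise ParseError("expected id | parent | rank", lineno)
                    tax_id = int(fields[0])
                    parent = int(fields[1])
                    name, rank = "", fields[2]
            except ValueError:
                raise ParseError(f"non-integer taxonomy id in {line!r}", lineno)
            if parent == tax_id:
                parent = None  # self-parenting root convention
            nodes.append(TaxonomyNode(tax_id, parent, name, rank))
    # Validation (single root, acyclic, connected) happens in TaxonomyTree;
    # imported here lazily to keep io free of a circular dependency.
    from .taxonomy import TaxonomyTree

    TaxonomyTree(nodes)
    return nodes


def write_taxonomy(nodes: Iterable[TaxonomyNode], path: PathLike) -> int:
    """Write taxonomy nodes in the tsv dialect; returns the row count."""
    n = 0
    with open_text(path, "wt") as fh:
        for node in nodes:
            parent = "" if node.parent_id is None else str(node.parent_id)
            fh.write(f"{node.taxonomy_id}\t{parent}\t{node.name}\t{node.rank}\n")
            n += 1
    return n


def to_zero_based(start: int, stop: int) -> tuple[int, int]:
    """1-based closed [start, stop] to 0-based half-open [start-1, stop)."""
    if not (1 <= start <= stop):
        raise ValueError(f"require 1 <= start <= stop, got [{start}, {stop}]")
    return start - 1, stop


def to_one_based(start: int, stop: int) -> tuple[int, int]:
    """0-based half-open [start, stop) to 1-based closed [start+1, stop]."""
    if not (0 <= start < stop):
        raise ValueError(f"require 0 <= start < stop, got [{start}, {stop})")
    return start + 1, stop
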