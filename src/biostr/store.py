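"""Relational backend: the logical schema, loaders, and named queries.

Sequences live in plain ``TEXT`` columns — the whole point of the bio-string
type is that the relational text type, plus a vocabulary of domain functions,
is sufficient for biological sequences; no BLOB path exists.  Every
many-to-many relationship of the conceptual schema becomes an intermediate
table whose primary key is the composition of the two referenced keys; the
enzyme table carries a nullable ``father`` self-reference; the GO
self-relationship is a ``go_relationship`` table keyed by a sequential
``relationship_id``.

Each taxonomy/comparative operation is registered as a named query executed
in SQL (descendants via a recursive common table expression); the library's
in-memory implementations are the reference semantics and the two must agree
on every fixture (the dual-execution contract).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Optional, Union

from . import io as bio_io
from .comparative import DEFAULT_E_CUTOFF
from .errors import (
    IntegrityError,
    SchemaExistsError,
    UnknownProteinError,
    UnknownQueryError,
    UnknownTaxonError,
)
from .model import (
    CDS,
    ORFT,
    AnnotationRecord,
    Gene,
    GenomicSequence,
    Hit,
    HitKind,
    Protein,
    TaxonomyNode,
)
from .taxonomy import DEFAULT_GENOME_PREFIXES

__all__ = ["ColumnDef", "TableDef", "SchemaDefinition", "LoadReport", "Store", "SCHEMA"]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ColumnDef:
    name: str
    sql_type: str
    nullable: bool = True


@dataclass(frozen=True)
class TableDef:
    name: str
    columns: tuple[ColumnDef, ...]
    primary_key: tuple[str, ...]
    foreign_keys: tuple[tuple[str, str, str], ...] = ()  # (column, ref_table, ref_column)
    indexes: tuple[str, ...] = ()  # single-column secondary indexes

    def ddl(self) -> str:
        parts = []
        for c in self.columns:
            null = "" if c.nullable else " NOT NULL"
            parts.append(f"    {c.name} {c.sql_type}{null}")
        parts.append(f"    PRIMARY KEY ({', '.join(self.primary_key)})")
        for col, ref_t, ref_c in self.foreign_keys:
            parts.append(f"    FOREIGN KEY ({col}) REFERENCES {ref_t}({ref_c})")
        body = ",\n".join(parts)
        stmts = [f"CREATE TABLE {self.name} (\n{body}\n);"]
        for col in self.indexes:
            stmts.append(f"CREATE INDEX idx_{self.name}_{col} ON {self.name}({col});")
        return "\n".join(stmts)


@dataclass
class SchemaDefinition:
    tables: list[TableDef]
    version: str = SCHEMA_VERSION

    def ddl(self) -> str:
        return "\n\n".join(t.ddl() for t in self.tables) + "\n"

    def table_names(self) -> list[str]:
        return [t.name for t in self.tables]


def _hit_table(name: str, fk: tuple[tuple[str, str, str], ...], indexes: tuple[str, ...] = ()) -> TableDef:
    cols = (
        ColumnDef("hit_id", "INTEGER"),
        ColumnDef("query_id", "INTEGER", nullable=False),
        ColumnDef("subject_id", "INTEGER", nullable=False),
        ColumnDef("sw_score", "INTEGER", nullable=False),
        ColumnDef("bit_score", "REAL", nullable=False),
        ColumnDef("e_value", "REAL", nullable=False),
        ColumnDef("pct_identity", "REAL", nullable=False),
        ColumnDef("aln_length", "INTEGER", nullable=False),
        ColumnDef("q_start", "INTEGER", nullable=False),
        ColumnDef("q_end", "INTEGER", nullable=False),
        ColumnDef("s_start", "INTEGER", nullable=False),
        ColumnDef("s_end", "INTEGER", nullable=False),
        ColumnDef("q_gaps", "INTEGER", nullable=False),
        ColumnDef("s_gaps", "INTEGER", nullable=False),
    )
    return TableDef(name, cols, ("hit_id",), fk, indexes)


SCHEMA = SchemaDefinition(
    tables=[
        TableDef(
            "taxonomy",
            (
                ColumnDef("taxonomy_id", "INTEGER"),
                ColumnDef("parent_id", "INTEGER"),
                ColumnDef("name", "TEXT"),
                ColumnDef("rank", "TEXT"),
            ),
            ("taxonomy_id",),
            (("parent_id", "taxonomy", "taxonomy_id"),),
            ("parent_id",),
        ),
        TableDef(
            "genomic_sequence",
            (
                ColumnDef("gbkid", "TEXT"),
                ColumnDef("definition", "TEXT"),
                ColumnDef("length", "INTEGER", nullable=False),
                ColumnDef("molecule", "TEXT", nullable=False),
                ColumnDef("status", "TEXT", nullable=False),
                ColumnDef("seq_type", "TEXT", nullable=False),
                ColumnDef("genome_project_id", "TEXT"),
                ColumnDef("gc_content", "INTEGER"),
                ColumnDef("taxonomy_id", "INTEGER", nullable=False),
                ColumnDef("sequence", "TEXT"),  # the bio-string itself
            ),
            ("gbkid",),
            (("taxonomy_id", "taxonomy", "taxonomy_id"),),
            ("taxonomy_id",),
        ),
        TableDef(
            "gene",
            (
                ColumnDef("gene_id", "INTEGER"),
                ColumnDef("gbkid", "TEXT", nullable=False),
                ColumnDef("start", "INTEGER", nullable=False),
                ColumnDef("stop", "INTEGER", nullable=False),
                ColumnDef("strand", "TEXT", nullable=False),
                ColumnDef("transcript_id", "TEXT"),
                ColumnDef("gc_content", "INTEGER"),
            ),
            ("gene_id",),
            (("gbkid", "genomic_sequence", "gbkid"),),
            ("gbkid",),
        ),
        TableDef(
            "protein",
            (
                ColumnDef("protein_id", "INTEGER"),
                ColumnDef("source", "TEXT", nullable=False),
                ColumnDef("taxonomy_id", "INTEGER", nullable=False),
                ColumnDef("length", "INTEGER", nullable=False),
                ColumnDef("sequence", "TEXT"),
            ),
            ("protein_id",),
            (("taxonomy_id", "taxonomy", "taxonomy_id"),),
            ("taxonomy_id",),
        ),
        TableDef(
            "cds",
            (
                ColumnDef("cds_id", "INTEGER"),
                ColumnDef("protein_id", "INTEGER", nullable=False),
                ColumnDef("gene_id", "INTEGER", nullable=False),
                ColumnDef("gbkid", "TEXT", nullable=False),
            ),
            ("cds_id",),
            (
                ("protein_id", "protein", "protein_id"),
                ("gene_id", "gene", "gene_id"),
                ("gbkid", "genomic_sequence", "gbkid"),
            ),
        ),
        # One row per exon, first normal form.
        TableDef(
            "cds_exon",
            (
                ColumnDef("cds_id", "INTEGER"),
                ColumnDef("exon_index", "INTEGER"),
                ColumnDef("start", "INTEGER", nullable=False),
                ColumnDef("end", "INTEGER", nullable=False),
            ),
            ("cds_id", "exon_index"),
            (("cds_id", "cds", "cds_id"),),
        ),
        TableDef(
            "orft",
            (
                ColumnDef("orf_id", "INTEGER"),
                ColumnDef("gbkid", "TEXT", nullable=False),
                ColumnDef("start", "INTEGER", nullable=False),
                ColumnDef("stop", "INTEGER", nullable=False),
                ColumnDef("strand", "TEXT", nullable=False),
                ColumnDef("neighbor_gene_position", "TEXT"),
                ColumnDef("sequence", "TEXT"),
            ),
            ("orf_id",),
            (("gbkid", "genomic_sequence", "gbkid"),),
        ),
        _hit_table(
            "hit_pp",
            (
                ("query_id", "protein", "protein_id"),
                ("subject_id", "protein", "protein_id"),
            ),
            indexes=("query_id", "subject_id", "e_value"),
        ),
        _hit_table(
            "hit_op",
            (
                ("query_id", "orft", "orf_id"),
                ("subject_id", "protein", "protein_id"),
            ),
        ),
        _hit_table(
            "hit_oo",
            (
                ("query_id", "orft", "orf_id"),
                ("subject_id", "orft", "orf_id"),
            ),
        ),
        TableDef(
            "domain",
            (ColumnDef("domain_id", "TEXT"), ColumnDef("description", "TEXT")),
            ("domain_id",),
        ),
        TableDef(
            "enzyme",
            (
                ColumnDef("enzyme_id", "TEXT"),
                ColumnDef("description", "TEXT"),
                # nullable self-reference: the parent term in the EC hierarchy
                ColumnDef("father", "TEXT"),
            ),
            ("enzyme_id",),
            (("father", "enzyme", "enzyme_id"),),
        ),
        TableDef(
            "go_term",
            (
                ColumnDef("go_id", "TEXT"),
                ColumnDef("namespace", "TEXT"),
                ColumnDef("description", "TEXT"),
            ),
            ("go_id",),
        ),
        # Many-to-many GO self-relationship; the composite of the two term
        # ids cannot key it (the same pair may relate in several ways), hence
        # the sequential relationship_id primary key.
        TableDef(
            "go_relationship",
            (
                ColumnDef("relationship_id", "INTEGER"),
                ColumnDef("go_id", "TEXT", nullable=False),
                ColumnDef("related_go_id", "TEXT", nullable=False),
                ColumnDef("relationship_type", "TEXT"),
            ),
            ("relationship_id",),
            (
                ("go_id", "go_term", "go_id"),
                ("related_go_id", "go_term", "go_id"),
            ),
        ),
        # Intermediate tables for the many-to-many protein<->annotation
        # relationships; primary key = composition of the two referenced keys.
        TableDef(
            "domain_annotation",
            (ColumnDef("protein_id", "INTEGER"), ColumnDef("domain_id", "TEXT")),
            ("protein_id", "domain_id"),
            (
                ("protein_id", "protein", "protein_id"),
                ("domain_id", "domain", "domain_id"),
            ),
        ),
        TableDef(
            "enzyme_annotation",
            (ColumnDef("protein_id", "INTEGER"), ColumnDef("enzyme_id", "TEXT")),
            ("protein_id", "enzyme_id"),
            (
                ("protein_id", "protein", "protein_id"),
                ("enzyme_id", "enzyme", "enzyme_id"),
            ),
        ),
        TableDef(
            "go_annotation",
            (ColumnDef("protein_id", "INTEGER"), ColumnDef("go_id", "TEXT")),
            ("protein_id", "go_id"),
            (
                ("protein_id", "protein", "protein_id"),
                ("go_id", "go_term", "go_id"),
            ),
        ),
    ]
)

_HIT_TABLE_FOR_KIND = {HitKind.PP: "hit_pp", HitKind.OP: "hit_op", HitKind.OO: "hit_oo"}


@dataclass
class LoadReport:
    """Outcome of a bulk load: accepted row counts per table and rejects."""

    accepted: dict[str, int] = field(default_factory=dict)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (table, reason)

    @property
    def total_accepted(self) -> int:
        return sum(self.accepted.values())

    @property
    def total(self) -> int:
        return self.total_accepted + len(self.rejected)


class Store:
    """An embedded, file-based relational store (single writer).

    Readers see a consistent snapshot; concurrent writes are serialized by
    the engine.  ``path`` may be ':memory:' for a throwaway store.
    """

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = OFF")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- schema -----------------------------------------------------------

    def schema_exists(self) -> bool:
        row = self.conn.execute(
            "SELECT COUNT(*) FROM sqlite_master WHERE type='table' AND name='taxonomy'"
        ).fetchone()
        return row[0] > 0

    def create_schema(self, overwrite: bool = False) -> SchemaDefinition:
        """Create all tables and secondary indexes of schema version 1."""
        if self.schema_exists():
            if not overwrite:
                raise SchemaExistsError(f"schema already present in {self.path}")
            for name in reversed(SCHEMA.table_names()):
                self.conn.execute(f"DROP TABLE IF EXISTS {name}")
        self.conn.executescript(SCHEMA.ddl())
        self.conn.commit()
        return SCHEMA

    def emit_ddl(self, path: Union[str, Path]) -> str:
        """Write the schema DDL to a .sql file; returns the DDL text."""
        ddl = SCHEMA.ddl()
        Path(path).write_text(ddl, encoding="utf-8")
        return ddl

    def table_count(self, name: str) -> int:
        return self.conn.execute(f"SELECT COUNT(*) FROM {name}").fetchone()[0]

    # -- loading ----------------------------------------------------------

    def load_entities(self, records: Iterable[object], strict: bool = False) -> LoadReport:
        """Load typed records, enforcing referential integrity.

        Hits referencing unknown proteins (and genes/CDS referencing unknown
        genomic sequences) are rejected with a reason, or raise
        :class:`IntegrityError` in strict mode.  Conflicting primary keys are
        ignored, which makes loading idempotent.
        """
        report = LoadReport(accepted={t: 0 for t in SCHEMA.table_names()})
        cur = self.conn.cursor()

        def known(table: str, col: str, value) -> bool:
            return (
                cur.execute(
                    f"SELECT 1 FROM {table} WHERE {col} = ? LIMIT 1", (value,)
                ).fetchone()
                is not None
            )

        def reject(table: str, reason: str):
            if strict:
                self.conn.commit()
                raise IntegrityError(f"{table}: {reason}")
            report.rejected.append((table, reason))

        def accept(table: str, sql: str, params: tuple):
            cur.execute(sql, params)
            report.accepted[table] += cur.rowcount if cur.rowcount > 0 else 0

        for rec in records:
            if isinstance(rec, TaxonomyNode):
                accept(
                    "taxonomy",
                    "INSERT OR IGNORE INTO taxonomy VALUES (?,?,?,?)",
                    (rec.taxonomy_id, rec.parent_id, rec.name, rec.rank),
                )
            elif isinstance(rec, GenomicSequence):
                accept(
                    "genomic_sequence",
                    "INSERT OR IGNORE INTO genomic_sequence VALUES (?,?,?,?,?,?,?,?,?,?)",
                    (
                        rec.gbkid,
                        rec.definition,
                        rec.length,
                        rec.molecule.value,
                        rec.status.value,
                        rec.seq_type.value,
                        rec.genome_project_id,
                        rec.gc_content,
                        rec.taxonomy_id,
                        rec.residues.residues if rec.residues else None,
                    ),
                )
            elif isinstance(rec, Gene):
                if not known("genomic_sequence", "gbkid", rec.gbkid):
                    reject("gene", f"gene {rec.gene_id} references unknown genome {rec.gbkid}")
                    continue
                accept(
                    "gene",
                    "INSERT OR IGNORE INTO gene VALUES (?,?,?,?,?,?,?)",
                    (
                        rec.gene_id,
                        rec.gbkid,
                        rec.start,
                        rec.stop,
                        rec.strand.value,
                        rec.transcript_id,
                        rec.gc_content,
                    ),
                )
            elif isinstance(rec, Protein):
                accept(
                    "protein",
                    "INSERT OR IGNORE INTO protein VALUES (?,?,?,?,?)",
                    (
                        rec.protein_id,
                        rec.source.value,
                        rec.taxonomy_id,
                        rec.length,
                        rec.residues.residues if rec.residues else None,
                    ),
                )
            elif isinstance(rec, CDS):
                missing = [
                    msg
                    for cond, msg in (
                        (known("protein", "protein_id", rec.protein_id), f"unknown protein {rec.protein_id}"),
                        (known("gene", "gene_id", rec.gene_id), f"unknown gene {rec.gene_id}"),
                        (known("genomic_sequence", "gbkid", rec.gbkid), f"unknown genome {rec.gbkid}"),
                    )
                    if not cond
                ]
                if missing:
                    reject("cds", f"cds {rec.cds_id}: " + "; ".join(missing))
                    continue
                accept(
                    "cds",
                    "INSERT OR IGNORE INTO cds VALUES (?,?,?,?)",
                    (rec.cds_id, rec.protein_id, rec.gene_id, rec.gbkid),
                )
                for i, (s, e) in enumerate(rec.exons):
                    accept(
                        "cds_exon",
                        "INSERT OR IGNORE INTO cds_exon VALUES (?,?,?,?)",
                        (rec.cds_id, i, s, e),
                    )
            elif isinstance(rec, ORFT):
                if not known("genomic_sequence", "gbkid", rec.gbkid):
                    reject("orft", f"orf {rec.orf_id} references unknown genome {rec.gbkid}")
                    continue
                accept(
                    "orft",
                    "INSERT OR IGNORE INTO orft VALUES (?,?,?,?,?,?,?)",
                    (
                        rec.orf_id,
                        rec.gbkid,
                        rec.start,
                        rec.stop,
                        rec.strand.value,
                        rec.neighbor_gene_position,
                        rec.residues.residues if rec.residues else None,
                    ),
                )
            elif isinstance(rec, Hit):
                table = _HIT_TABLE_FOR_KIND[rec.kind]
                if rec.kind is HitKind.PP:
                    refs = [("query", rec.query_id), ("subject", rec.subject_id)]
                elif rec.kind is HitKind.OP:
                    refs = [("subject", rec.subject_id)]
                else:
                    refs = []
                bad = [f"{side} protein {pid}" for side, pid in refs if not known("protein", "protein_id", pid)]
                if bad:
                    reject(table, "hit references unknown " + ", ".join(bad))
                    continue
                self._insert_hit(cur, table, rec)
                report.accepted[table] += cur.rowcount if cur.rowcount > 0 else 0
            elif isinstance(rec, AnnotationRecord):
                self._insert_annotation(cur, rec, report, reject)
            else:
                reject("?", f"unsupported record type {type(rec).__name__}")
        self.conn.commit()
        return report

    def _insert_hit(self, cur: sqlite3.Cursor, table: str, h: Hit) -> None:
        # hit_id is derived from the row content so re-loading the same hit
        # is a no-op (idempotent loads).
        key = hash(
            (h.query_id, h.subject_id, h.sw_score, h.bit_score, h.e_value,
             h.pct_identity, h.aln_length, h.q_start, h.q_end, h.s_start,
             h.s_end, h.q_gaps, h.s_gaps)
        ) & 0x7FFFFFFFFFFFFFFF
        cur.execute(
            f"INSERT OR IGNORE INTO {table} VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (key, h.query_id, h.subject_id, h.sw_score, h.bit_score, h.e_value,
             h.pct_identity, h.aln_length, h.q_start, h.q_end, h.s_start,
             h.s_end, h.q_gaps, h.s_gaps),
        )

    def _insert_annotation(self, cur, rec: AnnotationRecord, report: LoadReport, reject) -> None:
        table = {"Pfam": "domain_annotation", "Enzyme": "enzyme_annotation", "GO": "go_annotation"}[
            rec.namespace
        ]
        term_table, term_col = {
            "Pfam": ("domain", "domain_id"),
            "Enzyme": ("enzyme", "enzyme_id"),
            "GO": ("go_term", "go_id"),
        }[rec.namespace]
        exists = cur.execute(
            f"SELECT 1 FROM protein WHERE protein_id = ?", (rec.protein_id,)
        ).fetchone()
        if exists is None:
            reject(table, f"annotation references unknown protein {rec.protein_id}")
            return
        extra = dict(rec.extra)
        if rec.namespace == "Enzyme":
            cur.execute(
                f"INSERT OR IGNORE INTO enzyme VALUES (?,?,?)",
                (rec.term_id, extra.get("description", ""), extra.get("father")),
            )
        elif rec.namespace == "GO":
            cur.execute(
                "INSERT OR IGNORE INTO go_term VALUES (?,?,?)",
                (rec.term_id, extra.get("namespace", ""), extra.get("description", "")),
            )
        else:
            cur.execute(
                "INSERT OR IGNORE INTO domain VALUES (?,?)",
                (rec.term_id, extra.get("description", "")),
            )
        report.accepted[term_table] += cur.rowcount if cur.rowcount > 0 else 0
        cur.execute(
            f"INSERT OR IGNORE INTO {table} VALUES (?,?)", (rec.protein_id, rec.term_id)
        )
        report.accepted[table] += cur.rowcount if cur.rowcount > 0 else 0

    def load_hits_filtered(
        self, path: Union[str, Path], e_max: float = DEFAULT_E_CUTOFF, kind: HitKind = HitKind.PP
    ) -> int:
        """Load only the hit rows whose e-value <= ``e_max``; returns the
        number inserted."""
        table = _HIT_TABLE_FOR_KIND[HitKind(kind)]
        cur = self.conn.cursor()
        n = 0
        for h in bio_io.read_hits(path, kind=kind):
            if h.e_value <= e_max:
                self._insert_hit(cur, table, h)
                n += cur.rowcount if cur.rowcount > 0 else 0
        self.conn.commit()
        return n

    # -- named queries (the stored-function dispatch surface) -------------

    def run_query(self, name: str, *params: Any, **kwparams: Any) -> Any:
        """Execute a registered named query against the store."""
        try:
            fn = _QUERIES[name]
        except KeyError:
            raise UnknownQueryError(name)
        return fn(self, *params, **kwparams)

    # helpers shared by the SQL query bodies

    def _require_taxon(self, tax_id: int) -> None:
        row = self.conn.execute(
            "SELECT 1 FROM taxonomy WHERE taxonomy_id = ?", (tax_id,)
        ).fetchone()
        if row is None:
            raise UnknownTaxonError(tax_id)

    def _require_protein(self, protein_id: int) -> None:
        row = self.conn.execute(
            "SELECT 1 FROM protein WHERE protein_id = ?", (protein_id,)
        ).fetchone()
        if row is None:
            raise UnknownProteinError(protein_id)

    # -- materializing back into memory (for dual execution) --------------

    def taxonomy_nodes(self) -> list[TaxonomyNode]:
        rows = self.conn.execute(
            "SELECT taxonomy_id, parent_id, name, rank FROM taxonomy ORDER BY taxonomy_id"
        ).fetchall()
        return [TaxonomyNode(*r) for r in rows]

    def proteins(self) -> list[Protein]:
        rows = self.conn.execute(
            "SELECT protein_id, source, taxonomy_id, length FROM protein ORDER BY protein_id"
        ).fetchall()
        return [Protein(protein_id=r[0], source=r[1], taxonomy_id=r[2], length=r[3]) for r in rows]

    def genomic_sequences(self) -> list[GenomicSequence]:
        rows = self.conn.execute(
            "SELECT gbkid, definition, length, molecule, status, seq_type,"
            " genome_project_id, gc_content, taxonomy_id FROM genomic_sequence ORDER BY gbkid"
        ).fetchall()
        return [
            GenomicSequence(
                gbkid=r[0], definition=r[1], length=r[2], molecule=r[3], status=r[4],
                seq_type=r[5], genome_project_id=r[6], gc_content=r[7], taxonomy_id=r[8],
            )
            for r in rows
        ]

    def hits(self, kind: HitKind = HitKind.PP) -> list[Hit]:
        table = _HIT_TABLE_FOR_KIND[HitKind(kind)]
        rows = self.conn.execute(
            f"SELECT query_id, subject_id, sw_score, bit_score, e_value, pct_identity,"
            f" aln_length, q_start, q_end, s_start, s_end, q_gaps, s_gaps FROM {table}"
            f" ORDER BY hit_id"
        ).fetchall()
        return [Hit(*r, kind=kind) for r in rows]


# --------------------------------------------------------------------------
# SQL bodies of the named queries.  Group membership is always computed with
# the same recursive CTE over the taxonomy table.

_DESCENDANTS_CTE = """
WITH RECURSIVE subtree(taxonomy_id) AS (
    SELECT taxonomy_id FROM taxonomy WHERE taxonomy_id = :tax
    UNION
    SELECT t.taxonomy_id FROM taxonomy t JOIN subtree s ON t.parent_id = s.taxonomy_id
)
"""


def _q_descendants(store: Store, tax_id: int, include_self: bool = True) -> set[int]:
    store._require_taxon(tax_id)
    rows = store.conn.execute(
        _DESCENDANTS_CTE + "SELECT taxonomy_id FROM subtree", {"tax": tax_id}
    ).fetchall()
    result = {r[0] for r in rows}
    if not include_self:
        result.discard(tax_id)
    return result


def _q_lineage(store: Store, tax_id: int) -> list[int]:
    store._require_taxon(tax_id)
    rows = store.conn.execute(
        """
        WITH RECURSIVE up(taxonomy_id, parent_id, depth) AS (
            SELECT taxonomy_id, parent_id, 0 FROM taxonomy WHERE taxonomy_id = :tax
            UNION ALL
            SELECT t.taxonomy_id, t.parent_id, u.depth + 1
            FROM taxonomy t JOIN up u ON t.taxonomy_id = u.parent_id
        )
        SELECT taxonomy_id FROM up ORDER BY depth DESC
        """,
        {"tax": tax_id},
    ).fetchall()
    return [r[0] for r in rows]


def _q_count_genomes(
    store: Store, tax_id: int, prefixes: Optional[Iterable[str]] = None
) -> int:
    store._require_taxon(tax_id)
    if prefixes is None:
        prefixes = DEFAULT_GENOME_PREFIXES
    prefixes = sorted(prefixes)
    if not prefixes:
        return 0
    # Prefix match via LIKE with escaping ('_' is a LIKE wildcard and occurs
    # in every accession prefix).
    prefix_clause = " OR ".join("gbkid LIKE ? ESCAPE '\\'" for _ in prefixes)
    args = [
        p.replace("\\", "\\\\").replace("%", r"\%").replace("_", r"\_") + "%"
        for p in prefixes
    ]
    row = store.conn.execute(
        _DESCENDANTS_CTE.replace(":tax", "?")
        + f"""
        SELECT COUNT(*) FROM genomic_sequence
        WHERE taxonomy_id IN (SELECT taxonomy_id FROM subtree) AND ({prefix_clause})
        """,
        [tax_id, *args],
    ).fetchone()
    return row[0]


def _q_count_proteins(store: Store, tax_id: int) -> int:
    store._require_taxon(tax_id)
    row = store.conn.execute(
        _DESCENDANTS_CTE
        + """
        SELECT COUNT(*) FROM protein
        WHERE taxonomy_id IN (SELECT taxonomy_id FROM subtree)
        """,
        {"tax": tax_id},
    ).fetchone()
    return row[0]


def _q_count_hits_protein(
    store: Store,
    protein_id: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    kinds: Iterable[HitKind] = (HitKind.PP,),
) -> int:
    store._require_protein(protein_id)
    total = 0
    for kind in {HitKind(k) for k in kinds}:
        table = _HIT_TABLE_FOR_KIND[kind]
        if kind is HitKind.OP:
            where = "subject_id = :pid"
        else:
            where = "(query_id = :pid OR subject_id = :pid)"
        row = store.conn.execute(
            f"SELECT COUNT(*) FROM {table} WHERE {where} AND e_value <= :e",
            {"pid": protein_id, "e": e_cutoff},
        ).fetchone()
        total += row[0]
    return total


def _q_get_protein_taxonomy(store: Store, tax_id: int) -> list[int]:
    store._require_taxon(tax_id)
    rows = store.conn.execute(
        _DESCENDANTS_CTE
        + """
        SELECT protein_id FROM protein
        WHERE taxonomy_id IN (SELECT taxonomy_id FROM subtree)
        ORDER BY protein_id
        """,
        {"tax": tax_id},
    ).fetchall()
    return [r[0] for r in rows]


_GROUPS_CTE = """
WITH RECURSIVE sub_a(taxonomy_id) AS (
    SELECT taxonomy_id FROM taxonomy WHERE taxonomy_id = :taxa
    UNION
    SELECT t.taxonomy_id FROM taxonomy t JOIN sub_a s ON t.parent_id = s.taxonomy_id
),
sub_b(taxonomy_id) AS (
    SELECT taxonomy_id FROM taxonomy WHERE taxonomy_id = :taxb
    UNION
    SELECT t.taxonomy_id FROM taxonomy t JOIN sub_b s ON t.parent_id = s.taxonomy_id
),
group_a(protein_id) AS (
    SELECT protein_id FROM protein WHERE taxonomy_id IN (SELECT taxonomy_id FROM sub_a)
),
group_b(protein_id) AS (
    SELECT protein_id FROM protein
    WHERE taxonomy_id IN (SELECT taxonomy_id FROM sub_b)
      AND protein_id NOT IN (SELECT protein_id FROM group_a)
)
"""


def _q_get_similar_proteins(
    store: Store, tax_a: int, tax_b: int, e_cutoff: float = DEFAULT_E_CUTOFF
) -> set[int]:
    store._require_taxon(tax_a)
    store._require_taxon(tax_b)
    rows = store.conn.execute(
        _GROUPS_CTE
        + """
        SELECT query_id FROM hit_pp
        WHERE e_value <= :e
          AND query_id IN (SELECT protein_id FROM group_a)
          AND subject_id IN (SELECT protein_id FROM group_b)
        UNION
        SELECT subject_id FROM hit_pp
        WHERE e_value <= :e
          AND subject_id IN (SELECT protein_id FROM group_a)
          AND query_id IN (SELECT protein_id FROM group_b)
        """,
        {"taxa": tax_a, "taxb": tax_b, "e": e_cutoff},
    ).fetchall()
    return {r[0] for r in rows}


def _q_get_single_genes(
    store: Store, tax_a: int, tax_b: int, e_cutoff: float = DEFAULT_E_CUTOFF
) -> set[int]:
    store._require_taxon(tax_a)
    store._require_taxon(tax_b)
    rows = store.conn.execute(
        _GROUPS_CTE
        + """
        SELECT protein_id FROM group_a
        EXCEPT
        SELECT query_id FROM hit_pp
        WHERE e_value <= :e
          AND query_id IN (SELECT protein_id FROM group_a)
          AND subject_id IN (SELECT protein_id FROM group_b)
        EXCEPT
        SELECT subject_id FROM hit_pp
        WHERE e_value <= :e
          AND subject_id IN (SELECT protein_id FROM group_a)
          AND query_id IN (SELECT protein_id FROM group_b)
        """,
        {"taxa": tax_a, "taxb": tax_b, "e": e_cutoff},
    ).fetchall()
    return {r[0] for r in rows}


def _q_get_orthologous_genes(
    store: Store, tax_a: int, tax_b: int, e_cutoff: float = DEFAULT_E_CUTOFF
) -> list[tuple[int, int]]:
    store._require_taxon(tax_a)
    store._require_taxon(tax_b)
    rows = store.conn.execute(
        _GROUPS_CTE
        + """
        SELECT query_id AS a, subject_id AS b FROM hit_pp
        WHERE e_value <= :e
          AND query_id IN (SELECT protein_id FROM group_a)
          AND subject_id IN (SELECT protein_id FROM group_b)
        UNION
        SELECT subject_id AS a, query_id AS b FROM hit_pp
        WHERE e_value <= :e
          AND subject_id IN (SELECT protein_id FROM group_a)
          AND query_id IN (SELECT protein_id FROM group_b)
        ORDER BY a, b
        """,
        {"taxa": tax_a, "taxb": tax_b, "e": e_cutoff},
    ).fetchall()
    return [(r[0], r[1]) for r in rows]


def _q_get_paralogous_genes(
    store: Store, tax_id: int, e_cutoff: float = DEFAULT_E_CUTOFF
) -> list[tuple[int, int]]:
    store._require_taxon(tax_id)
    rows = store.conn.execute(
        _DESCENDANTS_CTE
        + """
        , grp(protein_id) AS (
            SELECT protein_id FROM protein
            WHERE taxonomy_id IN (SELECT taxonomy_id FROM subtree)
        )
        SELECT MIN(query_id, subject_id) AS p, MAX(query_id, subject_id) AS q
        FROM hit_pp
        WHERE e_value <= :e
          AND query_id <> subject_id
          AND query_id IN (SELECT protein_id FROM grp)
          AND subject_id IN (SELECT protein_id FROM grp)
        GROUP BY p, q
        ORDER BY p, q
        """,
        {"tax": tax_id, "e": e_cutoff},
    ).fetchall()
    return [(r[0], r[1]) for r in rows]


_QUERIES: dict[str, Callable[..., Any]] = {
    "descendants": _q_descendants,
    "lineage": _q_lineage,
    "count_genomes_by_taxon": _q_count_genomes,
    "count_proteins_by_taxon": _q_count_proteins,
    "count_hits_protein": _q_count_hits_protein,
    "get_protein_taxonomy": _q_get_protein_taxonomy,
    "get_similar_proteins": _q_get_similar_proteins,
    "get_single_genes": _q_get_single_genes,
    "get_orthologous_genes": _q_get_orthologous_genes,
    "get_paralogous_genes": _q_get_paralogous_genes,
}
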