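"""Validated domain types: the conceptual schema as in-memory records.

The central idea is the *bio-string*: a character sequence that carries its
biological semantics (molecule kind and alphabet) with it, instead of being a
bare string.  Every other record type here — genomic sequences, genes, CDS,
proteins, translated ORFs, similarity hits, taxonomy nodes — wraps or points
at bio-strings and enforces its own invariants at construction time, so that
downstream operations never need to re-validate.

Coordinates are 1-based, fully closed intervals (the GenBank convention);
converters to 0-based half-open live in :mod:`biostr.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import AlphabetError, CodeTableError

__all__ = [
    "Molecule",
    "Strand",
    "GenomeStatus",
    "SeqType",
    "ProteinSource",
    "HitKind",
    "BioSequence",
    "GenomicSequence",
    "Gene",
    "CDS",
    "Protein",
    "ORFT",
    "Hit",
    "TaxonomyNode",
    "GeneticCodeTable",
    "AnnotationRecord",
    "validate_sequence",
    "NUCLEOTIDE_AMBIGUITY",
]


class Molecule(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "PROTEIN"


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


class GenomeStatus(str, enum.Enum):
    COMPLETE = "Complete"
    ASSEMBLY = "Assembly"
    IN_PROGRESS = "InProgress"


class SeqType(str, enum.Enum):
    CHROMOSOME = "chromosome"
    ORGANELLE = "organelle"
    PLASMID = "plasmid"


class ProteinSource(str, enum.Enum):
    REFSEQ = "RefSeq"
    SWISSPROT = "SwissProt"
    SYNTHETIC = "synthetic"


class HitKind(str, enum.Enum):
    PP = "PP"  # protein x protein
    OP = "OP"  # translated ORF (query) x protein (subject)
    OO = "OO"  # translated ORF x translated ORF


# IUPAC one-letter ambiguity codes shared by DNA and RNA.
NUCLEOTIDE_AMBIGUITY = frozenset("RYSWKMBDHVN")

_DNA_ALPHABET = frozenset("ACGT") | NUCLEOTIDE_AMBIGUITY
_RNA_ALPHABET = frozenset("ACGU") | NUCLEOTIDE_AMBIGUITY
_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("X*")

_ALPHABETS = {
    Molecule.DNA: _DNA_ALPHABET,
    Molecule.RNA: _RNA_ALPHABET,
    Molecule.PROTEIN: _PROTEIN_ALPHABET,
}

# RefSeq accession prefixes for genomic molecules.
GENOMIC_PREFIXES = ("AC_", "NC_", "NG_", "NT_", "NW_", "NZ_", "NS_")


@dataclass(frozen=True)
class BioSequence:
    """A validated biological string: residues plus molecule semantics.

    Residues are stored uppercase.  DNA never contains U, RNA never contains
    T, protein residues are the 20 one-letter codes plus X (unknown) and
    ``*`` (translation stop).
    """

    residues: str
    molecule: Molecule
    seq_id: str = ""

    def __post_init__(self):
        alphabet = _ALPHABETS[self.molecule]
        for i, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise AlphabetError(ch, i + 1, self.molecule.value)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def validate_sequence(raw: str, molecule: Molecule, seq_id: str = "") -> BioSequence:
    """Normalize raw text (strip whitespace, uppercase) into a BioSequence.

    Raises :class:`AlphabetError` naming the first offending character and
    its 1-based position in the *normalized* string.
    """
    molecule = Molecule(molecule)
    cleaned = "".join(raw.split()).upper()
    return BioSequence(cleaned, molecule, seq_id)


@dataclass
class GenomicSequence:
    """A genomic nucleotide molecule (chromosome, organelle or plasmid)."""

    gbkid: str
    taxonomy_id: int
    length: int = 0
    definition: str = ""
    molecule: Molecule = Molecule.DNA
    status: GenomeStatus = GenomeStatus.COMPLETE
    seq_type: SeqType = SeqType.CHROMOSOME
    genome_project_id: Optional[str] = None
    gc_content: int = 0  # count of G+C bases, not a fraction
    residues: Optional[BioSequence] = None

    def __post_init__(self):
        self.molecule = Molecule(self.molecule)
        if self.molecule is Molecule.PROTEIN:
            raise ValueError("genomic sequences are DNA or RNA")
        self.status = GenomeStatus(self.status)
        self.seq_type = SeqType(self.seq_type)
        if self.residues is not None:
            if self.residues.molecule is not self.molecule:
                raise ValueError("residues molecule does not match record molecule")
            if self.length == 0:
                self.length = len(self.residues)
            elif self.length != len(self.residues):
                raise ValueError(
                    f"declared length {self.length} != sequence length {len(self.residues)}"
                )
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if self.gc_content < 0:
            raise ValueError("gc_content must be non-negative")
        if not _plausible_accession(self.gbkid):
            raise ValueError(f"accession {self.gbkid!r} lacks a recognisable prefix")


def _plausible_accession(gbkid: str) -> bool:
    # Documented RefSeq prefixes, or any synthetic XX_/XXX_ style prefix.
    if any(gbkid.startswith(p) for p in GENOMIC_PREFIXES):
        return True
    head, _, tail = gbkid.partition("_")
    return bool(tail) and head.isalpha() and 1 <= len(head) <= 4


@dataclass
class Gene:
    """A gene region on a genomic sequence (1-based closed coordinates)."""

    gene_id: int
    gbkid: str
    start: int
    stop: int
    strand: Strand = Strand.FORWARD
    transcript_id: Optional[str] = None
    gc_content: int = 0  # count, mirroring GenomicSequence.gc_content

    def __post_init__(self):
        self.strand = Strand(self.strand)
        if not (1 <= self.start <= self.stop):
            raise ValueError(f"require 1 <= start <= stop, got [{self.start}, {self.stop}]")
        if self.gc_content < 0:
            raise ValueError("gc_content must be non-negative")


@dataclass
class CDS:
    """Coding sequence: the exon coordinate list linking protein, gene and genome."""

    cds_id: int
    protein_id: int
    gene_id: int
    gbkid: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError("CDS requires at least one exon")
        prev_end = 0
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError("exons must be sorted by start and non-overlapping")
            prev_end = e


@dataclass
class Protein:
    """A protein sequence; carries taxonomy_id directly (a protein may be
    sequenced without a known source genome)."""

    protein_id: int
    taxonomy_id: int
    source: ProteinSource = ProteinSource.SYNTHETIC
    residues: Optional[BioSequence] = None
    length: int = 0

    def __post_init__(self):
        self.source = ProteinSource(self.source)
        if self.residues is not None:
            if self.residues.molecule is not Molecule.PROTEIN:
                raise ValueError("protein residues must be a PROTEIN BioSequence")
            if self.length == 0:
                self.length = len(self.residues)
        if self.length < 0:
            raise ValueError("length must be non-negative")


@dataclass
class ORFT:
    """A translated open reading frame: an amino-acid sequence located on a
    genomic sequence by an ORF region (it has no external identifier of its
    own, hence a synthetic orf_id)."""

    orf_id: int
    gbkid: str
    start: int
    stop: int
    strand: Strand = Strand.FORWARD
    neighbor_gene_position: Optional[str] = None
    residues: Optional[BioSequence] = None

    def __post_init__(self):
        self.strand = Strand(self.strand)
        if not (1 <= self.start <= self.stop):
            raise ValueError(f"require 1 <= start <= stop, got [{self.start}, {self.stop}]")
        if self.residues is not None and self.residues.molecule is not Molecule.PROTEIN:
            raise ValueError("ORFT residues must be a PROTEIN BioSequence")


@dataclass
class Hit:
    """One pairwise similarity record with Smith-Waterman statistics."""

    query_id: int
    subject_id: int
    sw_score: int
    bit_score: float
    e_value: float
    pct_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_gaps: int = 0
    s_gaps: int = 0
    kind: HitKind = HitKind.PP

    def __post_init__(self):
        self.kind = HitKind(self.kind)
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity must lie in [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be positive")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("alignment coordinates must satisfy start <= end")
        if self.q_gaps < 0 or self.s_gaps < 0:
            raise ValueError("gap counts must be non-negative")


@dataclass(frozen=True)
class TaxonomyNode:
    """One node of the taxonomic tree; parent_id None marks the root."""

    taxonomy_id: int
    parent_id: Optional[int]
    name: str = ""
    rank: str = ""


@dataclass
class GeneticCodeTable:
    """A 64-codon translation table over the RNA alphabet.

    ``codon_map`` maps every codon to a one-letter amino acid or '*' (stop);
    ``stop_codons`` must be exactly the codons mapping to '*'.
    """

    codon_map: dict[str, str]
    start_codons: frozenset[str] = frozenset({"AUG"})
    stop_codons: frozenset[str] = frozenset()
    name: str = "standard"

    def __post_init__(self):
        if len(self.codon_map) != 64:
            raise CodeTableError(
                f"genetic code must define exactly 64 codons, got {len(self.codon_map)}"
            )
        legal_aa = _PROTEIN_ALPHABET - {"X"}
        for codon, aa in self.codon_map.items():
            if len(codon) != 3 or any(ch not in "ACGU" for ch in codon):
                raise CodeTableError(f"bad RNA codon {codon!r}")
            if aa not in legal_aa:
                raise CodeTableError(f"illegal amino-acid letter {aa!r} for codon {codon}")
        derived_stops = frozenset(c for c, aa in self.codon_map.items() if aa == "*")
        if not self.stop_codons:
            self.stop_codons = derived_stops
        elif frozenset(self.stop_codons) != derived_stops:
            raise CodeTableError("stop_codons inconsistent with codons mapping to '*'")
        self.start_codons = frozenset(self.start_codons)
        unknown_starts = self.start_codons - set(self.codon_map)
        if unknown_starts:
            raise CodeTableError(f"start codons not in table: {sorted(unknown_starts)}")

    def translate_codon(self, codon: str) -> str:
        """One codon to one letter; any ambiguity letter yields 'X'."""
        return self.codon_map.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


@dataclass(frozen=True)
class AnnotationRecord:
    """A (protein, namespace, term) annotation; extra carries namespace
    specifics such as an enzyme parent term or a GO relationship type."""

    protein_id: int
    namespace: str  # Pfam | Enzyme | GO
    term_id: str
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.namespace not in ("Pfam", "Enzyme", "GO"):
            raise ValueError(f"unknown annotation namespace {self.namespace!r}")
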