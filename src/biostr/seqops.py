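"""Biological string functions: GC content, transcription, translation, ORF search.

These are the domain operations that turn a bare character string into a
*bio-string*.  GC content deliberately follows the text-type idiom of
deleting every non-G/C character and measuring the remaining length — the
point being that a plain string type plus a small function vocabulary is
enough to express the biology.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

from .errors import CodeTableError, FrameError
from .model import BioSequence, GeneticCodeTable, Molecule

__all__ = [
    "OrfRecord",
    "gc_content",
    "gc_fraction",
    "transcribe",
    "reverse_complement",
    "translate",
    "search_orfs",
    "load_genetic_code",
    "standard_code",
]

_UNAMBIGUOUS = frozenset("ACGTU")

_DNA_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame: an AUG...stop span in a fixed frame.

    Coordinates are 1-based on the input sequence; ``end`` is the last base
    of the stop codon, which is included in the span but excluded from the
    peptide.  ``nt_length`` is therefore 3 * (len(peptide) + 1).
    """

    frame: int
    start: int
    end: int
    peptide: str

    def __post_init__(self):
        if self.frame not in (1, 2, 3):
            raise FrameError(f"frame must be 1, 2 or 3, got {self.frame}")
        if self.nt_length % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if not self.peptide.startswith("M"):
            raise ValueError("ORF peptide must begin with Met")
        if self.nt_length != 3 * (len(self.peptide) + 1):
            raise ValueError("span length inconsistent with peptide length")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


def _require_nucleotide(seq: BioSequence) -> None:
    if seq.molecule is Molecule.PROTEIN:
        raise TypeError("operation requires a nucleotide sequence, got PROTEIN")


def gc_content(seq: BioSequence) -> int:
    """Number of G and C bases, via the replace trick.

    Every character other than G or C is replaced by the empty string and the
    length of what remains is the answer.  Ambiguity letters (including S,
    which denotes G-or-C) do not count.
    """
    _require_nucleotide(seq)
    s = seq.residues
    for ch in set(s) - {"G", "C"}:
        s = s.replace(ch, "")
    return len(s)


def gc_fraction(seq: BioSequence) -> float:
    """gc_content divided by the count of unambiguous A, C, G, T, U bases.

    Ambiguity letters are excluded from the denominator.  Raises ValueError
    on an empty sequence (or one made entirely of ambiguity letters).
    """
    _require_nucleotide(seq)
    denom = sum(1 for ch in seq.residues if ch in _UNAMBIGUOUS)
    if denom == 0:
        raise ValueError("gc_fraction undefined: no unambiguous bases")
    return gc_content(seq) / denom


def transcribe(dna: BioSequence) -> BioSequence:
    """DNA to mRNA under the coding-strand convention: T becomes U in place."""
    if dna.molecule is not Molecule.DNA:
        raise TypeError(f"transcribe requires DNA input, got {dna.molecule.value}")
    return BioSequence(dna.residues.replace("T", "U"), Molecule.RNA, dna.seq_id)


def reverse_complement(seq: BioSequence) -> BioSequence:
    """Watson-Crick complement then reversal; an involution on DNA strings."""
    if seq.molecule is not Molecule.DNA:
        raise TypeError(f"reverse_complement requires DNA input, got {seq.molecule.value}")
    return BioSequence(
        seq.residues.translate(_DNA_COMPLEMENT)[::-1], Molecule.DNA, seq.seq_id
    )


def _check_frame(frame: int) -> None:
    if frame not in (1, 2, 3):
        raise FrameError(f"frame must be 1, 2 or 3, got {frame}")


def translate(
    rna: BioSequence,
    frame: int = 1,
    code: GeneticCodeTable | None = None,
    stop_policy: str = "truncate_at_stop",
) -> BioSequence:
    """Translate consecutive codons starting at offset ``frame - 1``.

    A trailing partial codon is ignored.  Any codon containing an ambiguity
    letter yields X.  With ``truncate_at_stop`` (default) translation ends
    before the first stop codon; with ``read_through`` stops are emitted as
    '*' and translation continues to the end.
    """
    _check_frame(frame)
    if rna.molecule is not Molecule.RNA:
        raise TypeError(f"translate requires RNA input, got {rna.molecule.value}")
    if stop_policy not in ("truncate_at_stop", "read_through"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    if code is None:
        code = standard_code()
    s = rna.residues
    out: list[str] = []
    for i in range(frame - 1, len(s) - 2, 3):
        codon = s[i : i + 3]
        if code.is_stop(codon):
            if stop_policy == "truncate_at_stop":
                break
            out.append("*")
        else:
            out.append(code.translate_codon(codon))
    return BioSequence("".join(out), Molecule.PROTEIN, rna.seq_id)


def search_orfs(
    seq: BioSequence,
    frame: int = 1,
    min_peptide_len: int = 1,
    code: GeneticCodeTable | None = None,
) -> list[OrfRecord]:
    """Every AUG...stop span in one reading frame, in ascending start order.

    DNA input is transcribed first (a convenience guard against passing the
    wrong molecule), so coordinates always refer to the input sequence.  All
    in-frame AUGs are reported, including nested starts that share a stop;
    callers wanting one ORF per stop can post-filter to the longest.  Spans
    whose stop codon falls beyond the sequence end are not reported — an ORF
    is bounded by its stop.  ``min_peptide_len`` counts peptide residues,
    stop excluded.
    """
    _check_frame(frame)
    if min_peptide_len < 1:
        raise ValueError(f"min_peptide_len must be >= 1, got {min_peptide_len}")
    if seq.molecule is Molecule.PROTEIN:
        raise TypeError("search_orfs requires a nucleotide sequence")
    if seq.molecule is Molecule.DNA:
        seq = transcribe(seq)
    if code is None:
        code = standard_code()

    s = seq.residues
    orfs: list[OrfRecord] = []
    open_starts: list[int] = []  # 0-based codon start offsets awaiting a stop
    for i in range(frame - 1, len(s) - 2, 3):
        codon = s[i : i + 3]
        if code.is_stop(codon):
            for start in open_starts:
                peptide = "".join(
                    code.translate_codon(s[j : j + 3]) for j in range(start, i, 3)
                )
                if len(peptide) >= min_peptide_len:
                    orfs.append(
                        OrfRecord(frame=frame, start=start + 1, end=i + 3, peptide=peptide)
                    )
            open_starts.clear()
        elif codon == "AUG":
            open_starts.append(i)
    orfs.sort(key=lambda o: o.start)
    return orfs


def load_genetic_code(path: Union[str, Path]) -> GeneticCodeTable:
    """Load a genetic-code table from a tab-separated file.

    Expected dialect: header ``codon<TAB>aa<TAB>is_start`` followed by 64
    data rows over the RNA alphabet; ``aa`` is a one-letter amino acid or
    '*'; ``is_start`` is 0/1.
    """
    path = Path(path)
    codon_map: dict[str, str] = {}
    starts: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["codon", "aa", "is_start"]:
            raise CodeTableError(f"{path}: expected header 'codon<TAB>aa<TAB>is_start'")
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise CodeTableError(f"{path}: malformed row {row!r}")
            codon, aa, is_start = row[0].strip().upper(), row[1].strip(), row[2].strip()
            if codon in codon_map:
                raise CodeTableError(f"{path}: duplicate codon {codon}")
            codon_map[codon] = aa
            if is_start not in ("0", "1"):
                raise CodeTableError(f"{path}: is_start must be 0 or 1, got {is_start!r}")
            if is_start == "1":
                starts.add(codon)
    return GeneticCodeTable(codon_map=codon_map, start_codons=frozenset(starts), name=path.stem)


_STANDARD: GeneticCodeTable | None = None


def standard_code() -> GeneticCodeTable:
    """The standard genetic code, loaded once from the packaged table."""
    global _STANDARD
    if _STANDARD is None:
        ref = resources.files("biostr").joinpath("data/standard_code.tsv")
        with resources.as_file(ref) as p:
            _STANDARD = load_genetic_code(p)
    return _STANDARD
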