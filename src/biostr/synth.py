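"""Deterministic synthetic fixtures with recorded ground truth.

The generator builds a miniature comparative-genomics study: a taxonomy
tree, genomes with open reading frames planted at recorded coordinates,
proteomes for the leaf taxa, and a similarity-hit table wired to a known
homology structure — ortholog pairs across two designated taxa, paralog
families as within-taxon hit cliques in a third taxon, and unique proteins
with no qualifying cross-taxon hit (optionally shadowed by decoy hits above
the significance cutoff).  Hits are wired, not computed by alignment; the
point is exact, seed-reproducible ground truth for the query functions.

Every random quantity is drawn from one seeded stream in a fixed order, so
the same seed always yields byte-identical output files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

from . import io as bio_io
from .comparative import DEFAULT_E_CUTOFF
from .errors import SpecError
from .model import (
    BioSequence,
    GenomicSequence,
    Hit,
    HitKind,
    Molecule,
    Protein,
    ProteinSource,
    TaxonomyNode,
)
from .taxonomy import TaxonomyTree

__all__ = ["SynthSpec", "GroundTruth", "SynthBundle", "build", "generate", "read_manifest"]

# Codons free of adenine: in clean mode ORF interiors are built from these,
# so no in-frame stop (UAA/UGA/UAG all contain A) and no internal AUG can
# occur, and planted ORF coordinates are exact.
_A_FREE_CODONS = {
    "F": "UUC", "L": "CUG", "S": "UCC", "P": "CCG", "R": "CGC",
    "V": "GUG", "G": "GGC", "C": "UGC", "W": "UGG",
}
_STOPS = ("UAA", "UGA", "UAG")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "UCAG" for b in "UCAG" for c in "UCAG"
    if a + b + c not in _STOPS
)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small two-proteome comparison: a depth-3 binary
    taxonomy (15 nodes, 8 leaf taxa), one 2000-base genome per leaf with
    three planted ORFs of 20-60 residues on a 50% GC background, five
    background proteins per non-designated leaf taxon, and a homology plan
    of 3 ortholog pairs, paralog families of sizes (3, 2), and 2 unique
    proteins.  Qualifying e-values are drawn log-uniform in [1e-30, 1e-5],
    decoys in [1e-2, 1.0] — both sides of the 1e-3 base cutoff.
    """

    seed: int = 0
    taxonomy: tuple[int, int] = (3, 2)  # (depth below root, branching factor)
    n_genomes_per_taxon: int = 1
    genome_length: int = 2000
    gc_target: float = 0.5
    n_planted_orfs: int = 3
    orf_peptide_len_range: tuple[int, int] = (20, 60)
    n_proteins_per_taxon: int = 5
    homology: tuple[int, tuple[int, ...], int] = (3, (3, 2), 2)
    e_value_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (1e-30, 1e-5),
        (1e-2, 1.0),
    )
    clean: bool = True
    n_decoys_per_unique: int = 1
    e_cutoff: float = DEFAULT_E_CUTOFF

    def validate(self) -> None:
        depth, branching = self.taxonomy
        if depth < 1 or branching < 1:
            raise SpecError("taxonomy depth and branching must be >= 1")
        n_ortho, families, n_unique = self.homology
        if n_ortho < 0 or n_unique < 0 or any(f < 2 for f in families):
            raise SpecError("homology counts must be >= 0; family sizes >= 2")
        if branching ** depth < 3 and (n_ortho or n_unique or families):
            raise SpecError("need at least 3 leaf taxa to plant homology")
        counts = (
            self.n_genomes_per_taxon, self.genome_length, self.n_planted_orfs,
            self.n_proteins_per_taxon, self.n_decoys_per_unique,
        )
        if any(c < 0 for c in counts):
            raise SpecError("all counts must be non-negative")
        if not (0.0 <= self.gc_target <= 1.0):
            raise SpecError("gc_target must lie in [0, 1]")
        lo, hi = self.orf_peptide_len_range
        if not (1 <= lo <= hi):
            raise SpecError("orf_peptide_len_range must satisfy 1 <= min <= max")
        (qlo, qhi), (dlo, dhi) = self.e_value_ranges
        if not (0 < qlo <= qhi <= self.e_cutoff):
            raise SpecError("qualifying e-value range must sit at or below the cutoff")
        if not (self.e_cutoff < dlo <= dhi):
            raise SpecError("decoy e-value range must sit strictly above the cutoff")
        if self.n_planted_orfs:
            need = self.n_planted_orfs * (3 * (hi + 1) + 6)
            if self.genome_length < need:
                raise SpecError(
                    f"genome_length {self.genome_length} too short for "
                    f"{self.n_planted_orfs} ORFs of up to {hi} residues (need >= {need})"
                )


@dataclass
class GroundTruth:
    """Exact expected outputs recorded while generating."""

    taxon_a: int
    taxon_b: int
    taxon_paralog: int
    ortholog_pairs: list[tuple[int, int]] = field(default_factory=list)
    paralog_pairs: list[tuple[int, int]] = field(default_factory=list)
    unique_ids: list[int] = field(default_factory=list)
    planted_orfs: list[tuple[str, int, int, int]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SynthBundle:
    """In-memory form of one generated dataset."""

    nodes: list[TaxonomyNode]
    genomes: list[GenomicSequence]
    proteins: list[Protein]
    hits: list[Hit]
    truth: GroundTruth

    @property
    def tree(self) -> TaxonomyTree:
        return TaxonomyTree(self.nodes)


def _make_taxonomy(depth: int, branching: int) -> list[TaxonomyNode]:
    nodes = [TaxonomyNode(1, None, "root", "no rank")]
    level = [1]
    next_id = 2
    ranks = ["domain", "phylum", "genus", "species", "strain"]
    for d in range(depth):
        rank = ranks[min(d, len(ranks) - 1)]
        new_level = []
        for parent in level:
            for _ in range(branching):
                nodes.append(TaxonomyNode(next_id, parent, f"taxon_{next_id}", rank))
                new_level.append(next_id)
                next_id += 1
        level = new_level
    return nodes


def _log_uniform(rng: random.Random, lo: float, hi: float) -> float:
    import math

    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def _random_peptide(rng: random.Random, length: int, alphabet: str = _AA20) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _encode_orf(rng: random.Random, peptide_len: int, clean: bool) -> tuple[str, str]:
    """Return (rna_orf, peptide).  The ORF is AUG + interior codons + stop."""
    if clean:
        interior = [rng.choice(sorted(_A_FREE_CODONS.values())) for _ in range(peptide_len - 1)]
        peptide = "M" + "".join(_A_FREE_CODONS_INV[c] for c in interior)
        stop = "UAG"  # the only A is mid-codon; cannot seed a new AUG
    else:
        interior = []
        for _ in range(peptide_len - 1):
            interior.append(rng.choice(_NONSTOP_CODONS))
        from .seqops import standard_code

        code = standard_code()
        peptide = "M" + "".join(code.translate_codon(c) for c in interior)
        stop = rng.choice(_STOPS)
    return "AUG" + "".join(interior) + stop, peptide


_A_FREE_CODONS_INV = {codon: aa for aa, codon in _A_FREE_CODONS.items()}


def _background(rng: random.Random, length: int, gc: float) -> list[str]:
    out = []
    for _ in range(length):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return out


def _plant_genome(
    rng: random.Random, spec: SynthSpec, gbkid: str
) -> tuple[str, list[tuple[str, int, int, int]]]:
    """One DNA genome with n_planted_orfs non-overlapping ORFs; returns the
    sequence and (gbkid, frame, start, end) records."""
    bases = _background(rng, spec.genome_length, spec.gc_target)
    planted: list[tuple[str, int, int, int]] = []
    spans: list[tuple[int, int]] = []  # 0-based [start, end) of planted ORFs
    if spec.n_planted_orfs:
        slot = spec.genome_length // spec.n_planted_orfs
        lo, hi = spec.orf_peptide_len_range
        for k in range(spec.n_planted_orfs):
            peptide_len = rng.randint(lo, hi)
            orf_rna, _ = _encode_orf(rng, peptide_len, spec.clean)
            orf_dna = orf_rna.replace("U", "T")
            frame = rng.randint(1, 3)
            # earliest position inside the slot congruent with the frame
            pos0 = k * slot + 3  # 0-based, leave a small gap at the slot head
            pos0 += (frame - 1 - pos0) % 3
            if pos0 + len(orf_dna) > min((k + 1) * slot, spec.genome_length):
                raise SpecError("planted ORF does not fit its slot; shorten ORFs or grow genome")
            bases[pos0 : pos0 + len(orf_dna)] = list(orf_dna)
            spans.append((pos0, pos0 + len(orf_dna)))
            planted.append((gbkid, frame, pos0 + 1, pos0 + len(orf_dna)))
    seq = "".join(bases)
    if spec.clean:
        seq = _destroy_background_atg(seq, spans)
    return seq, planted


def _destroy_background_atg(seq: str, spans: list[tuple[int, int]]) -> str:
    """Mutate ATG -> AAG everywhere outside planted spans, so the planted
    starts are the only start codons in the genome (any frame).  The T->A
    flip is GC-neutral, keeping the background on its gc_target, and AAG
    cannot seed a new ATG with its neighbours."""
    starts = {s for s, _ in spans}

    def inside(i: int) -> bool:
        return any(s <= i < e for s, e in spans)

    chars = list(seq)
    i = seq.find("ATG")
    while i != -1:
        if i not in starts and not (inside(i) or inside(i + 2)):
            chars[i + 1] = "A"
        i = "".join(chars).find("ATG", i + 1)
    return "".join(chars)


def build(spec: SynthSpec) -> SynthBundle:
    """Construct the dataset in memory; fully determined by ``spec.seed``."""
    spec.validate()
    rng = random.Random(spec.seed)
    depth, branching = spec.taxonomy
    nodes = _make_taxonomy(depth, branching)
    tree = TaxonomyTree(nodes)
    leaves = tree.leaves()
    n_ortho, families, n_unique = spec.homology
    plant_homology = bool(n_ortho or n_unique or families)

    truth = GroundTruth(
        taxon_a=leaves[0] if plant_homology else 0,
        taxon_b=leaves[1] if plant_homology else 0,
        taxon_paralog=leaves[2] if plant_homology else 0,
    )

    # Genomes: one block per leaf, accession prefix cycling NC_/AC_/NG_ so
    # the prefix filter has something to reject.
    prefix_cycle = ("NC_", "AC_", "NG_")
    genomes: list[GenomicSequence] = []
    genome_no = 0
    for leaf in leaves:
        for _ in range(spec.n_genomes_per_taxon):
            prefix = prefix_cycle[genome_no % len(prefix_cycle)]
            gbkid = f"{prefix}SYN{genome_no + 1:06d}"
            seq, planted = _plant_genome(rng, spec, gbkid)
            truth.planted_orfs.extend(planted)
            bio = BioSequence(seq, Molecule.DNA, gbkid)
            genomes.append(
                GenomicSequence(
                    gbkid=gbkid,
                    taxonomy_id=leaf,
                    definition=f"synthetic genome for taxon {leaf}",
                    gc_content=seq.count("G") + seq.count("C"),
                    residues=bio,
                )
            )
            genome_no += 1

    # Proteins.  Designated taxa get exactly the proteins the homology plan
    # calls for, so the planted sets are the exact query answers; every other
    # leaf gets n_proteins_per_taxon hit-free background proteins.
    proteins: list[Protein] = []
    next_pid = 1001

    def new_protein(taxon: int, length: int) -> Protein:
        nonlocal next_pid
        p = Protein(
            protein_id=next_pid,
            taxonomy_id=taxon,
            source=ProteinSource.SYNTHETIC,
            residues=BioSequence(_random_peptide(rng, length), Molecule.PROTEIN, str(next_pid)),
        )
        next_pid += 1
        proteins.append(p)
        return p

    hits: list[Hit] = []

    def wire_hit(q: int, s: int, e_value: float) -> Hit:
        aln = rng.randint(50, 300)
        h = Hit(
            query_id=q,
            subject_id=s,
            sw_score=rng.randint(100, 2000),
            bit_score=round(rng.uniform(40.0, 900.0), 1),
            e_value=e_value,
            pct_identity=round(rng.uniform(25.0, 99.0), 2),
            aln_length=aln,
            q_start=1,
            q_end=aln,
            s_start=1,
            s_end=aln,
            q_gaps=rng.randint(0, 5),
            s_gaps=rng.randint(0, 5),
            kind=HitKind.PP,
        )
        hits.append(h)
        return h

    (qlo, qhi), (dlo, dhi) = spec.e_value_ranges

    if plant_homology:
        # Ortholog pairs across taxon_a x taxon_b.
        for _ in range(n_ortho):
            a = new_protein(truth.taxon_a, rng.randint(80, 300))
            b = new_protein(truth.taxon_b, rng.randint(80, 300))
            # orientation drawn at random; queries must normalize it away
            e = _log_uniform(rng, qlo, qhi)
            if rng.random() < 0.5:
                wire_hit(a.protein_id, b.protein_id, e)
            else:
                wire_hit(b.protein_id, a.protein_id, e)
            truth.ortholog_pairs.append((a.protein_id, b.protein_id))
        # Unique proteins in taxon_a: no qualifying cross-hit, decoys only.
        b_ids = [p.protein_id for p in proteins if p.taxonomy_id == truth.taxon_b]
        for _ in range(n_unique):
            u = new_protein(truth.taxon_a, rng.randint(80, 300))
            truth.unique_ids.append(u.protein_id)
            for _ in range(spec.n_decoys_per_unique):
                if b_ids:
                    wire_hit(u.protein_id, rng.choice(b_ids), _log_uniform(rng, dlo, dhi))
        # Paralog families: hit cliques inside taxon_paralog.
        for size in families:
            members = [new_protein(truth.taxon_paralog, rng.randint(80, 300)) for _ in range(size)]
            ids = [m.protein_id for m in members]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    e = _log_uniform(rng, qlo, qhi)
                    if rng.random() < 0.5:
                        wire_hit(ids[i], ids[j], e)
                    else:
                        wire_hit(ids[j], ids[i], e)
                    truth.paralog_pairs.append((ids[i], ids[j]))

    designated = {truth.taxon_a, truth.taxon_b, truth.taxon_paralog} if plant_homology else set()
    for leaf in leaves:
        if leaf in designated:
            continue
        for _ in range(spec.n_proteins_per_taxon):
            new_protein(leaf, rng.randint(80, 300))

    truth.ortholog_pairs.sort()
    truth.paralog_pairs.sort()
    truth.unique_ids.sort()
    truth.counts = {
        "taxonomy": len(nodes),
        "genomic_sequence": len(genomes),
        "protein": len(proteins),
        "hit_pp": len(hits),
    }
    return SynthBundle(nodes=nodes, genomes=genomes, proteins=proteins, hits=hits, truth=truth)


def generate(spec: SynthSpec, out_dir: Union[str, Path]) -> GroundTruth:
    """Generate the dataset and write it under ``out_dir``.

    Emits ``genomes.fasta``, ``proteins.fasta``, ``taxonomy.tsv``,
    ``hits_pp.tsv``, a copy of the standard genetic-code table, and
    ``manifest.txt`` (key=value lines, values JSON-encoded).  Byte-identical
    for equal seeds.
    """
    bundle = build(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bio_io.write_fasta(
        (
            bio_io.FastaRecord(
                header=f"{g.gbkid} taxonomy_id={g.taxonomy_id}",
                residues=g.residues.residues if g.residues else "",
            )
            for g in bundle.genomes
        ),
        out / "genomes.fasta",
    )
    bio_io.write_fasta(
        (
            bio_io.FastaRecord(
                header=f"{p.protein_id} taxonomy_id={p.taxonomy_id}",
                residues=p.residues.residues if p.residues else "",
            )
            for p in bundle.proteins
        ),
        out / "proteins.fasta",
    )
    bio_io.write_taxonomy(bundle.nodes, out / "taxonomy.tsv")
    bio_io.write_hits(bundle.hits, out / "hits_pp.tsv")

    from importlib import resources

    code_text = resources.files("biostr").joinpath("data/standard_code.tsv").read_text()
    (out / "standard_code.tsv").write_text(code_text, encoding="utf-8")

    truth = bundle.truth
    with open(out / "manifest.txt", "w", encoding="utf-8") as fh:
        for key, value in asdict(truth).items():
            fh.write(f"{key}={json.dumps(value, sort_keys=True)}\n")
        fh.write(f"seed={json.dumps(spec.seed)}\n")
    return truth


def read_manifest(path: Union[str, Path]) -> dict:
    """Parse a manifest back into a dict (lists of pairs become tuples)."""
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            value = json.loads(raw)
            if key in ("ortholog_pairs", "paralog_pairs", "planted_orfs"):
                value = [tuple(v) for v in value]
            out[key] = value
    return out
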