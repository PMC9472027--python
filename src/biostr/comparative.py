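"""Comparative-genomics set queries over similarity hits.

Unique genes, orthologs and paralogs are defined purely set-theoretically on
a table of pairwise protein similarity hits:

* group A = proteins whose taxonomy id falls in the subtree of taxon A;
* *similar* proteins of A w.r.t. B = members of A with at least one
  qualifying hit (e-value <= cutoff, either orientation) to a member of B;
* *unique* genes of A w.r.t. B = A minus its similar members;
* *orthologs* = the qualifying cross-group (a, b) pairs themselves;
* *paralogs* of a taxon = qualifying within-group pairs, self-hits excluded.

This is homology-by-similarity bookkeeping, not phylogenetic inference: no
reciprocal-best-hit filtering and no tree reconciliation is attempted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import UnknownProteinError
from .model import Hit, HitKind, Protein
from .taxonomy import TaxonomyTree

__all__ = [
    "DEFAULT_E_CUTOFF",
    "HomologyKind",
    "HomologyResult",
    "count_hits_protein",
    "get_protein_taxonomy",
    "get_similar_proteins",
    "get_single_genes",
    "get_orthologous_genes",
    "get_paralogous_genes",
]

# Base significance cutoff for similarity hits.
DEFAULT_E_CUTOFF = 1.0e-3


class HomologyKind(str, enum.Enum):
    UNIQUE = "unique"
    ORTHOLOG_PAIR = "ortholog_pair"
    PARALOG_PAIR = "paralog_pair"


@dataclass(frozen=True)
class HomologyResult:
    """One homology statement: a unique protein or an ortholog/paralog pair.

    For pairs, ``members`` is (a, b): ortholog pairs are ordered (group-A id,
    group-B id); paralog pairs are sorted ascending.  ``supporting_hit`` is
    one qualifying hit behind the statement, when available.
    """

    kind: HomologyKind
    members: tuple[int, ...]
    supporting_hit: Optional[Hit] = None

    def __post_init__(self):
        expected = 1 if self.kind is HomologyKind.UNIQUE else 2
        if len(self.members) != expected:
            raise ValueError(f"{self.kind.value} expects {expected} member(s)")


def _qualifying(hits: Iterable[Hit], e_cutoff: float, kinds: frozenset[HitKind]) -> Iterable[Hit]:
    return (h for h in hits if h.kind in kinds and h.e_value <= e_cutoff)


def count_hits_protein(
    proteins: Sequence[Protein],
    hits: Sequence[Hit],
    protein_id: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    kinds: Iterable[HitKind] = (HitKind.PP,),
) -> int:
    """Number of qualifying hits in which a protein occurs.

    For PP hits the protein may appear as query or subject; a self-hit
    (query == subject == protein) is one row and counts once.  For OP hits
    only the subject side is a protein, so only that side is compared.
    """
    if not any(p.protein_id == protein_id for p in proteins):
        raise UnknownProteinError(protein_id)
    kinds = frozenset(HitKind(k) for k in kinds)
    n = 0
    for h in _qualifying(hits, e_cutoff, kinds):
        if h.kind is HitKind.OP:
            if h.subject_id == protein_id:
                n += 1
        elif protein_id in (h.query_id, h.subject_id):
            n += 1
    return n


def get_protein_taxonomy(
    tree: TaxonomyTree, proteins: Sequence[Protein], tax_id: int
) -> list[int]:
    """Sorted ids of the proteins belonging to a taxonomic group."""
    group = tree.descendants(tax_id)
    return sorted(p.protein_id for p in proteins if p.taxonomy_id in group)


def _groups(
    tree: TaxonomyTree, proteins: Sequence[Protein], tax_a: int, tax_b: int
) -> tuple[set[int], set[int]]:
    """Protein-id sets of the two groups; overlap is assigned to group A."""
    group_a = set(get_protein_taxonomy(tree, proteins, tax_a))
    group_b = set(get_protein_taxonomy(tree, proteins, tax_b))
    overlap = group_a & group_b
    if overlap:
        warnings.warn(
            f"taxa {tax_a} and {tax_b} overlap on {len(overlap)} proteins; "
            "assigning them to the first group",
            stacklevel=3,
        )
        group_b -= overlap
    return group_a, group_b


def get_similar_proteins(
    tree: TaxonomyTree,
    proteins: Sequence[Protein],
    hits: Sequence[Hit],
    tax_a: int,
    tax_b: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> set[int]:
    """Group-A proteins with at least one qualifying PP hit into group B,
    checked in both hit orientations."""
    group_a, group_b = _groups(tree, proteins, tax_a, tax_b)
    similar: set[int] = set()
    for h in _qualifying(hits, e_cutoff, frozenset({HitKind.PP})):
        if h.query_id in group_a and h.subject_id in group_b:
            similar.add(h.query_id)
        if h.subject_id in group_a and h.query_id in group_b:
            similar.add(h.subject_id)
    return similar


def get_single_genes(
    tree: TaxonomyTree,
    proteins: Sequence[Protein],
    hits: Sequence[Hit],
    tax_a: int,
    tax_b: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> set[int]:
    """Unique genes of group A w.r.t. group B: the set difference between
    group A and its similar members."""
    group_a = set(get_protein_taxonomy(tree, proteins, tax_a))
    return group_a - get_similar_proteins(tree, proteins, hits, tax_a, tax_b, e_cutoff)


def get_orthologous_genes(
    tree: TaxonomyTree,
    proteins: Sequence[Protein],
    hits: Sequence[Hit],
    tax_a: int,
    tax_b: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> list[HomologyResult]:
    """All qualifying cross-group (a, b) protein pairs, orientation-normalized
    so members are (group-A id, group-B id), deduplicated and sorted."""
    group_a, group_b = _groups(tree, proteins, tax_a, tax_b)
    best: dict[tuple[int, int], Hit] = {}
    for h in _qualifying(hits, e_cutoff, frozenset({HitKind.PP})):
        if h.query_id in group_a and h.subject_id in group_b:
            pair = (h.query_id, h.subject_id)
        elif h.subject_id in group_a and h.query_id in group_b:
            pair = (h.subject_id, h.query_id)
        else:
            continue
        if pair not in best or h.e_value < best[pair].e_value:
            best[pair] = h
    return [
        HomologyResult(HomologyKind.ORTHOLOG_PAIR, pair, best[pair])
        for pair in sorted(best)
    ]


def get_paralogous_genes(
    tree: TaxonomyTree,
    proteins: Sequence[Protein],
    hits: Sequence[Hit],
    tax_id: int,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> list[HomologyResult]:
    """All qualifying within-group unordered pairs {p, q}, p != q.

    Self-hits carry no duplication signal and are excluded; each unordered
    pair is reported once with members sorted ascending.
    """
    group = set(get_protein_taxonomy(tree, proteins, tax_id))
    best: dict[tuple[int, int], Hit] = {}
    for h in _qualifying(hits, e_cutoff, frozenset({HitKind.PP})):
        if h.query_id == h.subject_id:
            continue
        if h.query_id in group and h.subject_id in group:
            pair = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
            if pair not in best or h.e_value < best[pair].e_value:
                best[pair] = h
    return [
        HomologyResult(HomologyKind.PARALOG_PAIR, pair, best[pair])
        for pair in sorted(best)
    ]
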