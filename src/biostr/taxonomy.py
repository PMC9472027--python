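"""Taxonomy tree queries: descendants, lineage, and per-taxon counts.

The taxonomic classification is a rooted tree; a *lineage* is the path from
the root to a node.  The in-memory implementations here are the reference
semantics; :mod:`biostr.store` registers recursive-SQL twins of each query
and the two are held to agree (the dual-execution contract).
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Optional, Sequence

from .errors import TreeError, UnknownTaxonError
from .model import GenomicSequence, Protein, TaxonomyNode

__all__ = [
    "TaxonomyTree",
    "DEFAULT_GENOME_PREFIXES",
    "count_genomes_by_taxon",
    "count_proteins_by_taxon",
]

# Accession prefixes of complete genomic molecules used when counting genomes.
DEFAULT_GENOME_PREFIXES = frozenset({"AC_", "NC_"})


class TaxonomyTree:
    """A validated taxonomy: exactly one root, no cycles, all nodes reachable.

    A self-parenting root (the NCBI dump convention) is normalized to a null
    parent at construction.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxonomy_id in self.nodes:
                raise TreeError(f"duplicate taxonomy_id {node.taxonomy_id}")
            if node.parent_id == node.taxonomy_id:
                node = TaxonomyNode(node.taxonomy_id, None, node.name, node.rank)
            self.nodes[node.taxonomy_id] = node
        roots = [t for t, n in self.nodes.items() if n.parent_id is None]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root: int = roots[0]
        self._children: dict[int, list[int]] = {t: [] for t in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise TreeError(
                        f"node {node.taxonomy_id} references missing parent {node.parent_id}"
                    )
                self._children[node.parent_id].append(node.taxonomy_id)
        # Reachability from the root doubles as the cycle check: a cycle
        # disconnects its members from the root, so the counts disagree.
        if len(self.descendants(self.root)) != len(self.nodes):
            raise TreeError("taxonomy is not a tree: cycle or unreachable nodes")

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, tax_id: int) -> None:
        if tax_id not in self.nodes:
            raise UnknownTaxonError(tax_id)

    def children(self, tax_id: int) -> list[int]:
        self._require(tax_id)
        return list(self._children[tax_id])

    def descendants(self, tax_id: int, include_self: bool = True) -> set[int]:
        """All taxonomy ids in the subtree rooted at ``tax_id`` (BFS)."""
        self._require(tax_id)
        seen: set[int] = {tax_id}
        queue: deque[int] = deque([tax_id])
        while queue:
            for child in self._children[queue.popleft()]:
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
        if not include_self:
            seen.discard(tax_id)
        return seen

    def lineage(self, tax_id: int) -> list[int]:
        """The root-to-node path, root first."""
        self._require(tax_id)
        path = [tax_id]
        node = self.nodes[tax_id]
        while node.parent_id is not None:
            path.append(node.parent_id)
            node = self.nodes[node.parent_id]
        path.reverse()
        return path

    def leaves(self) -> list[int]:
        return sorted(t for t, kids in self._children.items() if not kids)


def count_genomes_by_taxon(
    tree: TaxonomyTree,
    genomes: Sequence[GenomicSequence],
    tax_id: int,
    prefixes: Optional[Iterable[str]] = None,
) -> int:
    """Genomic sequences under a taxonomic group, filtered by accession prefix.

    Only accessions beginning with one of ``prefixes`` count (default AC_ and
    NC_, the complete-genomic-molecule classes); matching is case-sensitive.
    """
    if prefixes is None:
        prefixes = DEFAULT_GENOME_PREFIXES
    prefixes = tuple(prefixes)
    group = tree.descendants(tax_id)
    return sum(
        1 for g in genomes if g.taxonomy_id in group and g.gbkid.startswith(prefixes)
    )


def count_proteins_by_taxon(
    tree: TaxonomyTree, proteins: Sequence[Protein], tax_id: int
) -> int:
    """Proteins belonging to a taxonomic group, via the protein-level
    taxonomy attribute directly (no join through genomes)."""
    group = tree.descendants(tax_id)
    return sum(1 for p in proteins if p.taxonomy_id in group)
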