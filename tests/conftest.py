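"""Shared fixtures and independent oracles.

The oracles here are deliberately naive — direct tallies, brute-force triplet
scans, breadth-first traversals over a raw parent map — and never call the
implementation paths they check.
"""

from __future__ import annotations

import random

import pytest

from biostr.model import BioSequence, Molecule, TaxonomyNode
from biostr.synth import SynthSpec, build


# ---------------------------------------------------------------------------
# oracles

def gc_tally(residues: str) -> int:
    """Direct per-character count of G and C."""
    return sum(1 for ch in residues if ch in "GC")


def brute_force_orfs(rna: str, frame: int, min_peptide_len: int, codon_map: dict[str, str]):
    """Enumerate every in-frame AUG and scan forward for the first in-frame
    stop; returns (start, end, peptide) triples, 1-based closed coordinates."""
    stops = {c for c, aa in codon_map.items() if aa == "*"}
    results = []
    for i in range(frame - 1, len(rna) - 2, 3):
        if rna[i : i + 3] != "AUG":
            continue
        j = i
        while j + 3 <= len(rna):
            codon = rna[j : j + 3]
            if codon in stops:
                peptide = "".join(
                    codon_map.get(rna[k : k + 3], "X") for k in range(i, j, 3)
                )
                if len(peptide) >= min_peptide_len:
                    results.append((i + 1, j + 3, peptide))
                break
            j += 3
    results.sort()
    return results


def random_tree_nodes(rng: random.Random, n: int) -> list[TaxonomyNode]:
    """A uniformly random recursive tree: node i attaches to a parent < i."""
    nodes = [TaxonomyNode(1, None, "root", "no rank")]
    for i in range(2, n + 1):
        nodes.append(TaxonomyNode(i, rng.randint(1, i - 1), f"n{i}", ""))
    return nodes


def bfs_descendants(nodes: list[TaxonomyNode], tax_id: int) -> set[int]:
    """Breadth-first subtree walk over a raw child map built here."""
    children: dict[int, list[int]] = {}
    for node in nodes:
        if node.parent_id is not None:
            children.setdefault(node.parent_id, []).append(node.taxonomy_id)
    out = {tax_id}
    frontier = [tax_id]
    while frontier:
        nxt = []
        for t in frontier:
            for c in children.get(t, []):
                if c not in out:
                    out.add(c)
                    nxt.append(c)
        frontier = nxt
    return out


def parent_walk_lineage(nodes: list[TaxonomyNode], tax_id: int) -> list[int]:
    parents = {n.taxonomy_id: n.parent_id for n in nodes}
    path = [tax_id]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return list(reversed(path))


def random_nucleotides(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def dna(s: str, seq_id: str = "") -> BioSequence:
    return BioSequence(s, Molecule.DNA, seq_id)


def rna(s: str, seq_id: str = "") -> BioSequence:
    return BioSequence(s, Molecule.RNA, seq_id)


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def bundle41():
    """The default study conditions at seed 41: 3 ortholog pairs, paralog
    families (3, 2), 2 unique proteins."""
    return build(SynthSpec(seed=41))


@pytest.fixture()
def loaded_store(bundle41):
    from biostr.store import Store

    store = Store()
    store.create_schema()
    store.load_entities(
        list(bundle41.nodes) + list(bundle41.genomes)
        + list(bundle41.proteins) + list(bundle41.hits)
    )
    yield store
    store.close()
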