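# biostr — a bio-string abstract data type over a relational schema

`biostr` treats a biological sequence as what it is — a *bio-string*, a
character string carrying explicit molecular semantics (DNA/RNA/protein
alphabet, coordinates, taxon) — rather than an opaque blob. Around that type
it provides:

* **Sequence operations**: GC content (by the text-type replace idiom),
  transcription (T→U), reverse complement, codon-table translation, and open
  reading frame (ORF) search per reading frame with a minimum peptide length.
* **A relational schema** for the core molecular-biology entities (genomic
  sequence, gene, CDS + exons, protein, translated ORF, similarity hits,
  taxonomy, annotations), embedded in SQLite with sequences stored in plain
  `TEXT` columns.
* **Taxonomy queries**: subtree descendants (recursive common table
  expression in SQL, BFS in memory), lineages, and per-taxon genome/protein
  counts with RefSeq accession-prefix filtering (`AC_`, `NC_` by default).
* **Comparative-genomics set queries** over Smith–Waterman similarity hits
  with an e-value cutoff (default `1.0e-3`): hit counts per protein, *similar*
  proteins between two taxa, *unique genes* (group A minus its similar
  members), *ortholog pairs* (cross-taxon qualifying pairs), and *paralog
  pairs* (within-taxon qualifying pairs, self-hits excluded).
* **A synthetic-data generator** that plants ORFs at recorded coordinates and
  wires a known homology structure into a hit table, so every query has exact
  ground truth without downloading anything.

Every taxonomy/comparative query runs two ways — in memory and as SQL against
the store — and the two are held to agree (the dual-execution contract).

Who is it for: anyone teaching, prototyping, or testing comparative-genomics
bookkeeping who wants the set-theoretic definitions (unique = A ∖ similar(A,B);
orthologs = qualifying pairs across taxa; paralogs = qualifying pairs within a
taxon) implemented exactly, with oracle-checked primitives, rather than a
full phylogenetic orthology inference pipeline.

## Worked example

```bash
$ printf '>gene1\nATGAAATTTGGCTGA\n' > tiny.fasta
$ biostr gc tiny.fasta
gene1	5
$ biostr translate tiny.fasta --frame 1
gene1	MKFG
$ biostr find-orfs tiny.fasta --frame 1 --min-len 1
gene1	1	1	15	MKFG
```

`gc` counts the 5 G/C bases. `translate` reads codons from frame 1 and stops
before the TGA stop codon, giving the peptide `MKFG`. `find-orfs` reports one
ORF: frame 1, bases 1–15 (stop codon included in the span, excluded from the
peptide).

A full round trip through the relational store, on a generated dataset whose
ground truth is 3 ortholog pairs between taxa 8 and 9, paralog families of
sizes 3 and 2 in taxon 10, and 2 unique proteins in taxon 8:

```bash
$ biostr synth --out data --seed 41
taxon_a	8
taxon_b	9
taxon_paralog	10
count_genomic_sequence	8
count_hit_pp	9
count_protein	38
count_taxonomy	15
$ biostr init-db --db demo.db
$ biostr load taxonomy data/taxonomy.tsv --db demo.db
$ biostr load fasta data/genomes.fasta --db demo.db
$ biostr load fasta data/proteins.fasta --db demo.db --as proteins
$ biostr load hits data/hits_pp.tsv --db demo.db --e-max 1e-3
loaded	7
$ biostr unique-genes 8 9 --db demo.db
1007
1008
$ biostr orthologs 8 9 --db demo.db
1001	1002
1003	1004
1005	1006
$ biostr paralogs 10 --db demo.db
1009	1010
1009	1011
1010	1011
1012	1013
```

Of the 9 generated hits, 7 pass the `1e-3` load filter (the other 2 are
decoys above the cutoff, which by construction change no query answer). The
query outputs match the generator's manifest exactly: proteins 1007 and 1008
are the planted unique genes, the three ortholog pairs are recovered with
orientation normalized to (taxon-8 id, taxon-9 id), and the paralog cliques
of sizes 3 and 2 yield C(3,2) + C(2,2) = 4 pairs.

The same answers are available from Python:

```python
from biostr.synth import SynthSpec, build
from biostr.comparative import get_single_genes

b = build(SynthSpec(seed=41))
t = b.truth
print(sorted(get_single_genes(b.tree, b.proteins, b.hits, t.taxon_a, t.taxon_b)))
# [1007, 1008]
```

## Layout

| module | contents |
| --- | --- |
| `biostr.model` | validated domain types (`BioSequence`, `Gene`, `Hit`, ...) |
| `biostr.seqops` | GC, transcription, translation, ORF search, code tables |
| `biostr.taxonomy` | `TaxonomyTree`, descendants/lineage, per-taxon counts |
| `biostr.comparative` | hit counts, similar/unique proteins, orthologs, paralogs |
| `biostr.store` | SQLite schema, loaders, named-query registry |
| `biostr.io` | FASTA, 13-column hit TSV, taxonomy TSV / nodes.dmp |
| `biostr.synth` | deterministic fixture generator with ground truth |
| `biostr.cli` | the `biostr` command |

See `docs/methods.md` for the model, parameter conventions, and known
limitations.
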