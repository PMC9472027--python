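# Methods

## The bio-string model

A biological sequence taken in isolation is just characters; its meaning
comes from the molecule kind and the operations defined over it. `biostr`
makes that explicit: `BioSequence` pairs residues with a molecule enum and an
alphabet invariant (DNA never contains U, RNA never contains T, proteins are
the 20 one-letter codes plus `X` and `*`), validated at construction. IUPAC
ambiguity letters are legal in nucleotide sequences; each operation defines
its own handling rather than rejecting them.

All genomic coordinates are 1-based, fully closed intervals (the GenBank
convention). Converters to 0-based half-open intervals live in `biostr.io`.
Strand is `forward`/`reverse`, with `forward` meaning the given strand read
5′→3′.

## Sequence operations

**GC content** is implemented by the text-type idiom: delete every character
other than `G`/`C` and measure the remaining length. This is deliberately the
string-function formulation — the claim being tested is that a plain text
type plus a small domain vocabulary suffices — and the test suite holds it
equal to a direct per-character tally. Ambiguity letters (including `S`,
G-or-C) do not count toward GC; `gc_fraction` likewise excludes ambiguity
letters from its denominator and is undefined (ValueError) on sequences with
no unambiguous base.

**Transcription** uses the coding-strand convention: `T`→`U` in place, length
preserved. Template-strand transcription is obtained by composing
`reverse_complement` with `transcribe`.

**Translation** reads consecutive codons starting at offset `frame − 1`
(frames 1–3), ignoring a trailing partial codon. Any codon containing an
ambiguity letter yields `X` instead of raising, so genome-scale scans never
abort. The default stop policy truncates before the first stop codon;
`read_through` emits `*` and continues. The genetic code is a loadable
64-codon table (TSV: `codon, aa, is_start`); the packaged standard table is
NCBI translation table 1, with stops {UAA, UGA, UAG} and AUG→M.

**ORF search** returns every `AUG…stop` span in the requested frame whose
peptide (stop excluded) has at least `min_peptide_len` residues. Decisions
where the convention was genuinely open:

* DNA input is transcribed first, so a caller cannot accidentally scan the
  wrong molecule; coordinates always refer to the input sequence.
* The minimum size parameter counts peptide residues excluding the stop.
* All in-frame starts are reported, including nested starts sharing a stop;
  callers wanting one ORF per stop post-filter to the longest. This makes the
  output a well-defined set rather than a heuristic choice.
* A start with no in-frame stop before the sequence end is *not* reported: an
  ORF is bounded by its stop. The alternative (reporting open-ended spans)
  would make `nt_length ≡ 0 (mod 3)` and the peptide-length bookkeeping
  ambiguous.
* Reverse-strand ORFs are the caller's composition of `reverse_complement`
  and `search_orfs`; the search itself is single-strand, three-frame.

## Taxonomy

The taxonomy is a rooted tree; the loader normalizes the NCBI self-parenting
root to a null parent and rejects duplicate ids, multiple roots, missing
parents, and cycles (reachable-from-root count must equal node count).
`descendants` includes the queried node itself by default, because counting
genomes or proteins "belonging to a taxonomic group" includes records filed
directly under the group's own id. Genome counting filters accessions by
prefix — default {`AC_`, `NC_`}, the complete-genomic-molecule classes —
case-sensitively and configurably. Protein counting uses the taxonomy id
stored on the protein record directly: proteins are routinely sequenced
without a known source genome, so the protein table carries its own taxon
attribute rather than joining through genomes.

## Comparative queries

All homology queries operate on pairwise similarity hit records
(Smith–Waterman score, bit score, e-value, identity, alignment coordinates,
gap counts) with a significance cutoff applied as `e_value ≤ cutoff`
(default `1.0e-3`, also the default load-time filter). The `≤` convention
was chosen so the load filter and the query filter agree. Definitions:

* *group A* — proteins whose taxonomy id lies in the subtree of taxon A;
* *similar(A, B)* — members of A with ≥ 1 qualifying protein–protein hit to a
  member of B, in either hit orientation;
* *unique(A, B)* — A ∖ similar(A, B), so unique ∪ similar partitions A;
* *orthologs(A, B)* — the qualifying cross-group pairs themselves, orientation
  normalized to (A-side id, B-side id) and deduplicated; the A-side projection
  of the pair list equals similar(A, B) by construction;
* *paralogs(T)* — qualifying unordered pairs within the group of T, self-hits
  excluded (a protein aligning to itself carries no duplication signal).

If the two subtrees overlap, overlap proteins are assigned to group A and a
warning is emitted; the partition identity is preserved. ORF–protein hits
participate only in per-protein hit counting (subject side only, since the
query side of an OP hit is an ORF id); similar/unique/ortholog/paralog
queries are defined over protein–protein hits.

This is similarity bookkeeping, not evolutionary inference: no
reciprocal-best-hit filtering, no tree reconciliation, no alignment
computation (hits are inputs).

## The relational store

The embedded store is SQLite — file-based, single-writer, readers see a
consistent snapshot — with 17 tables covering genomic sequences, genes, CDS
(one row per exon in `cds_exon`, first normal form), proteins, translated
ORFs, the three hit kinds (PP/OP/OO), taxonomy, and the annotation vocabulary
(Pfam domains, enzymes with a nullable `father` self-reference, GO terms with
a `go_relationship` table keyed by a sequential `relationship_id`, because the
same term pair may be related in more than one way). Many-to-many
protein↔annotation links are intermediate tables keyed by the composition of
the two referenced keys. Sequences are plain `TEXT` columns; there is no BLOB
path. Secondary indexes are created on `hit_pp(query_id)`,
`hit_pp(subject_id)` and `hit_pp(e_value)`, the columns every similarity
query touches. The DDL is engine-light ANSI SQL (the one hard requirement is
recursive common table expressions) and can be emitted to a standalone `.sql`
file.

Every taxonomy/comparative operation is also registered as a named query
(`Store.run_query`) implemented in SQL — subtree membership via a recursive
CTE, set operations via `UNION`/`EXCEPT` — and the test suite holds the SQL
results equal to the in-memory implementations on every fixture. Loading is
idempotent under an insert-or-ignore conflict policy; hit rows get a
content-derived key so re-loading a file is a no-op. Referential integrity
(hits→proteins, genes/CDS/ORFs→genomes) is checked at load: strict mode
raises, lenient mode returns a report of per-table accepted counts and
rejected rows with reasons.

## Synthetic data: what it emulates and what it does not

The generator builds the study conditions the queries are verified under.
Defaults: a depth-3, branching-2 taxonomy (15 nodes, 8 leaves); one
2,000-base genome per leaf taxon with accession prefixes cycling
NC_/AC_/NG_ (so prefix filtering has something to reject); three planted
ORFs per genome with peptide lengths uniform in 20–60; an i.i.d. background
at GC fraction 0.5; a homology plan of 3 ortholog pairs between the first two
leaf taxa, paralog families of sizes 3 and 2 in a third leaf taxon, and 2
unique proteins, with 5 background proteins in every other leaf taxon.
Qualifying e-values are drawn log-uniform in [1e-30, 1e-5], decoy e-values in
[1e-2, 1.0] — strictly either side of the 1e-3 cutoff, so decoys provably
change no answer. Paralog families live in their own taxon so their hits
cannot perturb the unique/ortholog ground truth between the two compared
taxa. All draws come from one seeded stream in a fixed order; equal seeds
give byte-identical files.

ORF planting has two modes. In **clean** mode (default) ORF interiors are
built from adenine-free codons — no in-frame stop (all three stops contain A)
and no internal start can occur — the stop is `TAG`, and a final pass mutates
every background `ATG` to `AAG` (a GC-neutral flip that cannot create a new
start codon with its neighbours). The planted spans are then *exactly* the
ORFs present per frame, so recovery is asserted as equality. In **noisy**
mode the background is untouched i.i.d. sequence and interiors are arbitrary
non-stop codons, so extra ORFs may occur and recovery is asserted as superset
membership. Clean-mode composition is therefore mildly constrained (A-free
interiors skew ORF bases away from A/T); the GC-calibration test uses
ORF-free genomes, where the background is exactly Binomial(n, gc_target),
and checks the pooled G+C count within 3σ.

What passing these tests shows: the set logic, tree recursion, filtering,
dual execution and formats behave exactly as specified on data with known
structure. What it does not show: behaviour on real proteomes — hits here are
wired, not computed from alignments; e-values carry no relationship to
sequence content; there are no splice variants, no multi-exon translation, no
contamination or annotation noise.

## Numerical and degenerate-input conventions

* e-value comparisons are `≤`; e-values must be ≥ 0; ties at the cutoff load
  and qualify.
* `gc_fraction` on an empty (or all-ambiguous) sequence raises rather than
  returning 0/0.
* Frames are {1, 2, 3}; anything else is a `FrameError`. `min_peptide_len`
  must be ≥ 1.
* Ortholog/paralog pair lists are sorted ascending; when several hits support
  one pair, the lowest-e-value hit is attached as the supporting hit.
* Duplicate identical hit rows collapse to one stored row (content-keyed);
  distinct rows with equal statistics are kept.
* CLI exit codes: 0 success, 1 usage error, 2 data/domain error; stdout
  carries TSV data only, diagnostics go to stderr.

## Problem sizes

The shipped study conditions are desk-scale by design: genomes of a few
kilobases, tens of proteins, hit tables of tens to a thousand rows, random
trees up to 500 nodes, and oracle sweeps of 10⁴ sequences. These sizes make
every oracle comparison exact and the whole suite run in seconds while
exercising every code path; the store and queries contain nothing
size-specific beyond the indexes noted above.

## Known limitations

* No alternative genetic codes beyond file-loadable tables; `search_orfs`
  recognizes only `AUG` as a start even if the table marks alternate starts.
* No rank-aware taxonomy queries and no name/synonym resolution.
* `hit_oo` (ORF×ORF) has a schema slot but no bespoke query functions, and
  the annotation tables are created and loadable but have no query surface.
* No GenBank/GFF/EMBL parsing; FASTA, the 13-column hit TSV, taxonomy
  TSV/nodes.dmp and the code-table TSV are the supported formats.
* The store is single-writer; no server deployment or partitioning.
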