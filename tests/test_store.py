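"""Relational backend: schema shape, loaders, and the dual-execution contract."""

import random
import sqlite3

import pytest

from biostr import comparative as cmp
from biostr.errors import (
    IntegrityError,
    SchemaExistsError,
    UnknownQueryError,
    UnknownTaxonError,
)
from biostr.model import Hit, HitKind, Protein, TaxonomyNode
from biostr.store import SCHEMA, Store
from biostr.synth import SynthSpec, build
from biostr.taxonomy import TaxonomyTree, count_genomes_by_taxon, count_proteins_by_taxon
from conftest import random_tree_nodes

EXPECTED_TABLES = {
    "genomic_sequence", "gene", "cds", "cds_exon", "protein", "orft",
    "hit_pp", "hit_op", "hit_oo", "taxonomy", "domain", "enzyme", "go_term",
    "go_relationship", "domain_annotation", "enzyme_annotation", "go_annotation",
}


class TestCreateSchema:
    def test_all_17_tables_created_and_empty(self):
        with Store() as store:
            store.create_schema()
            names = {
                r[0]
                for r in store.conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            }
            assert EXPECTED_TABLES <= names
            assert len(EXPECTED_TABLES) == 17
            for t in EXPECTED_TABLES:
                assert store.table_count(t) == 0

    def test_rerun_without_overwrite_rejected(self):
        with Store() as store:
            store.create_schema()
            with pytest.raises(SchemaExistsError):
                store.create_schema()
            store.create_schema(overwrite=True)  # explicit overwrite allowed

    def test_hit_pp_secondary_indexes_present(self):
        with Store() as store:
            store.create_schema()
            idx = {
                r[0]
                for r in store.conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='index' AND tbl_name='hit_pp'"
                )
            }
            assert {"idx_hit_pp_query_id", "idx_hit_pp_subject_id", "idx_hit_pp_e_value"} <= idx

    def test_emitted_ddl_executes_on_a_fresh_engine(self, tmp_path):
        """The .sql dump must stand alone: a second, independent connection
        replays it from the file without reference to this package."""
        with Store() as store:
            ddl = store.emit_ddl(tmp_path / "schema.sql")
        fresh = sqlite3.connect(":memory:")
        fresh.executescript((tmp_path / "schema.sql").read_text())
        names = {
            r[0] for r in fresh.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        assert EXPECTED_TABLES <= names
        assert "father" in ddl and "relationship_id" in ddl  # self-FK + sequential key

    def test_many_to_many_annotation_keys_are_composite(self):
        by_name = {t.name: t for t in SCHEMA.tables}
        for name, keys in [
            ("domain_annotation", ("protein_id", "domain_id")),
            ("enzyme_annotation", ("protein_id", "enzyme_id")),
            ("go_annotation", ("protein_id", "go_id")),
        ]:
            assert by_name[name].primary_key == keys
        assert by_name["go_relationship"].primary_key == ("relationship_id",)
        enzyme_fks = dict((c, (t, r)) for c, t, r in by_name["enzyme"].foreign_keys)
        assert enzyme_fks["father"] == ("enzyme", "enzyme_id")


def _hit(q, s, e=1e-9):
    return Hit(
        query_id=q, subject_id=s, sw_score=10, bit_score=5.0, e_value=e,
        pct_identity=50.0, aln_length=10, q_start=1, q_end=10, s_start=1, s_end=10,
    )


class TestLoadEntities:
    def test_empty_iterable_all_zero_report(self):
        with Store() as store:
            store.create_schema()
            report = store.load_entities([])
            assert report.total == 0 and report.total_accepted == 0

    def test_hit_referencing_missing_protein_strict(self):
        with Store() as store:
            store.create_schema()
            with pytest.raises(IntegrityError):
                store.load_entities([_hit(1, 2)], strict=True)

    def test_hit_referencing_missing_protein_lenient_rejected_with_reason(self):
        with Store() as store:
            store.create_schema()
            report = store.load_entities([_hit(1, 2)])
            assert report.total_accepted == 0
            assert len(report.rejected) == 1 and "unknown" in report.rejected[0][1]

    def test_accepted_counts_equal_generator_counts(self):
        bundle = build(SynthSpec(seed=5))
        with Store() as store:
            store.create_schema()
            report = store.load_entities(
                list(bundle.nodes) + list(bundle.genomes)
                + list(bundle.proteins) + list(bundle.hits)
            )
            assert report.rejected == []
            for table, n in bundle.truth.counts.items():
                assert report.accepted[table] == n

    def test_idempotent_under_ignore_policy(self):
        bundle = build(SynthSpec(seed=5))
        records = list(bundle.nodes) + list(bundle.proteins) + list(bundle.hits)
        with Store() as store:
            store.create_schema()
            store.load_entities(records)
            before = {t: store.table_count(t) for t in EXPECTED_TABLES}
            store.load_entities(records)
            after = {t: store.table_count(t) for t in EXPECTED_TABLES}
            assert before == after


class TestLoadHitsFiltered:
    def test_counts_and_oracle(self, tmp_path):
        from biostr import io as bio_io

        rng = random.Random(3)
        hits = [_hit(i, i + 1, e=10 ** rng.uniform(-6, 0)) for i in range(1000)]
        path = tmp_path / "hits.tsv"
        bio_io.write_hits(hits, path)
        oracle = sum(1 for h in hits if h.e_value <= 1e-3)
        with Store() as store:
            store.create_schema()
            assert store.load_hits_filtered(path, e_max=1e-3) == oracle
        with Store() as store:
            store.create_schema()
            assert store.load_hits_filtered(path, e_max=float("inf")) == len(hits)

    def test_small_hand_count(self, tmp_path):
        from biostr import io as bio_io

        hits = [_hit(1, 2, e) for e in (1e-9, 1e-4, 1e-3, 2e-3, 0.5, 1e-8, 1e-2, 3.0, 0.7, 0.9)]
        path = tmp_path / "hits.tsv"
        bio_io.write_hits(hits, path)
        with Store() as store:
            store.create_schema()
            assert store.load_hits_filtered(path, e_max=1e-3) == 4


class TestRunQueryDualExecution:
    def test_unknown_query_rejected(self):
        with Store() as store:
            store.create_schema()
            with pytest.raises(UnknownQueryError):
                store.run_query("no_such_query")

    def test_unknown_taxon_propagates(self, loaded_store):
        with pytest.raises(UnknownTaxonError):
            loaded_store.run_query("descendants", 424242)

    def test_descendants_on_leaf(self, loaded_store, bundle41):
        leaf = bundle41.tree.leaves()[0]
        assert loaded_store.run_query("descendants", leaf) == {leaf}

    def test_store_matches_memory_on_synthetic_fixture(self, loaded_store, bundle41):
        tree, t = bundle41.tree, bundle41.truth
        proteins, genomes, hits = bundle41.proteins, bundle41.genomes, bundle41.hits
        for tax in list(tree.nodes)[:10]:
            assert loaded_store.run_query("descendants", tax) == tree.descendants(tax)
            assert loaded_store.run_query("lineage", tax) == tree.lineage(tax)
            assert loaded_store.run_query("count_genomes_by_taxon", tax) == count_genomes_by_taxon(
                tree, genomes, tax
            )
            assert loaded_store.run_query("count_proteins_by_taxon", tax) == count_proteins_by_taxon(
                tree, proteins, tax
            )
            assert loaded_store.run_query("get_protein_taxonomy", tax) == cmp.get_protein_taxonomy(
                tree, proteins, tax
            )
        for e in (1e-10, 1e-3, 1.0):
            assert loaded_store.run_query(
                "get_similar_proteins", t.taxon_a, t.taxon_b, e
            ) == cmp.get_similar_proteins(tree, proteins, hits, t.taxon_a, t.taxon_b, e)
            assert loaded_store.run_query(
                "get_single_genes", t.taxon_a, t.taxon_b, e
            ) == cmp.get_single_genes(tree, proteins, hits, t.taxon_a, t.taxon_b, e)
            assert loaded_store.run_query(
                "get_orthologous_genes", t.taxon_a, t.taxon_b, e
            ) == [r.members for r in cmp.get_orthologous_genes(tree, proteins, hits, t.taxon_a, t.taxon_b, e)]
            assert loaded_store.run_query("get_paralogous_genes", t.taxon_paralog, e) == [
                r.members for r in cmp.get_paralogous_genes(tree, proteins, hits, t.taxon_paralog, e)
            ]
        pid = proteins[0].protein_id
        assert loaded_store.run_query("count_hits_protein", pid, 1e-3) == cmp.count_hits_protein(
            proteins, hits, pid, 1e-3
        )

    def test_recursive_cte_matches_bfs_on_random_trees(self):
        rng = random.Random(11)
        for _ in range(20):
            nodes = random_tree_nodes(rng, rng.randint(2, 300))
            tree = TaxonomyTree(nodes)
            with Store() as store:
                store.create_schema()
                store.load_entities(nodes)
                probe = rng.randint(1, len(nodes))
                assert store.run_query("descendants", probe) == tree.descendants(probe)
                assert store.run_query("lineage", probe) == tree.lineage(probe)
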