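"""Dialect importers and the fixture generator."""

import csv
import random
from pathlib import Path

import pytest

from biograph import BioGraphDB, ImportAbortedError, ValidationError
from biograph.importers import (
    FIXTURE_FILES,
    IMPORTERS,
    generate_fixture,
    import_disgenet,
    import_disprot,
    import_hgnc,
    import_iedb,
    import_tantigen,
    import_worked_example,
)

from .conftest import entity_id
from .oracles import FaultyContract


def _fresh_db():
    return BioGraphDB.open(None)


def _write(path: Path, text: str) -> Path:
    path.write_text(text, encoding="utf-8")
    return path


class TestDisgenet:
    def test_row_maps_to_entities_and_scored_edge(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "d.tsv",
            "geneSymbol\tdiseaseId\tdiseaseName\tscore\n"
            "CDKN1A\tC0038356\tStomach Neoplasms\t0.9\n",
        )
        import_disgenet(path, mem_db.service)
        stats = mem_db.store.stats()
        assert stats.entities == 2
        assert stats.relations_by_label["RELATED_WITH"] == 1
        (edge,) = [r for _, r in mem_db.store.iter_edges() if r.label == "RELATED_WITH"]
        assert edge.props == {"score": 0.9}
        assert edge.source_id == entity_id("gene", "CDKN1A")
        assert edge.target_id == entity_id("disease", "C0038356")

    def test_unparsable_score_skips_row(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "d.tsv",
            "geneSymbol\tdiseaseId\tdiseaseName\tscore\n"
            "CDKN1A\tC0038356\tx\tnot-a-number\n"
            "TP53\tC0038356\tx\t0.4\n",
        )
        record = import_disgenet(path, mem_db.service)
        assert record.records_read == 2
        assert record.records_skipped == 1
        assert mem_db.store.stats().relations_by_label["RELATED_WITH"] == 1

    def test_missing_required_column_aborts(self, tmp_path, mem_db):
        path = _write(tmp_path / "d.tsv", "geneSymbol\tdiseaseName\nCDKN1A\tx\n")
        with pytest.raises(ImportAbortedError, match="score"):
            import_disgenet(path, mem_db.service)
        assert mem_db.store.stats().entities == 0
        assert mem_db.catalog.imports() == []

    def test_header_only_file_is_empty_import(self, tmp_path, mem_db):
        path = _write(tmp_path / "d.tsv", "geneSymbol\tdiseaseId\tdiseaseName\tscore\n")
        record = import_disgenet(path, mem_db.service)
        assert record.inserted == 0 and record.records_read == 0

    def test_edge_count_matches_distinct_row_oracle(self, tmp_path, mem_db):
        generate_fixture("disgenet", n_records=100, seed=1, out_path=tmp_path)
        path = tmp_path / FIXTURE_FILES["disgenet"]
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        distinct = {(r["geneSymbol"], r["diseaseId"], float(r["score"])) for r in rows}
        import_disgenet(path, mem_db.service)
        assert mem_db.store.stats().relations_by_label["RELATED_WITH"] == len(distinct)


class TestHgnc:
    def test_record_maps_gene_protein_and_location(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "h.json",
            '[{"symbol": "CDKN1A", "location": "6p21.2", "entrez_id": "1026",'
            ' "uniprot_ids": ["P38936"]}]',
        )
        import_hgnc(path, mem_db.service)
        stats = mem_db.store.stats()
        assert stats.entities == 2  # gene + protein
        assert stats.relations_by_label["FROM"] == 1
        gene = entity_id("gene", "CDKN1A")
        data = [d for _, d in mem_db.store.neighbors(gene, label="HAS_DATA", direction="out")]
        assert any(d.payload.get("location") == "6p21.2" for d in data)

    def test_record_without_protein_reference(self, tmp_path, mem_db):
        path = _write(tmp_path / "h.json", '[{"symbol": "TP53"}]')
        import_hgnc(path, mem_db.service)
        stats = mem_db.store.stats()
        assert stats.entities == 1
        assert "FROM" not in stats.relations_by_label

    def test_record_without_symbol_skipped(self, tmp_path, mem_db):
        path = _write(tmp_path / "h.json", '[{"name": "mystery"}, {"symbol": "TP53"}]')
        record = import_hgnc(path, mem_db.service)
        assert record.records_skipped == 1
        assert mem_db.store.stats().entities == 1

    def test_non_array_json_aborts(self, tmp_path, mem_db):
        path = _write(tmp_path / "h.json", '{"symbol": "TP53"}')
        with pytest.raises(ImportAbortedError):
            import_hgnc(path, mem_db.service)
        assert mem_db.store.stats().entities == 0


class TestDisprot:
    def test_record_maps_protein_with_two_identifiers(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "p.json",
            '[{"acc": "P38936", "disprot_id": "DP00016", "disorder_content": 0.9}]',
        )
        import_disprot(path, mem_db.service)
        protein = entity_id("protein", "P38936")
        identifiers = [
            i.value for _, i in mem_db.store.neighbors(protein, label="HAS_ID", direction="out")
        ]
        assert sorted(identifiers) == ["DP00016", "P38936"]
        data = [d for _, d in mem_db.store.neighbors(protein, label="HAS_DATA", direction="out")]
        assert data[0].payload["disorder_content"] == 0.9

    def test_out_of_range_disorder_warns_but_stores(self, tmp_path, mem_db, caplog):
        path = _write(tmp_path / "p.json", '[{"acc": "P1", "disorder_content": 1.5}]')
        with caplog.at_level("WARNING"):
            import_disprot(path, mem_db.service)
        assert any("outside [0, 1]" in message for message in caplog.messages)
        protein = entity_id("protein", "P1")
        data = [d for _, d in mem_db.store.neighbors(protein, label="HAS_DATA", direction="out")]
        assert data[0].payload["disorder_content"] == 1.5

    def test_taxon_creates_organism_from_edge(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "p.json",
            '[{"acc": "P1", "taxon_id": "9606", "organism": "Homo sapiens"}]',
        )
        import_disprot(path, mem_db.service)
        protein = entity_id("protein", "P1")
        from_edges = mem_db.store.neighbors(protein, label="FROM", direction="out")
        assert [o.primary_identifier for _, o in from_edges] == ["9606"]


class TestAntigenEpitope:
    def test_tantigen_maps_antigen_gene_and_epitope(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "t.json",
            '[{"agid": "Ag002102", "full_name": "x", "gene_symbol": "CDKN1A",'
            ' "epitopes": ["FAWERVRGL"]}]',
        )
        import_tantigen(path, mem_db.service)
        stats = mem_db.store.stats()
        assert stats.relations_by_label["CONTAINS"] == 1
        assert stats.relations_by_label["IS"] == 1
        (is_edge,) = [r for _, r in mem_db.store.iter_edges() if r.label == "IS"]
        assert is_edge.source_id == entity_id("gene", "CDKN1A")
        assert is_edge.target_id == entity_id("antigen", "Ag002102")

    def test_shared_epitope_one_node_two_edges(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "t.json",
            '[{"agid": "Ag1", "epitopes": ["FAWERVRGL"]},'
            ' {"agid": "Ag2", "epitopes": ["FAWERVRGL"]}]',
        )
        import_tantigen(path, mem_db.service)
        stats = mem_db.store.stats()
        assert stats.relations_by_label["CONTAINS"] == 2
        epitopes = [
            o for _, o in mem_db.store.iter_nodes("entity") if o.entity_type == "epitope"
        ]
        assert len(epitopes) == 1

    def test_iedb_maps_epitope_antigen_organism(self, tmp_path, mem_db):
        path = _write(
            tmp_path / "i.tsv",
            "epitope_seq\tepitope_type\tantigen_ref\torganism_taxon\torganism_name\n"
            "FAWERVRGL\tLinear peptide\tAg002102\t9606\tHomo sapiens\n",
        )
        import_iedb(path, mem_db.service)
        stats = mem_db.store.stats()
        assert stats.entities == 3  # epitope + antigen + organism
        assert stats.relations_by_label["CONTAINS"] == 1
        assert stats.relations_by_label["FROM"] == 1


class TestWorkedExample:
    def test_counts_and_cross_dataset_linkage(self, worked_db):
        stats = worked_db.store.stats()
        assert stats.entities == 5
        assert stats.identifiers == 6
        # the HGNC gene and the DisGeNET gene are one node
        gene = entity_id("gene", "CDKN1A")
        labels = {r.label for r, _ in worked_db.store.neighbors(gene)}
        assert {"RELATED_WITH", "IS", "FROM", "HAS_ID", "HAS_DATA"} <= labels

    def test_reimport_is_idempotent(self, worked_db, tmp_path):
        before = worked_db.store.stats()
        records = import_worked_example(worked_db.service, tmp_path / "again")
        assert all(record.inserted == 0 for record in records)
        assert worked_db.store.stats() == before


class TestFixtureGenerator:
    def test_same_seed_byte_identical(self, tmp_path):
        for dialect in ("disgenet", "hgnc", "disprot", "tantigen", "iedb"):
            generate_fixture(dialect, n_records=15, seed=9, out_path=tmp_path / "a")
            generate_fixture(dialect, n_records=15, seed=9, out_path=tmp_path / "b")
            name = FIXTURE_FILES[dialect]
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="unknown dialect"):
            generate_fixture("mobidb", 1, 0, tmp_path)

    def test_worked_example_deterministic(self, tmp_path):
        paths_a = generate_fixture("worked_example", out_path=tmp_path / "a")
        paths_b = generate_fixture("worked_example", out_path=tmp_path / "b")
        for a, b in zip(paths_a, paths_b):
            assert a.read_bytes() == b.read_bytes()

    def test_random_fixtures_importable_and_idempotent(self, tmp_path):
        db = _fresh_db()
        for dialect, importer in IMPORTERS.items():
            generate_fixture(dialect, n_records=12, seed=4, out_path=tmp_path)
            record = importer(tmp_path / FIXTURE_FILES[dialect], db.service)
            assert record.records_read == 12
            assert record.records_read == 12 - record.records_skipped + record.records_skipped
        before = db.store.stats()
        for dialect, importer in IMPORTERS.items():
            record = importer(tmp_path / FIXTURE_FILES[dialect], db.service)
            assert record.inserted == 0
        assert db.store.stats() == before
        db.close()


class TestAtomicity:
    def test_injected_failure_restores_pristine_state(self, tmp_path):
        generate_fixture("disgenet", n_records=10, seed=2, out_path=tmp_path)
        path = tmp_path / FIXTURE_FILES["disgenet"]
        rng = random.Random(13)
        for _ in range(12):
            db = _fresh_db()
            faulty = FaultyContract(db.service, fail_after=rng.randint(1, 40))
            with pytest.raises(RuntimeError, match="injected"):
                import_disgenet(path, faulty)
            stats = db.store.stats()
            assert stats.node_total == 0 and stats.relations == 0
            assert db.catalog.entry_count() == 0
            assert db.catalog.imports() == []
            assert db.catalog.posting_ids() == set()
            db.close()
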