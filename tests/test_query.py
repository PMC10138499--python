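"""Query language: parsing, matching vs brute force, decomposition, exports."""

import json
import random

import pytest

from biograph import (
    MatchResult,
    QueryParseError,
    Relation,
    decompose_paths,
    evaluate_condition,
    execute,
    export_results,
    load_query,
    load_results_json,
    make_data,
    make_entity,
    parse_query,
    save_query,
    serialize_pattern,
)
from biograph.importers import figure_query
from biograph.query import Condition
from biograph.service import BioGraphDB
from biograph.testing import random_pattern, random_store, random_tree_edges

from .conftest import entity_id
from .oracles import (
    brute_force_execute,
    match_result_keys,
    min_path_cover,
    odd_degree_count,
)


class TestParsing:
    def test_gene_protein_disorder_query(self):
        # genes and their proteins where disorder content is 0.9 or higher
        pattern = parse_query(
            {
                "match": [
                    {"from": {"p": "protein"}, "relation": "FROM", "to": {"g": "gene"}}
                ],
                "params": {
                    "p": [
                        {
                            "target": "data.disprot.disorder_content",
                            "op": "gte",
                            "value": 0.9,
                        }
                    ]
                },
            }
        )
        assert len(pattern.nodes) == 2
        assert len(pattern.edges) == 1
        assert sum(len(conds) for _, conds in pattern.conditions) == 1

    @pytest.mark.parametrize(
        "document,match",
        [
            ({"match": [], "params": {}}, "non-empty"),
            ({"match": [{"from": {"a": "gene"}, "to": "a"}], "params": {}}, "self-relation"),
            (
                {
                    "match": [{"from": {"a": "gene"}, "to": {"b": "disease"}}],
                    "params": {"z": []},
                },
                "unknown alias 'z'",
            ),
            (
                {"match": [{"from": {"a": "gene"}, "to": {"b": "disease"}}], "extra": 1},
                "unknown top-level",
            ),
            (
                {
                    "match": [
                        {"from": {"a": "gene"}, "to": {"b": "disease"}},
                        {"from": {"c": "gene"}, "to": {"d": "disease"}},
                    ]
                },
                "connected",
            ),
            (
                {
                    "match": [{"from": {"a": "gene"}, "to": {"b": "disease"}}],
                    "params": {"a": [{"target": "primary_id", "op": "like", "value": "x"}]},
                },
                "allowed ops",
            ),
            (
                {
                    "match": [{"from": {"a": "gene"}, "to": {"b": "disease"}}],
                    "params": {"a": [{"target": "primary_id", "op": "gte", "value": "x"}]},
                },
                "numeric",
            ),
            (
                {"match": [{"from": {"a": "gene"}, "to": {"a": "disease"}}]},
                "redeclared",
            ),
            (
                {"match": [{"from": "a", "to": {"b": "disease"}}]},
                "never declared",
            ),
        ],
    )
    def test_invalid_documents_rejected(self, document, match):
        with pytest.raises(QueryParseError, match=match):
            parse_query(document)

    def test_malformed_json_reports_location(self):
        with pytest.raises(QueryParseError, match="line 1"):
            parse_query('{"match": [,]}')

    def test_serialize_round_trip(self):
        pattern = parse_query(figure_query())
        assert parse_query(serialize_pattern(pattern)) == pattern


class TestConditionEvaluation:
    def test_disorder_threshold_inclusive(self, worked_db):
        protein = entity_id("protein", "P38936")
        cond = Condition("data.disprot.disorder_content", "gte", 0.9)
        assert evaluate_condition(cond, protein, worked_db.store)
        assert not evaluate_condition(
            Condition("data.disprot.disorder_content", "gt", 0.9), protein, worked_db.store
        )

    def test_score_filter_on_edge(self, worked_db):
        edge_ids = [
            eid for eid, rel in worked_db.store.iter_edges() if rel.label == "RELATED_WITH"
        ]
        assert len(edge_ids) == 1
        assert evaluate_condition(
            Condition("prop.score", "gt", 0.5), edge_ids[0], worked_db.store
        )

    def test_identifier_condition_sees_linked_values(self, worked_db):
        protein = entity_id("protein", "P38936")
        assert evaluate_condition(
            Condition("identifier", "eq", "dp00016"), protein, worked_db.store
        )
        assert not evaluate_condition(
            Condition("primary_id", "eq", "DP00016"), protein, worked_db.store
        )

    def test_missing_attribute_is_false(self, worked_db):
        gene = entity_id("gene", "CDKN1A")
        assert not evaluate_condition(
            Condition("data.disprot.disorder_content", "gte", 0.0), gene, worked_db.store
        )

    def test_ordering_against_non_numeric_is_false(self, mem_db, caplog):
        service = mem_db.service
        service.begin_import("x")
        entity = make_entity("gene", "G1")
        service.map_entity(entity)
        service.map_data(make_data("src", {"level": "high"}), entity)
        service.finish_import()
        cond = Condition("data.src.level", "gte", 1)
        with caplog.at_level("WARNING"):
            assert not evaluate_condition(cond, entity_id("gene", "G1"), mem_db.store)
        assert any("non-numeric" in message for message in caplog.messages)


class TestExecute:
    def test_worked_example_binding(self, worked_db):
        matches = execute(parse_query(figure_query()), worked_db.store)
        assert len(matches) == 1
        bound = {
            alias: worked_db.store.get(object_id)[1].primary_identifier
            for alias, object_id in matches[0].binding.items()
        }
        assert bound == {
            "gene": "CDKN1A",
            "protein": "P38936",
            "disease": "C0038356",
            "antigen": "Ag002102",
            "epitope": "FAWERVRGL",
        }

    def test_empty_store_empty_result(self, mem_db):
        assert execute(parse_query(figure_query()), mem_db.store) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(17)
        for _ in range(40):
            db = random_store(rng, max_entities=30)
            pattern = parse_query(random_pattern(rng, db))
            got = match_result_keys(execute(pattern, db.store))
            want = brute_force_execute(pattern, db.store)
            assert got == want
            db.close()

    def test_threshold_tightening_shrinks_results(self):
        rng = random.Random(23)
        db = random_store(rng, max_entities=35)
        base = {
            "match": [
                {
                    "from": {"g": "gene"},
                    "relation": "RELATED_WITH",
                    "to": {"d": "disease"},
                    "alias": "r",
                }
            ],
            "params": {"r": [{"target": "prop.score", "op": "gte", "value": 0.5}]},
        }
        loose = match_result_keys(execute(parse_query(base), db.store))
        base["params"]["r"][0]["value"] = 0.9
        tight = match_result_keys(execute(parse_query(base), db.store))
        assert tight <= loose
        db.close()

    def test_injectivity(self):
        rng = random.Random(29)
        for _ in range(10):
            db = random_store(rng, max_entities=25)
            pattern = parse_query(random_pattern(rng, db))
            for match in execute(pattern, db.store):
                assert len(set(match.binding.values())) == len(match.binding)
                assert len(set(match.edge_binding.values())) == len(match.edge_binding)
            db.close()

    def test_deterministic_order(self):
        rng = random.Random(31)
        db = random_store(rng, max_entities=30)
        pattern = parse_query(random_pattern(rng, db))
        first = [m.sort_key() for m in execute(pattern, db.store)]
        second = [m.sort_key() for m in execute(pattern, db.store)]
        assert first == second == sorted(first)
        db.close()


def _tree_match(edges):
    """A MatchResult-like object for decomposition tests, from raw edges."""
    match = MatchResult(binding={}, edge_binding={})
    for edge_id, u, v in edges:
        match.edges[edge_id] = Relation("RELATED_WITH", u, v)
    return match


class TestDecomposition:
    def test_linear_match_is_one_path(self):
        edges = [("e1" * 32, "a" * 64, "b" * 64), ("f1" * 32, "b" * 64, "c" * 64)]
        paths = decompose_paths(_tree_match(edges))
        assert len(paths) == 1
        assert len(paths[0]) == 2

    def test_worked_example_decomposes_into_two_paths(self, worked_db):
        matches = execute(parse_query(figure_query()), worked_db.store)
        paths = decompose_paths(matches[0])
        assert len(paths) == 2
        # edge-disjoint and exactly covering
        used = [edge_id for path in paths for edge_id in path.edge_ids]
        assert len(used) == len(set(used)) == len(matches[0].edges)

    def test_tree_decomposition_is_minimal(self):
        rng = random.Random(37)
        for _ in range(60):
            edges = random_tree_edges(rng, max_edges=9)
            paths = decompose_paths(_tree_match(edges))
            used = [edge_id for path in paths for edge_id in path.edge_ids]
            assert len(used) == len(set(used)) == len(edges)
            expected = max(1, odd_degree_count(edges) // 2)
            assert len(paths) == expected == min_path_cover(edges)

    def test_cycle_is_covered(self):
        a, b, c = "a" * 64, "b" * 64, "c" * 64
        edges = [("1" * 64, a, b), ("2" * 64, b, c), ("3" * 64, c, a)]
        paths = decompose_paths(_tree_match(edges))
        used = [edge_id for path in paths for edge_id in path.edge_ids]
        assert sorted(used) == sorted(e[0] for e in edges)


class TestExportAndRoundTrips:
    def test_csv_rows_per_match_path(self, worked_db, tmp_path):
        matches = execute(parse_query(figure_query()), worked_db.store)
        out = tmp_path / "results.csv"
        export_results(matches, "csv", out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("match_index,path_index")
        assert len(lines) == 3  # header + one row per path
        assert any("CDKN1A" in line for line in lines[1:])

    def test_empty_results_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        export_results([], "csv", out)
        assert out.read_text().strip() == "match_index,path_index"

    def test_json_round_trip(self, worked_db, tmp_path):
        matches = execute(parse_query(figure_query()), worked_db.store)
        out = tmp_path / "results.json"
        export_results(matches, "json", out)
        reread = load_results_json(out)
        assert reread == [(m.binding, m.edge_binding) for m in matches]

    def test_exports_are_deterministic(self, worked_db, tmp_path):
        matches = execute(parse_query(figure_query()), worked_db.store)
        for fmt in ("csv", "json"):
            a, b = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
            export_results(matches, fmt, a)
            export_results(execute(parse_query(figure_query()), worked_db.store), fmt, b)
            assert a.read_bytes() == b.read_bytes()

    def test_query_save_load_round_trip(self, tmp_path):
        pattern = parse_query(figure_query())
        path = tmp_path / "query.json"
        save_query(pattern, path)
        assert load_query(path) == pattern

    def test_hand_edited_bad_op_rejected(self, tmp_path):
        document = figure_query()
        document["params"]["gd"][0]["op"] = "approximately"
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(document))
        with pytest.raises(QueryParseError, match="allowed ops"):
            load_query(path)

    def test_random_pattern_round_trips(self, tmp_path):
        rng = random.Random(41)
        for index in range(25):
            db = random_store(rng, max_entities=20)
            pattern = parse_query(random_pattern(rng, db))
            path = tmp_path / f"q{index}.json"
            save_query(pattern, path)
            assert load_query(path) == pattern
            db.close()
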