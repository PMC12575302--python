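"""Schema validation, triple assembly, export round-trips, multi-hop queries."""

import numpy as np
import networkx as nx
import pytest

from emrkg.kg import (
    Triple,
    TripleStore,
    assemble,
    export_csv,
    export_cypher,
    import_csv,
    parse_cypher,
    validate_triple,
)
from emrkg.schema import KgSchema, SchemaError


@pytest.fixture(scope="module")
def schema():
    return KgSchema.default()


def T(s_type, s, rel, o_type, o):
    return Triple((s_type, s), rel, (o_type, o))


class TestSchema:
    def test_eleven_entity_types(self, schema):
        assert len(schema.entity_types) == 11
        assert "operation_recording" in schema.entity_types

    def test_relation_alias_normalised(self, schema):
        assert schema.relation("acompany_with").name == "accompany_with"

    def test_unknown_relation_raises(self, schema):
        with pytest.raises(SchemaError):
            schema.relation("treats")

    def test_relation_inventory_covers_audit_strata(self, schema):
        for rel in ("has_symptom", "accompany_with", "recommand_drug",
                    "recommand_eat", "rels_diseases"):
            assert rel in schema.relations


class TestValidateTriple:
    def test_disease_has_symptom_passes(self, schema):
        ok, _ = validate_triple(schema, T("diseases", "肝癌", "has_symptom", "symptom", "腹痛"))
        assert ok

    def test_reversed_direction_fails_domain(self, schema):
        ok, reason = validate_triple(
            schema, T("symptom", "腹痛", "has_symptom", "diseases", "肝癌")
        )
        assert not ok and "domain" in reason

    def test_self_typed_complication_relation_passes(self, schema):
        ok, _ = validate_triple(
            schema, T("diseases", "肝癌", "accompany_with", "diseases", "感染")
        )
        assert ok

    def test_self_loop_rejected(self, schema):
        ok, reason = validate_triple(
            schema, T("diseases", "肝癌", "accompany_with", "diseases", "肝癌")
        )
        assert not ok and "self-loop" in reason

    def test_unknown_relation_raises(self, schema):
        with pytest.raises(SchemaError):
            validate_triple(schema, T("diseases", "a", "treats", "drug", "b"))


class TestAssemble:
    def test_counting_oracle_one_patient(self, schema):
        entities = {
            "P1": [
                ("diseases", "d1"),
                ("diseases", "d2"),
                ("symptom", "s1"),
                ("symptom", "s2"),
                ("symptom", "s3"),
            ]
        }
        store = assemble(entities, schema=schema)
        assert len(store.entities) == 1 + 2 + 3
        assert len(store.triples) == 5
        assert store.relation_counts() == {"rels_disease": 2, "rels_symptom": 3}

    def test_empty_input_empty_store(self, schema):
        store = assemble({}, schema=schema)
        assert not store.entities and not store.triples

    def test_assembly_idempotent(self, schema):
        entities = {"P1": [("diseases", "d1"), ("diseases", "d1"), ("symptom", "s1")]}
        a = assemble(entities, schema=schema)
        b = assemble(entities, schema=schema)
        assert a == b
        assert len(a.triples) == 2  # duplicate collapsed

    def test_proxy_hub_mode_materialises_hubs(self, schema):
        store = assemble({"P1": [("diseases", "d1")]}, schema=schema, proxy_hubs=True)
        assert ("diseases", "P1/diseases") in store.entities
        assert len(store.triples) == 2

    def test_invalid_external_relations_collected_not_added(self, schema):
        bad = T("symptom", "s", "has_symptom", "diseases", "d")
        good = T("diseases", "d", "has_symptom", "symptom", "s")
        store = assemble({}, external_relations=[bad, good], schema=schema)
        assert good in store.triples and bad not in store.triples
        assert len(store.rejected) == 1

    def test_referential_integrity(self, schema, dicts):
        rng = np.random.default_rng(0)
        entities = {
            f"P{i}": [
                ("diseases", rng.choice(dicts["diseases"])),
                ("symptom", rng.choice(dicts["symptom"])),
            ]
            for i in range(20)
        }
        store = assemble(entities, schema=schema)
        for t in store.triples:
            assert t.subject in store.entities
            assert t.object in store.entities


@pytest.fixture(scope="module")
def toy_store(schema):
    store = TripleStore(schema=schema)
    store.add(T("patient", "P1", "rels_disease", "diseases", "肝癌"))
    store.add(T("diseases", "肝癌", "accompany_with", "diseases", "术后感染"))
    store.add(T("diseases", "肝癌", "has_symptom", "symptom", "腹痛"))
    store.add(T("diseases", "肝癌", "recommand_drug", "drug", 'a "quoted", drug'))
    store.set_attributes(("patient", "P1"), age="63", sex="F")
    return store


class TestExport:
    def test_csv_roundtrip_preserves_store(self, toy_store, tmp_path):
        export_csv(toy_store, tmp_path)
        back = import_csv(tmp_path, schema=toy_store.schema)
        assert back == toy_store
        assert back.attributes[("patient", "P1")] == {"age": "63", "sex": "F"}

    def test_relationship_csv_references_node_ids(self, schema, tmp_path):
        store = TripleStore(schema=schema)
        store.add(T("diseases", "d", "has_symptom", "symptom", "s"))
        files = export_csv(store, tmp_path)
        rel_file = [f for f in files if f.name == "relationships.csv"][0]
        lines = rel_file.read_text("utf-8").strip().splitlines()
        assert len(lines) == 2  # header + 1 triple
        assert "diseases::d" in lines[1] and "symptom::s" in lines[1]

    def test_relation_counts_conserved_through_roundtrip(self, toy_store, tmp_path):
        export_csv(toy_store, tmp_path / "g")
        back = import_csv(tmp_path / "g", schema=toy_store.schema)
        assert back.relation_counts() == toy_store.relation_counts()

    def test_cypher_roundtrip(self, toy_store, tmp_path):
        path = export_cypher(toy_store, tmp_path / "graph.cypher")
        back = parse_cypher(path, schema=toy_store.schema)
        assert back == toy_store

    def test_cypher_golden_output(self, schema, tmp_path):
        store = TripleStore(schema=schema)
        store.add(T("diseases", "d'1", "has_symptom", "symptom", "s1"))
        path = export_cypher(store, tmp_path / "toy.cypher")
        assert path.read_text("utf-8") == (
            "MERGE (:diseases {name: 'd\\'1'});\n"
            "MERGE (:symptom {name: 's1'});\n"
            "MATCH (s:diseases {name: 'd\\'1'}), (o:symptom {name: 's1'}) "
            "MERGE (s)-[:has_symptom]->(o);\n"
        )


class TestMultiHop:
    def test_patient_disease_complication_pattern(self, toy_store):
        result = toy_store.query_multihop(
            ("patient", "P1"), ["rels_disease", "accompany_with"]
        )
        assert result == [("diseases", "术后感染")]

    def test_empty_path_returns_start(self, toy_store):
        assert toy_store.query_multihop(("patient", "P1"), []) == [("patient", "P1")]

    def test_relation_absent_from_graph_empty(self, toy_store):
        assert toy_store.query_multihop(("patient", "P1"), ["do_eat"]) == []

    def test_unknown_start_entity_empty_with_warning(self, toy_store, caplog):
        with caplog.at_level("WARNING"):
            assert toy_store.query_multihop(("patient", "nobody"), ["rels_disease"]) == []
        assert "unknown start entity" in caplog.text

    def test_unregistered_relation_in_path_raises(self, toy_store):
        with pytest.raises(SchemaError):
            toy_store.query_multihop(("patient", "P1"), ["not_a_relation"])

    def test_agrees_with_networkx_oracle_on_random_graphs(self, schema):
        rng = np.random.default_rng(4)
        rels = ["rels_disease", "accompany_with", "has_symptom"]
        domains = {
            "rels_disease": ("patient", "diseases"),
            "accompany_with": ("diseases", "diseases"),
            "has_symptom": ("diseases", "symptom"),
        }
        for trial in range(10):
            store = TripleStore(schema=schema)
            g = nx.MultiDiGraph()
            for _ in range(30):
                rel = rels[rng.integers(3)]
                st_t, ot_t = domains[rel]
                s = (st_t, f"{st_t}{rng.integers(5)}")
                o = (ot_t, f"{ot_t}{rng.integers(5)}")
                if store.add(Triple(s, rel, o)):
                    g.add_edge(s, o, key=rel)
            start = ("patient", f"patient{rng.integers(5)}")
            path = ["rels_disease", "accompany_with"]
            expected = set()
            if start in g:
                frontier = {start}
                for rel in path:
                    frontier = {
                        v for u in frontier for _, v, k in g.out_edges(u, keys=True)
                        if k == rel
                    }
                expected = frontier
            got = set(store.query_multihop(start, path)) if start in store.entities else set()
            assert got == expected
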