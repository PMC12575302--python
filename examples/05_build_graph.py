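"""Assemble a patient-centric knowledge graph and query it multi-hop.

Builds a store from per-patient fused entities plus website-style reference
relations, exports bulk-import CSVs and Cypher, and retrieves a patient's
disease complications via rels_disease -> accompany_with.
"""

import tempfile
from pathlib import Path

from emrkg.kg import Triple, assemble, export_csv, export_cypher

patient_entities = {
    "PT2490513_1": [
        ("diseases", "肝癌"),
        ("symptom", "腹痛"),
        ("examination", "CT"),
        ("operation_recording", "胆囊切除术"),
    ]
}
reference_relations = [
    Triple(("diseases", "肝癌"), "accompany_with", ("diseases", "术后感染"), "website"),
    Triple(("diseases", "肝癌"), "has_symptom", ("symptom", "腹痛"), "website"),
    Triple(("diseases", "肝癌"), "recommand_drug", ("drug", "某药"), "website"),
]

store = assemble(patient_entities, reference_relations,
                 patient_attributes={"PT2490513_1": {"age": "63", "sex": "M"}})
print("entity counts:", store.entity_counts())
print("relation counts:", store.relation_counts())

complications = store.query_multihop(
    ("patient", "PT2490513_1"), ["rels_disease", "accompany_with"]
)
print("complications reachable from the patient:", complications)

out = Path(tempfile.mkdtemp())
files = export_csv(store, out / "graph")
export_cypher(store, out / "graph.cypher")
print("exported", [f.name for f in files], "and graph.cypher ->", out)
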