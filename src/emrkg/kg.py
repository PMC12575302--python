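"""Triple assembly, graph storage, export and multi-hop retrieval.

Facts are (subject, relation, object) triples whose endpoint types must
satisfy the relation's declared domain/range.  A :class:`TripleStore` keeps
the deduplicated triple set together with its typed entity inventory and
per-type/per-relation tallies, and exports to the bulk-import CSV convention
of property-graph databases (``id:ID`` / ``:LABEL`` node files,
``:START_ID`` / ``:END_ID`` / ``:TYPE`` relationship files) plus a Cypher
text file of MERGE statements — no database server is required.

Patient-centric assembly follows the record structure: each patient links to
the typed entities extracted from their note via the rels_* relations,
either directly or through per-category proxy hub nodes; reference relations
from external tables (website/terminology facts) are merged on top.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .schema import KgSchema, SchemaError

Entity = tuple[str, str]  # (entity_type, canonical name)

#: entity type -> patient-link relation
PATIENT_RELATIONS: dict[str, str] = {
    "diseases": "rels_disease",
    "symptom": "rels_symptom",
    "examination": "rels_check",
    "operation_recording": "rels_operation",
    "treatment_options": "rels_treatment",
    "physical_examination": "rels_body",
    "past_history": "rels_condition",
}


@dataclass(frozen=True)
class Triple:
    subject: Entity
    relation: str
    object: Entity
    provenance: str = ""

    def key(self) -> tuple:
        return (self.subject, self.relation, self.object)


class TripleValidationError(ValueError):
    pass


def validate_triple(
    schema: KgSchema, triple: Triple, self_loop_whitelist: frozenset[str] = frozenset()
) -> tuple[bool, str]:
    """(passes, reason).  Fails on domain/range violations or disallowed
    self-loops; an unknown relation raises :class:`SchemaError`."""
    rel = schema.relation(triple.relation)  # raises on unknown relation
    s_type, s_name = triple.subject
    o_type, o_name = triple.object
    for etype in (s_type, o_type):
        if not schema.is_entity_type(etype):
            return False, f"unregistered entity type {etype!r}"
    if rel.domain != "*" and s_type != rel.domain:
        return False, (
            f"domain violation: {rel.name} expects subject type "
            f"{rel.domain!r}, got {s_type!r}"
        )
    if rel.range != "*" and o_type != rel.range:
        return False, (
            f"range violation: {rel.name} expects object type "
            f"{rel.range!r}, got {o_type!r}"
        )
    if (
        s_type == o_type
        and s_name == o_name
        and not rel.allow_self_loop
        and rel.name not in self_loop_whitelist
    ):
        return False, f"self-loop {s_name!r} not allowed for {rel.name}"
    if not s_name or not o_name:
        return False, "empty entity name"
    return True, "ok"


@dataclass(eq=False)
class TripleStore:
    schema: KgSchema
    entities: set[Entity] = field(default_factory=set)
    triples: set[Triple] = field(default_factory=set)
    attributes: dict[Entity, dict[str, str]] = field(default_factory=dict)
    rejected: list[tuple[Triple, str]] = field(default_factory=list)

    def add(self, triple: Triple) -> bool:
        ok, reason = validate_triple(self.schema, triple)
        if not ok:
            self.rejected.append((triple, reason))
            return False
        self.entities.add(triple.subject)
        self.entities.add(triple.object)
        self.triples.add(triple)
        return True

    def add_all(self, triples: Iterable[Triple]) -> int:
        return sum(self.add(t) for t in triples)

    def set_attributes(self, entity: Entity, **attrs: str) -> None:
        self.entities.add(entity)
        self.attributes.setdefault(entity, {}).update(attrs)

    # -- statistics ----------------------------------------------------------

    def entity_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for etype, _name in self.entities:
            counts[etype] = counts.get(etype, 0) + 1
        return dict(sorted(counts.items()))

    def relation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.triples:
            counts[t.relation] = counts.get(t.relation, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripleStore):
            return NotImplemented
        return (
            self.entities == other.entities
            and {t.key() for t in self.triples} == {t.key() for t in other.triples}
        )

    # -- retrieval -----------------------------------------------------------

    def neighbors(self, entity: Entity, relation: str) -> list[Entity]:
        rel = self.schema.relation(relation)
        return sorted(
            t.object for t in self.triples
            if t.subject == entity and t.relation == rel.name
        )

    def query_multihop(
        self, start: Entity, relation_path: Sequence[str]
    ) -> list[Entity]:
        """Entities reachable by following the exact relation sequence,
        lexicographically ordered.  An empty path returns the start entity;
        an unknown start entity yields an empty set."""
        for rel in relation_path:
            self.schema.relation(rel)  # raises on unregistered relation
        if start not in self.entities:
            import logging

            logging.getLogger(__name__).warning("unknown start entity %r", start)
            return []
        frontier = {start}
        for rel in relation_path:
            frontier = {
                t.object
                for t in self.triples
                if t.relation == rel and t.subject in frontier
            }
            if not frontier:
                return []
        return sorted(frontier)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble(
    patient_entities: Mapping[str, Sequence[Entity]],
    external_relations: Iterable[Triple] = (),
    schema: KgSchema | None = None,
    patient_attributes: Mapping[str, Mapping[str, str]] | None = None,
    proxy_hubs: bool = False,
) -> TripleStore:
    """Build a store from per-patient canonicalized entities plus imported
    reference relations.  Duplicate triples collapse; validation failures are
    collected on ``store.rejected`` and the offending triples dropped.

    ``patient_entities`` maps a patient id to its typed (entity_type, name)
    mentions (already fused).  With ``proxy_hubs`` each patient links to one
    hub node per category, and the hub to the specific entities; otherwise
    patients link directly.
    """
    schema = schema or KgSchema.default()
    store = TripleStore(schema=schema)
    for pid in sorted(patient_entities):
        patient: Entity = ("patient", pid)
        store.entities.add(patient)
        if patient_attributes and pid in patient_attributes:
            store.set_attributes(patient, **dict(patient_attributes[pid]))
        for etype, name in patient_entities[pid]:
            relation = PATIENT_RELATIONS.get(etype)
            if relation is None:
                store.rejected.append(
                    (
                        Triple(patient, "rels_disease", (etype, name), pid),
                        f"no patient relation for entity type {etype!r}",
                    )
                )
                continue
            if proxy_hubs:
                hub: Entity = (etype, f"{pid}/{etype}")
                store.add(Triple(patient, relation, hub, provenance=pid))
                store.add(Triple(hub, "category_member", (etype, name), pid))
            else:
                store.add(Triple(patient, relation, (etype, name), provenance=pid))
    store.add_all(external_relations)
    return store


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def _node_id(entity: Entity) -> str:
    return f"{entity[0]}::{entity[1]}"


def export_csv(store: TripleStore, out_dir) -> list[Path]:
    """Bulk-import CSVs: one node file per entity type, one relationships
    file.  Names with quotes/commas survive standard CSV quoting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    by_type: dict[str, list[Entity]] = {}
    for ent in sorted(store.entities):
        by_type.setdefault(ent[0], []).append(ent)

    attr_keys = {
        etype: sorted(
            {
                k
                for ent in ents
                for k in store.attributes.get(ent, {})
            }
        )
        for etype, ents in by_type.items()
    }
    for etype, ents in by_type.items():
        path = out_dir / f"nodes_{etype}.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id:ID", "name", ":LABEL", *attr_keys[etype]])
            for ent in ents:
                attrs = store.attributes.get(ent, {})
                writer.writerow(
                    [
                        _node_id(ent),
                        ent[1],
                        etype,
                        *[attrs.get(k, "") for k in attr_keys[etype]],
                    ]
                )
        written.append(path)

    rel_path = out_dir / "relationships.csv"
    with open(rel_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([":START_ID", ":END_ID", ":TYPE", "provenance"])
        for t in sorted(store.triples, key=Triple.key):
            writer.writerow(
                [_node_id(t.subject), _node_id(t.object), t.relation, t.provenance]
            )
    written.append(rel_path)
    return written


def import_csv(in_dir, schema: KgSchema | None = None) -> TripleStore:
    """Rebuild a store from :func:`export_csv` output (round-trip inverse)."""
    schema = schema or KgSchema.default()
    store = TripleStore(schema=schema)
    in_dir = Path(in_dir)
    ids: dict[str, Entity] = {}
    for path in sorted(in_dir.glob("nodes_*.csv")):
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            extra = header[3:]
            for row in reader:
                ent: Entity = (row[2], row[1])
                ids[row[0]] = ent
                store.entities.add(ent)
                attrs = {k: v for k, v in zip(extra, row[3:]) if v}
                if attrs:
                    store.attributes[ent] = attrs
    with open(in_dir / "relationships.csv", "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            store.add(
                Triple(ids[row[0]], row[2], ids[row[1]], provenance=row[3])
            )
    return store


def _cypher_quote(s: str) -> str:
    return s.replace("\\", "\\\\").replace("'", "\\'")


def export_cypher(store: TripleStore, out_file) -> Path:
    """MERGE statements reproducing the same graph in a Cypher console."""
    out_file = Path(out_file)
    lines = []
    for ent in sorted(store.entities):
        attrs = store.attributes.get(ent, {})
        props = f"name: '{_cypher_quote(ent[1])}'"
        for k in sorted(attrs):
            props += f", {k}: '{_cypher_quote(attrs[k])}'"
        lines.append(f"MERGE (:{ent[0]} {{{props}}});")
    for t in sorted(store.triples, key=Triple.key):
        lines.append(
            f"MATCH (s:{t.subject[0]} {{name: '{_cypher_quote(t.subject[1])}'}}), "
            f"(o:{t.object[0]} {{name: '{_cypher_quote(t.object[1])}'}}) "
            f"MERGE (s)-[:{t.relation}]->(o);"
        )
    out_file.write_text("\n".join(lines) + "\n", "utf-8")
    return out_file


def parse_cypher(path, schema: KgSchema | None = None) -> TripleStore:
    """Parse :func:`export_cypher` output back into a store (round-trip)."""
    import re

    schema = schema or KgSchema.default()
    store = TripleStore(schema=schema)
    node_re = re.compile(r"^MERGE \(:(\w+) \{name: '((?:[^'\\]|\\.)*)'")
    rel_re = re.compile(
        r"^MATCH \(s:(\w+) \{name: '((?:[^'\\]|\\.)*)'\}\), "
        r"\(o:(\w+) \{name: '((?:[^'\\]|\\.)*)'\}\) MERGE \(s\)-\[:(\w+)\]->\(o\);$"
    )

    def unquote(s: str) -> str:
        return s.replace("\\'", "'").replace("\\\\", "\\")

    for line in Path(path).read_text("utf-8").splitlines():
        m = node_re.match(line)
        if m:
            store.entities.add((m.group(1), unquote(m.group(2))))
            continue
        m = rel_re.match(line)
        if m:
            store.add(
                Triple(
                    (m.group(1), unquote(m.group(2))),
                    m.group(5),
                    (m.group(3), unquote(m.group(4))),
                )
            )
    return store


def query_multihop(
    store: TripleStore, start_entity: Entity, relation_path: Sequence[str]
) -> list[Entity]:
    """Module-level convenience wrapper for :meth:`TripleStore.query_multihop`."""
    return store.query_multihop(start_entity, relation_path)
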