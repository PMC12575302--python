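"""Knowledge-graph conceptual layer: entity types, relations, attributes.

The conceptual layer follows the design used for liver-cancer EMR graphs:
eleven entity types (patient-centric clinical categories plus the
website-sourced food/drug/department types) and a fixed relation inventory
whose domain/range constraints are declared in an editable YAML file shipped
with the package, so corrections to the inferred pairs need no code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

#: The eleven registered entity types of the conceptual layer.
ENTITY_TYPES: tuple[str, ...] = (
    "patient",
    "examination",
    "symptom",
    "diseases",
    "past_history",
    "operation_recording",
    "treatment_options",
    "physical_examination",
    "food",
    "drug",
    "department",
)

#: Legacy spellings accepted on load and normalised to canonical names.
RELATION_ALIASES: dict[str, str] = {
    "acompany_with": "accompany_with",
}


class SchemaError(ValueError):
    """Raised when a schema file or a triple violates the conceptual layer."""


@dataclass(frozen=True)
class RelationType:
    """A directed relation with a typed domain (subject) and range (object)."""

    name: str
    domain: str  # subject entity type, or "*" for any
    range: str  # object entity type, or "*" for any
    #: self-typed relations (domain == range) normally forbid self-loops
    allow_self_loop: bool = False


@dataclass
class KgSchema:
    """Registry of entity types, relations and per-type attribute keys."""

    entity_types: tuple[str, ...] = ENTITY_TYPES
    relations: dict[str, RelationType] = field(default_factory=dict)
    attributes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rel in self.relations.values():
            if rel.domain != "*" and rel.domain not in self.entity_types:
                raise SchemaError(
                    f"relation {rel.name!r}: unknown domain type {rel.domain!r}"
                )
            if rel.range != "*" and rel.range not in self.entity_types:
                raise SchemaError(
                    f"relation {rel.name!r}: unknown range type {rel.range!r}"
                )

    def relation(self, name: str) -> RelationType:
        name = RELATION_ALIASES.get(name, name)
        try:
            return self.relations[name]
        except KeyError:
            raise SchemaError(f"unknown relation {name!r}") from None

    def is_entity_type(self, name: str) -> bool:
        return name in self.entity_types

    @classmethod
    def from_mapping(cls, spec: dict) -> "KgSchema":
        ents = tuple(spec.get("entity_types", ENTITY_TYPES))
        rels: dict[str, RelationType] = {}
        for name, dr in spec.get("relations", {}).items():
            name = RELATION_ALIASES.get(name, name)
            rels[name] = RelationType(
                name=name,
                domain=dr["domain"],
                range=dr["range"],
                allow_self_loop=bool(dr.get("allow_self_loop", False)),
            )
        attrs = {k: tuple(v) for k, v in spec.get("attributes", {}).items()}
        obj = cls(entity_types=ents, relations=rels, attributes=attrs)
        return obj

    @classmethod
    def from_yaml(cls, path) -> "KgSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "KgSchema":
        text = (
            resources.files("emrkg.data").joinpath("schema.yaml").read_text("utf-8")
        )
        return cls.from_mapping(yaml.safe_load(text))


def validate_entity_types(types: Iterable[str]) -> None:
    unknown = sorted(set(types) - set(ENTITY_TYPES))
    if unknown:
        raise SchemaError(f"unregistered entity types: {unknown}")
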