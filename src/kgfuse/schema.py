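"""Schema layer: entity types and the closed relation inventory.

A disease-centred medical knowledge graph has a fixed schema: diseases are
head entities; symptoms, examinations, surgeries, medicines, treatments and
the disease attributes (pathogeny, department, English name, alternative
name) are tails; body structures hang off symptoms.  The schema layer
constrains the data layer: every triple must instantiate one of the ten
relation signatures below, with exactly the head/tail entity types listed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class EntityType(str, enum.Enum):
    """Closed set of node types. Unknown labels are rejected at load time."""

    DISEASE = "disease"
    SYMPTOM = "symptom"
    EXAMINATION = "examination"
    SURGERY = "surgery"
    MEDICINE = "medicine"
    BODY_STRUCTURE = "body_structure"
    TREATMENT = "treatment"
    PATHOGENY = "pathogeny"
    DEPARTMENT = "department"
    ENGLISH_NAME = "english_name"
    ALTERNATIVE_NAME = "alternative_name"

    @classmethod
    def parse(cls, label: str) -> "EntityType":
        try:
            return cls(label.strip())
        except ValueError:
            raise SchemaError(f"unknown entity type {label!r}") from None


class SchemaError(ValueError):
    """A record violates the fixed schema (unknown label or type mismatch)."""


@dataclass(frozen=True)
class RelationType:
    """One of the ten allowed relation signatures.

    ``is_attribute`` marks disease attributes (label contains ``attr``);
    these are the relations whose tails are serialized as RDF literals.
    """

    label: str
    head_type: EntityType
    tail_type: EntityType

    @property
    def is_attribute(self) -> bool:
        return "_attr_" in self.label

    @property
    def is_relational(self) -> bool:
        return not self.is_attribute

    @classmethod
    def parse(cls, label: str) -> "RelationType":
        rel = RELATIONS.get(label.strip())
        if rel is None:
            raise SchemaError(f"unknown relation label {label!r}")
        return rel


def _rel(label: str, head: EntityType, tail: EntityType) -> RelationType:
    return RelationType(label, head, tail)


#: The full relation inventory, keyed by label. Head/tail types are fixed.
RELATIONS: dict[str, RelationType] = {
    r.label: r
    for r in (
        _rel("Diseases_rel_Symptom", EntityType.DISEASE, EntityType.SYMPTOM),
        _rel("Diseases_rel_Surgery", EntityType.DISEASE, EntityType.SURGERY),
        _rel("Diseases_rel_Medicines", EntityType.DISEASE, EntityType.MEDICINE),
        _rel("Diseases_rel_Examination", EntityType.DISEASE, EntityType.EXAMINATION),
        _rel("Symptoms_rel_Body structure", EntityType.SYMPTOM, EntityType.BODY_STRUCTURE),
        _rel("Diseases_rel_Treatment", EntityType.DISEASE, EntityType.TREATMENT),
        _rel("Diseases_attr_Pathogeny", EntityType.DISEASE, EntityType.PATHOGENY),
        _rel("Diseases_attr_Department", EntityType.DISEASE, EntityType.DEPARTMENT),
        _rel("Diseases_attr_English name", EntityType.DISEASE, EntityType.ENGLISH_NAME),
        _rel("Diseases_attr_Alternative name", EntityType.DISEASE, EntityType.ALTERNATIVE_NAME),
    )
}

#: Relations that carry graph structure (as opposed to disease attributes).
RELATIONAL_LABELS: tuple[str, ...] = tuple(
    r.label for r in RELATIONS.values() if r.is_relational
)
ATTRIBUTE_LABELS: tuple[str, ...] = tuple(
    r.label for r in RELATIONS.values() if r.is_attribute
)


def validate_signature(relation: RelationType, head_type: EntityType, tail_type: EntityType) -> None:
    """Raise :class:`SchemaError` unless the types match the relation signature."""
    if head_type is not relation.head_type or tail_type is not relation.tail_type:
        raise SchemaError(
            f"relation {relation.label!r} requires "
            f"({relation.head_type.value}, {relation.tail_type.value}), "
            f"got ({head_type.value}, {tail_type.value})"
        )
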