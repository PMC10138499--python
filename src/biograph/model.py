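"""Core model objects and content addressing.

The model represents biological metadata with four addressable kinds:

* :class:`EntityObject` — one biological (or contextual) thing, keyed by its
  entity type and primary identifier (e.g. ``gene`` / ``CDKN1A``).
* :class:`IdentifierObject` — a reusable identifier record (kind, title,
  value), attachable to any number of entities via ``HAS_ID`` relations.
* :class:`DataObject` — a bundle of non-identifier metadata labeled with its
  originating dataset, attached via ``HAS_DATA`` relations.
* :class:`Relation` — a labeled, directed, property-carrying edge.

Every object's unique id is derived from its content (*content addressing*):
a canonical serialization is hashed with SHA-256, so identical objects arriving
from different datasets collapse onto one graph node, and repeated imports are
deduplicated for free.

Canonical serialization (bit-exact contract, so independent implementations
agree on ids): the JSON document ``[tag, fields]`` where ``tag`` is the kind
tag (``entity`` / ``identifier`` / ``data`` / ``relation``) and ``fields`` is
the object's field mapping, serialized with lexicographically sorted keys,
compact separators (``,`` and ``:``), UTF-8 encoding, no NaN/Infinity, and
floats in shortest round-trip decimal form. The hex digest of SHA-256 over
those bytes is the :data:`ObjectID`.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from typing import Any, Mapping, Union

from .errors import ValidationError

#: Scalar payload/property value types admitted by the model.
Scalar = Union[str, int, float, bool]

#: A content-derived object id: 64 lowercase hex characters (SHA-256).
ObjectID = str

OBJECT_ID_RE = re.compile(r"^[0-9a-f]{64}$")

#: Structural relation labels wiring entities to their identifier/data objects.
HAS_ID = "HAS_ID"
HAS_DATA = "HAS_DATA"
STRUCTURAL_LABELS = frozenset({HAS_ID, HAS_DATA})

#: The six base entity-to-entity relation labels. The list is open: any other
#: label is admitted as an extension defined by higher-level schemas.
BASE_RELATION_LABELS = frozenset(
    {"IS", "IS_INSTANCE", "IS_VARIANT", "FROM", "CONTAINS", "RELATED_WITH"}
)

#: The three identifier kinds: a name, a URL, or a generic identifier.
IDENTIFIER_KINDS = ("name", "url", "id")

KIND_ENTITY = "entity"
KIND_IDENTIFIER = "identifier"
KIND_DATA = "data"
KIND_RELATION = "relation"


def normalize_relation_label(label: str) -> str:
    """Canonical spelling of a relation label: upper-case, spaces -> ``_``.

    ``"HAS ID"`` and ``"has_id"`` both normalize to ``HAS_ID`` so one canonical
    spelling participates in content addressing.
    """
    normalized = re.sub(r"\s+", "_", label.strip()).upper()
    return normalized


class RelationVocabulary:
    """The open set of entity-relation labels.

    The six base labels are immutable; any other normalized label is admitted
    and flagged as an extension (higher-level schemas may define them).
    """

    base_labels = BASE_RELATION_LABELS

    def __init__(self, extensions: tuple[str, ...] = ()) -> None:
        self._extensions: set[str] = {normalize_relation_label(x) for x in extensions}

    @property
    def extension_labels(self) -> frozenset[str]:
        return frozenset(self._extensions)

    def classify(self, label: str) -> str:
        """Return ``"structural"``, ``"base"`` or ``"extension"`` for a label,
        registering unseen labels as extensions."""
        normalized = normalize_relation_label(label)
        if not normalized:
            raise ValidationError("relation label must be non-empty")
        if normalized in STRUCTURAL_LABELS:
            return "structural"
        if normalized in self.base_labels:
            return "base"
        self._extensions.add(normalized)
        return "extension"

    def is_base(self, label: str) -> bool:
        return normalize_relation_label(label) in self.base_labels


@dataclass(frozen=True)
class EntityObject:
    """One biological entity, keyed by ``(entity_type, primary_identifier)``."""

    entity_type: str
    primary_identifier: str


@dataclass(frozen=True)
class IdentifierObject:
    """One identifier record; shareable across entities via ``HAS_ID`` edges."""

    id_type: str
    title: str
    value: str


@dataclass(frozen=True)
class DataObject:
    """Non-identifier metadata from one dataset (``source_label``)."""

    source_label: str
    payload: Mapping[str, Scalar] = field(default_factory=dict)


@dataclass(frozen=True)
class Relation:
    """A labeled directed edge with optional scalar properties."""

    label: str
    source_id: ObjectID
    target_id: ObjectID
    props: Mapping[str, Scalar] = field(default_factory=dict)


ModelObject = Union[EntityObject, IdentifierObject, DataObject, Relation]


def _require_nonempty(value: str, field_name: str) -> str:
    if not isinstance(value, str):
        raise ValidationError(f"{field_name} must be a string, got {type(value).__name__}")
    trimmed = value.strip()
    if not trimmed:
        raise ValidationError(f"{field_name} must be non-empty")
    return trimmed


def _validate_scalar(value: Any, where: str) -> Scalar:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, str)):
        return value
    if isinstance(value, float):
        if not math.isfinite(value):
            raise ValidationError(f"{where}: non-finite number {value!r} is not serializable")
        return value
    raise ValidationError(
        f"{where}: value must be a string, number, or boolean, got {type(value).__name__}"
    )


def _validate_mapping(payload: Mapping[str, Any], field_name: str, allow_empty: bool) -> dict:
    if not isinstance(payload, Mapping):
        raise ValidationError(f"{field_name} must be a mapping, got {type(payload).__name__}")
    if not payload and not allow_empty:
        raise ValidationError(f"{field_name} must be non-empty")
    out: dict[str, Scalar] = {}
    for key, value in payload.items():
        key = _require_nonempty(key, f"{field_name} key")
        if key in out:
            raise ValidationError(f"{field_name} key {key!r} repeats after trimming")
        out[key] = _validate_scalar(value, f"{field_name}[{key!r}]")
    return out


def make_entity(entity_type: str, primary_identifier: str) -> EntityObject:
    """Build a validated entity object.

    ``entity_type`` is lower-cased (dataset dialects disagree on casing) and
    both fields are whitespace-trimmed.
    """
    entity_type = _require_nonempty(entity_type, "entity_type").lower()
    primary_identifier = _require_nonempty(primary_identifier, "primary_identifier")
    return EntityObject(entity_type, primary_identifier)


def make_identifier(id_type: str, title: str, value: str) -> IdentifierObject:
    """Build a validated identifier object.

    ``id_type`` must be one of ``name`` (a human-readable name), ``url`` or
    ``id`` (a generic identifier without any more specific nature).
    """
    id_type = _require_nonempty(id_type, "id_type").lower()
    if id_type not in IDENTIFIER_KINDS:
        allowed = ", ".join(IDENTIFIER_KINDS)
        raise ValidationError(f"id_type must be one of {{{allowed}}}, got {id_type!r}")
    return IdentifierObject(
        id_type,
        _require_nonempty(title, "title"),
        _require_nonempty(value, "value"),
    )


def make_data(source_label: str, payload: Mapping[str, Scalar]) -> DataObject:
    """Build a validated data object carrying dataset-sourced metadata."""
    source_label = _require_nonempty(source_label, "source_label").lower()
    return DataObject(source_label, _validate_mapping(payload, "payload", allow_empty=False))


def make_relation(
    label: str,
    source: ObjectID,
    target: ObjectID,
    props: Mapping[str, Scalar] | None = None,
) -> Relation:
    """Build a validated relation between two stored objects.

    Endpoint *kind* rules (``HAS_ID`` entity->identifier, ``HAS_DATA``
    entity->data, entity labels entity->entity) require knowledge of the
    stored endpoints and are enforced at store time. Self-relations are
    rejected: no label in the vocabulary admits them.
    """
    normalized = normalize_relation_label(_require_nonempty(label, "label"))
    for name, endpoint in (("source", source), ("target", target)):
        if not isinstance(endpoint, str) or not OBJECT_ID_RE.match(endpoint):
            raise ValidationError(f"{name} must be a 64-char lowercase hex ObjectID")
    if source == target:
        raise ValidationError(f"self-relation with label {normalized!r} is not permitted")
    validated_props = _validate_mapping(props or {}, "props", allow_empty=True)
    return Relation(normalized, source, target, validated_props)


_TAG_AND_FIELDS = {
    EntityObject: (
        KIND_ENTITY,
        lambda o: {"entity_type": o.entity_type, "primary_identifier": o.primary_identifier},
    ),
    IdentifierObject: (
        KIND_IDENTIFIER,
        lambda o: {"id_type": o.id_type, "title": o.title, "value": o.value},
    ),
    DataObject: (
        KIND_DATA,
        lambda o: {"source_label": o.source_label, "payload": dict(o.payload)},
    ),
    Relation: (
        KIND_RELATION,
        lambda o: {
            "label": o.label,
            "source_id": o.source_id,
            "target_id": o.target_id,
            "props": dict(o.props),
        },
    ),
}


def kind_of(obj: ModelObject) -> str:
    """Kind tag (``entity``/``identifier``/``data``/``relation``) of an object."""
    try:
        return _TAG_AND_FIELDS[type(obj)][0]
    except KeyError:
        raise ValidationError(f"not a model object: {type(obj).__name__}") from None


def canonical_bytes(obj: ModelObject) -> bytes:
    """The canonical serialization hashed by :func:`content_address`.

    Exposed so the byte format is testable as an external contract.
    """
    tag, fields = _TAG_AND_FIELDS.get(type(obj), (None, None))
    if tag is None:
        raise ValidationError(f"not a model object: {type(obj).__name__}")
    try:
        doc = json.dumps(
            [tag, fields(obj)],
            sort_keys=True,
            separators=(",", ":"),
            ensure_ascii=False,
            allow_nan=False,
        )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"unserializable value in {tag} object: {exc}") from exc
    return doc.encode("utf-8")


def content_address(obj: ModelObject) -> ObjectID:
    """Deterministic content-derived id of a model object.

    Equal content (independent of mapping key order) yields equal ids; the
    kind tag participates in the hash, so an entity and a data object that
    happen to share field values never collide.
    """
    return hashlib.sha256(canonical_bytes(obj)).hexdigest()
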