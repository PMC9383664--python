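"""Minimal PROV-DM subset with canonical ordering and PROV-JSON serialization.

The model keeps exactly what the distributed backbone needs: entities,
activities and agents, six relation kinds (``used``, ``wasGeneratedBy``,
``wasInvalidatedBy``, ``wasDerivedFrom``, ``wasAttributedTo``,
``specializationOf``), flat typed attributes, and named bundles. Other
standard PROV relations are accepted on parse and carried through opaquely so
third-party documents survive a round trip.

Canonicalization imposes a total deterministic order on the statements of a
bundle (statement class, then kind, then subject, then object, then
attributes), with identifiers compared in their prefix-independent expanded
form. Equality of canonical forms is the bundle equality used everywhere
else; the canonical PROV-JSON bytes are what gets digested at finalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import BackboneTypeError, IntegrityError, ParseError
from .identifiers import (
    BACKBONE_NS,
    BACKBONE_PREFIX,
    PROV_NS,
    PROV_PREFIX,
    XSD_NS,
    XSD_PREFIX,
    QualifiedId,
)

# --------------------------------------------------------------------------
# Backbone vocabulary
# --------------------------------------------------------------------------


class BackboneType(Enum):
    """The nine backbone record types and their PROV-DM base kinds.

    Five entity types (the four connector kinds plus the external input), two
    activity types (the documented process and the receipt of an exchanged
    object) and two agent types (the responsible organizations on either side
    of an exchange).
    """

    SENDER_CONNECTOR = "senderConnector"
    RECEIVER_CONNECTOR = "receiverConnector"
    JUMP_FORWARD_CONNECTOR = "jumpForwardConnector"
    JUMP_BACKWARD_CONNECTOR = "jumpBackwardConnector"
    EXTERNAL_INPUT = "externalInput"
    MAIN_ACTIVITY = "mainActivity"
    RECEIPT_ACTIVITY = "receiptActivity"
    SENDER_AGENT = "senderAgent"
    RECEIVER_AGENT = "receiverAgent"

    @property
    def base_kind(self) -> str:
        if self in _ENTITY_TYPES:
            return "entity"
        if self in _ACTIVITY_TYPES:
            return "activity"
        return "agent"

    @property
    def is_connector(self) -> bool:
        return self in _CONNECTOR_TYPES

    @property
    def is_jump(self) -> bool:
        return self in (
            BackboneType.JUMP_FORWARD_CONNECTOR,
            BackboneType.JUMP_BACKWARD_CONNECTOR,
        )


_ENTITY_TYPES = frozenset(
    {
        BackboneType.SENDER_CONNECTOR,
        BackboneType.RECEIVER_CONNECTOR,
        BackboneType.JUMP_FORWARD_CONNECTOR,
        BackboneType.JUMP_BACKWARD_CONNECTOR,
        BackboneType.EXTERNAL_INPUT,
    }
)
_ACTIVITY_TYPES = frozenset({BackboneType.MAIN_ACTIVITY, BackboneType.RECEIPT_ACTIVITY})
_AGENT_TYPES = frozenset({BackboneType.SENDER_AGENT, BackboneType.RECEIVER_AGENT})
_CONNECTOR_TYPES = frozenset(
    {
        BackboneType.SENDER_CONNECTOR,
        BackboneType.RECEIVER_CONNECTOR,
        BackboneType.JUMP_FORWARD_CONNECTOR,
        BackboneType.JUMP_BACKWARD_CONNECTOR,
    }
)

_BACKBONE_BY_NAME = {t.value: t for t in BackboneType}

# Attribute keys used by connectors for navigation.
ATTR_DESTINATION_BUNDLE = QualifiedId(BACKBONE_PREFIX, BACKBONE_NS, "destinationBundle")
ATTR_SERVICE_URL = QualifiedId(BACKBONE_PREFIX, BACKBONE_NS, "serviceUrl")
ATTR_REFERENCED_ENTITY = QualifiedId(BACKBONE_PREFIX, BACKBONE_NS, "referencedEntity")
ATTR_DESTINATION_DIGEST = QualifiedId(BACKBONE_PREFIX, BACKBONE_NS, "destinationDigest")

PROV_TYPE = QualifiedId(PROV_PREFIX, PROV_NS, "type")

AttrValue = Union[str, int, float, bool, QualifiedId]
AttrPairs = tuple  # tuple[tuple[QualifiedId, AttrValue], ...]


def _freeze_attrs(attributes) -> AttrPairs:
    if attributes is None:
        return ()
    if isinstance(attributes, Mapping):
        items = attributes.items()
    else:
        items = attributes
    out = []
    for key, value in items:
        if not isinstance(key, QualifiedId):
            raise TypeError(f"attribute key must be a QualifiedId, got {key!r}")
        if not isinstance(value, (str, int, float, bool, QualifiedId)):
            raise TypeError(f"unsupported attribute value {value!r}")
        out.append((key, value))
    return tuple(out)


# --------------------------------------------------------------------------
# Statements
# --------------------------------------------------------------------------

RECORD_KINDS = ("entity", "activity", "agent")


@dataclass(frozen=True)
class Record:
    """An entity, activity, or agent with typed attributes.

    ``backbone_type``, when set, must map to ``kind`` per the backbone/PROV-DM
    type table. Multi-valued attributes (e.g. ``dct:hasPart``) are expressed
    as repeated key/value pairs.
    """

    kind: str
    id: QualifiedId
    attributes: AttrPairs = ()
    backbone_type: Optional[BackboneType] = None

    def __post_init__(self):
        if self.kind not in RECORD_KINDS:
            raise ValueError(f"unknown record kind {self.kind!r}")
        object.__setattr__(self, "attributes", _freeze_attrs(self.attributes))
        if self.backbone_type is not None and self.backbone_type.base_kind != self.kind:
            raise BackboneTypeError(
                f"backbone type {self.backbone_type.value} requires a "
                f"{self.backbone_type.base_kind}, not a {self.kind} ({self.id})"
            )

    def attr(self, key: QualifiedId):
        """First value for ``key``, or None."""
        for k, v in self.attributes:
            if k == key:
                return v
        return None

    def attr_values(self, key: QualifiedId) -> tuple:
        return tuple(v for k, v in self.attributes if k == key)

    def is_backbone(self) -> bool:
        return self.backbone_type is not None


class RelationKind(Enum):
    USED = "used"
    WAS_GENERATED_BY = "wasGeneratedBy"
    WAS_INVALIDATED_BY = "wasInvalidatedBy"
    WAS_DERIVED_FROM = "wasDerivedFrom"
    WAS_ATTRIBUTED_TO = "wasAttributedTo"
    SPECIALIZATION_OF = "specializationOf"


#: PROV-DM subject/object record kinds for each relation kind.
RELATION_SIGNATURES = {
    RelationKind.USED: ("activity", "entity"),
    RelationKind.WAS_GENERATED_BY: ("entity", "activity"),
    RelationKind.WAS_INVALIDATED_BY: ("entity", "activity"),
    RelationKind.WAS_DERIVED_FROM: ("entity", "entity"),
    RelationKind.WAS_ATTRIBUTED_TO: ("entity", "agent"),
    RelationKind.SPECIALIZATION_OF: ("entity", "entity"),
}

#: PROV-JSON role names (subject role, object role) per relation kind.
_RELATION_ROLES = {
    RelationKind.USED: ("prov:activity", "prov:entity"),
    RelationKind.WAS_GENERATED_BY: ("prov:entity", "prov:activity"),
    RelationKind.WAS_INVALIDATED_BY: ("prov:entity", "prov:activity"),
    RelationKind.WAS_DERIVED_FROM: ("prov:generatedEntity", "prov:usedEntity"),
    RelationKind.WAS_ATTRIBUTED_TO: ("prov:entity", "prov:agent"),
    RelationKind.SPECIALIZATION_OF: ("prov:specificEntity", "prov:generalEntity"),
}

_KIND_BY_SECTION = {k.value: k for k in RelationKind}

#: Standard PROV relation sections outside our subset: parsed and preserved
#: opaquely, never interpreted.
PASSTHROUGH_SECTIONS = frozenset(
    {
        "wasAssociatedWith",
        "actedOnBehalfOf",
        "wasInformedBy",
        "wasStartedBy",
        "wasEndedBy",
        "wasInfluencedBy",
        "alternateOf",
        "hadMember",
        "hadPrimarySource",
        "wasQuotedFrom",
    }
)


@dataclass(frozen=True)
class Relation:
    kind: RelationKind
    subject: QualifiedId
    object: QualifiedId
    attributes: AttrPairs = ()

    def __post_init__(self):
        object.__setattr__(self, "attributes", _freeze_attrs(self.attributes))


@dataclass(frozen=True)
class OpaqueStatement:
    """A preserved statement from a PROV section outside the modeled subset."""

    section: str
    statement_id: str
    payload_json: str  # canonical (sorted-keys) JSON text of the raw statement


@dataclass(frozen=True)
class RawBundle:
    """A bare bundle: just an id plus statements, no lifecycle semantics."""

    bundle_id: QualifiedId
    records: tuple
    relations: tuple
    passthrough: tuple = ()
    prefix_hints: tuple = ()


@dataclass(frozen=True)
class FinalizedBundle:
    """An immutable, canonicalized, digested provenance bundle.

    The digest is the SHA-256 of the canonical PROV-JSON bytes. Any change to
    the content must go through the versioning mechanism; a finalized bundle
    itself is never updated. ``finalized_at`` is metadata about the
    finalization event and is deliberately excluded from the digested bytes.
    """

    bundle_id: QualifiedId
    records: tuple
    relations: tuple
    digest: str
    passthrough: tuple = ()
    finalized_at: Optional[str] = None
    prefix_hints: tuple = ()

    # -- convenience accessors used throughout validation and traversal ----

    def record(self, rid: QualifiedId) -> Optional[Record]:
        return records_by_id(self.records).get(rid)

    def backbone_records(self, *types: BackboneType) -> tuple:
        wanted = set(types) if types else None
        return tuple(
            r
            for r in self.records
            if r.backbone_type is not None
            and (wanted is None or r.backbone_type in wanted)
        )


BundleLike = Union[RawBundle, FinalizedBundle]


def records_by_id(records: Iterable[Record]) -> dict:
    return {r.id: r for r in records}


# --------------------------------------------------------------------------
# Integrity and canonical ordering
# --------------------------------------------------------------------------


def check_integrity(records: Sequence[Record], relations: Sequence[Relation]) -> None:
    """Verify declarations are unique and every relation endpoint resolves.

    Raises :class:`IntegrityError` naming the first missing or conflicting
    identifier. Relation endpoints must also carry the PROV-DM record kinds
    required by the relation (e.g. ``used`` links an activity to an entity).
    """
    by_id: dict = {}
    for rec in records:
        prev = by_id.get(rec.id)
        if prev is not None and prev.kind == rec.kind:
            raise IntegrityError(
                f"duplicate declaration of {rec.kind} {rec.id}", rec.id
            )
        if prev is not None:
            raise IntegrityError(
                f"{rec.id} declared both as {prev.kind} and {rec.kind}", rec.id
            )
        by_id[rec.id] = rec
    for rel in relations:
        want_subj, want_obj = RELATION_SIGNATURES[rel.kind]
        for endpoint, want in ((rel.subject, want_subj), (rel.object, want_obj)):
            rec = by_id.get(endpoint)
            if rec is None:
                raise IntegrityError(
                    f"{rel.kind.value} references undeclared id {endpoint}", endpoint
                )
            if rec.kind != want:
                raise IntegrityError(
                    f"{rel.kind.value} requires a {want} at this position, "
                    f"{endpoint} is a {rec.kind}",
                    endpoint,
                )


def _value_tag(value: AttrValue) -> tuple:
    if isinstance(value, QualifiedId):
        return ("qid", value.namespace_uri, value.local_name)
    if isinstance(value, bool):  # bool before int: bool is an int subtype
        return ("bool", "true" if value else "false")
    if isinstance(value, int):
        return ("int", str(value))
    if isinstance(value, float):
        return ("float", repr(value))
    return ("str", value)


def _attrs_tag(attributes: AttrPairs) -> tuple:
    return tuple(sorted((k.key, _value_tag(v)) for k, v in attributes))


_KIND_ORDER = {"entity": 0, "activity": 1, "agent": 2}


def canonicalize(
    records: Iterable[Record], relations: Iterable[Relation], passthrough=()
) -> tuple:
    """Total deterministic ordering of a bundle's statements.

    Statements are keyed by class (records, then relations, then opaque
    pass-through), then kind, then subject id, then object id, then sorted
    attributes; identifiers compare in expanded (prefix-free) form. The
    result is idempotent under re-canonicalization and independent of
    insertion order; equality of two bundles' canonical forms is the bundle
    equality used by finalization and the chain store.
    """
    records = tuple(records)
    relations = tuple(relations)
    check_integrity(records, relations)
    stmts = []
    for rec in records:
        stmts.append(
            (
                0,
                _KIND_ORDER[rec.kind],
                rec.kind,
                rec.id.key,
                ("", ""),
                rec.backbone_type.value if rec.backbone_type else "",
                _attrs_tag(rec.attributes),
            )
        )
    for rel in relations:
        stmts.append(
            (
                1,
                0,
                rel.kind.value,
                rel.subject.key,
                rel.object.key,
                "",
                _attrs_tag(rel.attributes),
            )
        )
    for op in passthrough:
        stmts.append((2, 0, op.section, (op.statement_id, ""), ("", ""), "", op.payload_json))
    return tuple(sorted(stmts))


def canonical_statements(bundle: BundleLike) -> tuple:
    return canonicalize(bundle.records, bundle.relations, bundle.passthrough)


def canonical_equal(a: BundleLike, b: BundleLike) -> bool:
    return (
        a.bundle_id == b.bundle_id
        and canonical_statements(a) == canonical_statements(b)
    )


# --------------------------------------------------------------------------
# PROV-JSON serialization
# --------------------------------------------------------------------------


def _collect_prefixes(bundle: BundleLike) -> dict:
    """Deterministic URI→prefix assignment from the identifiers in use."""
    observed: dict = {}  # uri -> set of prefixes seen

    def see(qid: QualifiedId):
        observed.setdefault(qid.namespace_uri, set()).add(qid.prefix)

    see(bundle.bundle_id)
    for rec in bundle.records:
        see(rec.id)
        if rec.backbone_type is not None:
            see(PROV_TYPE)
            observed.setdefault(BACKBONE_NS, set()).add(BACKBONE_PREFIX)
        for k, v in rec.attributes:
            see(k)
            if isinstance(v, QualifiedId):
                see(v)
    for rel in bundle.relations:
        see(rel.subject)
        see(rel.object)
        for k, v in rel.attributes:
            see(k)
            if isinstance(v, QualifiedId):
                see(v)
    for prefix, uri in getattr(bundle, "prefix_hints", ()):
        observed.setdefault(uri, set()).add(prefix)

    assignment: dict = {}
    taken: set = set()
    for uri in sorted(observed):
        want = min(observed[uri])
        candidate, n = want, 1
        while candidate in taken:
            n += 1
            candidate = f"{want}{n}"
        assignment[uri] = candidate
        taken.add(candidate)
    return assignment


def _qname(qid: QualifiedId, prefixes: dict) -> str:
    return f"{prefixes[qid.namespace_uri]}:{qid.local_name}"


def _encode_value(value: AttrValue, prefixes: dict):
    if isinstance(value, QualifiedId):
        return {"$": _qname(value, prefixes), "type": "prov:QUALIFIED_NAME"}
    if isinstance(value, bool):
        return {"$": value, "type": f"{XSD_PREFIX}:boolean"}
    if isinstance(value, int):
        return {"$": value, "type": f"{XSD_PREFIX}:int"}
    if isinstance(value, float):
        return {"$": value, "type": f"{XSD_PREFIX}:double"}
    return value  # plain string


def _encode_attrs(record: Record, prefixes: dict) -> dict:
    grouped: dict = {}
    if record.backbone_type is not None:
        grouped.setdefault("prov:type", []).append(
            {"$": f"{prefixes[BACKBONE_NS]}:{record.backbone_type.value}",
             "type": "prov:QUALIFIED_NAME"}
        )
    for k, v in record.attributes:
        grouped.setdefault(_qname(k, prefixes), []).append(_encode_value(v, prefixes))
    return {k: (vs[0] if len(vs) == 1 else vs) for k, vs in grouped.items()}


def serialize_bundle(bundle: BundleLike) -> bytes:
    """Emit the bundle as deterministic UTF-8 PROV-JSON bytes.

    For a canonicalized bundle the bytes are a pure function of the content,
    which is what makes them digestible: serializing twice, or serializing a
    parse of the output, yields identical bytes. Sections for all six
    relation kinds are always present (possibly empty).
    """
    stmts = canonical_statements(bundle)  # also enforces integrity
    del stmts
    prefixes = _collect_prefixes(bundle)

    sections: dict = {k: {} for k in RECORD_KINDS}
    for kind in RelationKind:
        sections[kind.value] = {}

    for rec in sorted(bundle.records, key=lambda r: (_KIND_ORDER[r.kind], r.id.key)):
        sections[rec.kind][_qname(rec.id, prefixes)] = _encode_attrs(rec, prefixes)

    counters: dict = {}
    for rel in sorted(
        bundle.relations,
        key=lambda r: (r.kind.value, r.subject.key, r.object.key, _attrs_tag(r.attributes)),
    ):
        n = counters.get(rel.kind, 0) + 1
        counters[rel.kind] = n
        subj_role, obj_role = _RELATION_ROLES[rel.kind]
        stmt = {
            subj_role: _qname(rel.subject, prefixes),
            obj_role: _qname(rel.object, prefixes),
        }
        extra: dict = {}
        for k, v in rel.attributes:
            extra.setdefault(_qname(k, prefixes), []).append(_encode_value(v, prefixes))
        stmt.update({k: (vs[0] if len(vs) == 1 else vs) for k, vs in extra.items()})
        sections[rel.kind.value][f"_:{rel.kind.value}{n}"] = stmt

    for op in sorted(bundle.passthrough, key=lambda o: (o.section, o.statement_id)):
        sections.setdefault(op.section, {})[op.statement_id] = json.loads(op.payload_json)

    doc = {
        "prefix": {p: uri for uri, p in prefixes.items()},
        "bundle": {_qname(bundle.bundle_id, prefixes): sections},
    }
    return json.dumps(
        doc, sort_keys=True, ensure_ascii=False, separators=(",", ":")
    ).encode("utf-8")


# --------------------------------------------------------------------------
# PROV-JSON parsing
# --------------------------------------------------------------------------


def _parse_qname(text: str, prefixes: dict, location: str) -> QualifiedId:
    if ":" not in text:
        raise ParseError(f"not a qualified name: {text!r}", location)
    prefix, local = text.split(":", 1)
    uri = prefixes.get(prefix)
    if uri is None:
        raise ParseError(f"undeclared prefix {prefix!r}", location)
    if not local:
        raise ParseError(f"empty local name in {text!r}", location)
    return QualifiedId(prefix, uri, local)


def _parse_value(raw, prefixes: dict, location: str):
    if isinstance(raw, str):
        return raw
    if isinstance(raw, bool):
        return raw
    if isinstance(raw, (int, float)):
        return raw
    if isinstance(raw, dict) and "$" in raw:
        vtype = raw.get("type", "")
        dollar = raw["$"]
        if vtype == "prov:QUALIFIED_NAME":
            return _parse_qname(dollar, prefixes, location)
        if vtype.endswith(":int") or vtype.endswith(":integer") or vtype.endswith(":long"):
            return int(dollar)
        if vtype.endswith(":double") or vtype.endswith(":float") or vtype.endswith(":decimal"):
            return float(dollar)
        if vtype.endswith(":boolean"):
            return dollar if isinstance(dollar, bool) else dollar == "true"
        if isinstance(dollar, (str, int, float, bool)):
            return dollar
    raise ParseError(f"unsupported attribute value {raw!r}", location)


def _iter_raw_values(raw):
    return raw if isinstance(raw, list) else [raw]


def _parse_record(kind: str, qname: str, body, prefixes: dict) -> Record:
    location = f"{kind}/{qname}"
    rid = _parse_qname(qname, prefixes, location)
    if body is None:
        body = {}
    if not isinstance(body, dict):
        raise ParseError("record body must be an object", location)
    backbone_type = None
    attrs = []
    for key, raw in sorted(body.items()):
        for raw_value in _iter_raw_values(raw):
            value = _parse_value(raw_value, prefixes, location)
            if key == "prov:type" and isinstance(value, QualifiedId) and (
                value.namespace_uri == BACKBONE_NS
                and value.local_name in _BACKBONE_BY_NAME
            ):
                found = _BACKBONE_BY_NAME[value.local_name]
                if backbone_type is not None and backbone_type is not found:
                    raise ParseError("record carries two backbone types", location)
                backbone_type = found
                continue
            attrs.append((_parse_qname(key, prefixes, location), value))
    return Record(kind=kind, id=rid, attributes=tuple(attrs), backbone_type=backbone_type)


def _parse_relation(kind: RelationKind, stmt_id: str, body, prefixes: dict) -> Relation:
    location = f"{kind.value}/{stmt_id}"
    if not isinstance(body, dict):
        raise ParseError("relation body must be an object", location)
    subj_role, obj_role = _RELATION_ROLES[kind]
    if subj_role not in body or obj_role not in body:
        raise ParseError(
            f"relation needs {subj_role} and {obj_role}", location
        )
    subject = _parse_qname(body[subj_role], prefixes, location)
    obj = _parse_qname(body[obj_role], prefixes, location)
    attrs = []
    for key, raw in sorted(body.items()):
        if key in (subj_role, obj_role):
            continue
        for raw_value in _iter_raw_values(raw):
            attrs.append(
                (_parse_qname(key, prefixes, location),
                 _parse_value(raw_value, prefixes, location))
            )
    return Relation(kind=kind, subject=subject, object=obj, attributes=tuple(attrs))


def deserialize_bundle(data: bytes) -> FinalizedBundle:
    """Parse PROV-JSON bytes holding exactly one named bundle.

    Round-trip law: ``deserialize_bundle(serialize_bundle(b))`` is
    canonical-equal to ``b`` and carries the same digest. Unknown relation
    sections raise :class:`ParseError` unless they are standard PROV
    relations, which are preserved opaquely.
    """
    from .finalization import compute_digest  # local import to avoid a cycle

    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        doc = json.loads(data.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ParseError(f"not valid JSON: {exc}", "document") from None
    if not isinstance(doc, dict):
        raise ParseError("document root must be an object", "document")

    doc_prefixes = dict(doc.get("prefix", {}))
    doc_prefixes.setdefault(PROV_PREFIX, PROV_NS)
    doc_prefixes.setdefault(XSD_PREFIX, XSD_NS)

    bundles = doc.get("bundle")
    if not isinstance(bundles, dict) or len(bundles) != 1:
        raise ParseError(
            "document must contain exactly one named bundle", "bundle"
        )
    (bundle_qname, body), = bundles.items()
    prefixes = dict(doc_prefixes)
    prefixes.update(body.get("prefix", {}))
    bundle_id = _parse_qname(bundle_qname, prefixes, "bundle")

    records, relations, passthrough = [], [], []
    for section, content in sorted(body.items()):
        if section == "prefix":
            continue
        if section in RECORD_KINDS:
            for qname, rec_body in sorted(content.items()):
                records.append(_parse_record(section, qname, rec_body, prefixes))
        elif section in _KIND_BY_SECTION:
            for stmt_id, rel_body in sorted(content.items()):
                relations.append(
                    _parse_relation(_KIND_BY_SECTION[section], stmt_id, rel_body, prefixes)
                )
        elif section in PASSTHROUGH_SECTIONS:
            for stmt_id, raw in sorted(content.items()):
                passthrough.append(
                    OpaqueStatement(
                        section=section,
                        statement_id=stmt_id,
                        payload_json=json.dumps(raw, sort_keys=True, ensure_ascii=False),
                    )
                )
        else:
            raise ParseError(f"unknown section {section!r}", section)

    # Prefix bindings are reconstructed from the parsed identifiers on
    # re-serialization; hints are kept only for prefixes that appear inside
    # opaque pass-through payloads, so round-tripping our own output stays
    # byte-identical.
    hint_items = tuple(
        sorted(
            (p, u)
            for p, u in prefixes.items()
            if any(f"{p}:" in op.payload_json for op in passthrough)
        )
    )
    raw = RawBundle(
        bundle_id=bundle_id,
        records=tuple(records),
        relations=tuple(relations),
        passthrough=tuple(passthrough),
        prefix_hints=hint_items,
    )
    try:
        canonical_statements(raw)
    except IntegrityError:
        raise
    digest = compute_digest(serialize_bundle(raw))
    return FinalizedBundle(
        bundle_id=bundle_id,
        records=raw.records,
        relations=raw.relations,
        digest=digest,
        passthrough=raw.passthrough,
        prefix_hints=hint_items,
    )
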