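"""Backbone bundle construction.

A :class:`BundleBuilder` assembles one organization's provenance bundle for
one documented process. The builder's operations emit exactly the backbone
structure the chain traversal relies on:

* ``record_receipt`` — an object arrives from another organization: a
  *receiverConnector* (the object as sent, under the sender's shared
  identifier), an *externalInput* (the object as received, under a fresh
  local identifier) and a *receiptActivity* mediating the two, wired with
  five relations (use, generation, invalidation, derivation, attribution).
* ``record_output`` — an object leaves this organization: a
  *senderConnector* under this organization's namespace, generated by the
  single *mainActivity*.
* ``link_derivation`` — declares that a particular output was affected by a
  particular input: ``senderConnector wasDerivedFrom externalInput``. These
  length-2 derivation paths (output → input → origin connector) are the
  whole substrate of chain traversal.
* ``add_jump_backward`` / ``add_jump_forward`` — navigation bridges across
  non-adjacent steps, tolerant to missing intermediate bundles. Jump
  connectors exist solely for navigation, so all three destination
  attributes are mandatory.

Every bundle has exactly one mainActivity, created up front. Builders become
permanently frozen at finalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import (
    BackboneTypeError,
    DuplicateConnectorError,
    IdentifierError,
    ImmutabilityError,
    IntegrityError,
)
from .identifiers import CONNECTOR_SEGMENT, QualifiedId, make_qualified_id
from .model import (
    ATTR_DESTINATION_BUNDLE,
    ATTR_DESTINATION_DIGEST,
    ATTR_REFERENCED_ENTITY,
    ATTR_SERVICE_URL,
    BackboneType,
    RawBundle,
    Record,
    Relation,
    RelationKind,
)


@dataclass(frozen=True)
class ConnectorRecord:
    """Read-only view of a connector entity's navigation payload."""

    id: QualifiedId
    connector_kind: BackboneType
    destination_bundle_id: Optional[QualifiedId] = None
    service_url: Optional[str] = None
    referenced_entity_id: Optional[QualifiedId] = None
    destination_bundle_digest: Optional[str] = None

    @property
    def has_destination(self) -> bool:
        return self.destination_bundle_id is not None and self.service_url is not None


def connector_view(record: Record) -> ConnectorRecord:
    """Extract the navigation attributes of a connector-typed record."""
    if record.backbone_type is None or not record.backbone_type.is_connector:
        raise BackboneTypeError(f"{record.id} is not a connector")
    return ConnectorRecord(
        id=record.id,
        connector_kind=record.backbone_type,
        destination_bundle_id=record.attr(ATTR_DESTINATION_BUNDLE),
        service_url=record.attr(ATTR_SERVICE_URL),
        referenced_entity_id=record.attr(ATTR_REFERENCED_ENTITY),
        destination_bundle_digest=record.attr(ATTR_DESTINATION_DIGEST),
    )


def connectors(bundle) -> Tuple[ConnectorRecord, ...]:
    """All connector views in a bundle-like object."""
    return tuple(
        connector_view(r)
        for r in bundle.records
        if r.backbone_type is not None and r.backbone_type.is_connector
    )


def _destination_attrs(destination_bundle_id, service_url, destination_digest):
    attrs = []
    if destination_bundle_id is not None:
        attrs.append((ATTR_DESTINATION_BUNDLE, destination_bundle_id))
    if service_url is not None:
        attrs.append((ATTR_SERVICE_URL, service_url))
    if destination_digest is not None:
        attrs.append((ATTR_DESTINATION_DIGEST, destination_digest))
    return attrs


class BundleBuilder:
    """Mutable assembly of a single backbone bundle.

    Create with :func:`start_bundle`. All mutating operations raise
    :class:`ImmutabilityError` once the builder is frozen (normally by
    :func:`provbackbone.finalization.finalize`).
    """

    def __init__(self, org_namespace: str, org_prefix: str, local_id: str):
        self.org_namespace = org_namespace
        self.org_prefix = org_prefix
        self.bundle_id = make_qualified_id(org_prefix, org_namespace, f"bundle/{local_id}")
        self.main_activity_id = make_qualified_id(
            org_prefix, org_namespace, f"activity/{local_id}"
        )
        self._records: dict = {}
        self._relations: list = []
        self._passthrough: tuple = ()
        self._prefix_hints: tuple = ()
        self._frozen = False
        self._declare(
            Record(
                kind="activity",
                id=self.main_activity_id,
                backbone_type=BackboneType.MAIN_ACTIVITY,
            )
        )

    # -- plumbing ----------------------------------------------------------

    @property
    def frozen(self) -> bool:
        return self._frozen

    @property
    def records(self) -> tuple:
        return tuple(self._records.values())

    @property
    def relations(self) -> tuple:
        return tuple(self._relations)

    @property
    def passthrough(self) -> tuple:
        return self._passthrough

    @property
    def prefix_hints(self) -> tuple:
        return self._prefix_hints

    def freeze(self) -> None:
        self._frozen = True

    def snapshot(self) -> RawBundle:
        return RawBundle(
            bundle_id=self.bundle_id,
            records=self.records,
            relations=self.relations,
            passthrough=self._passthrough,
            prefix_hints=self._prefix_hints,
        )

    def record(self, rid: QualifiedId) -> Optional[Record]:
        return self._records.get(rid)

    def backbone_records(self, *types: BackboneType) -> tuple:
        wanted = set(types) if types else None
        return tuple(
            r
            for r in self._records.values()
            if r.backbone_type is not None
            and (wanted is None or r.backbone_type in wanted)
        )

    def _guard(self) -> None:
        if self._frozen:
            raise ImmutabilityError(
                f"bundle {self.bundle_id} is finalized; updates require a new version"
            )

    def _declare(self, record: Record) -> None:
        existing = self._records.get(record.id)
        if existing is not None:
            raise IntegrityError(f"id {record.id} already declared", record.id)
        self._records[record.id] = record

    def _local_id(self, local_name: str) -> QualifiedId:
        return make_qualified_id(self.org_prefix, self.org_namespace, local_name)

    def _fresh_local(self, stem: str) -> str:
        if stem not in {r.local_name for r in self._known_locals()}:
            return stem
        for n in itertools.count(2):
            candidate = f"{stem}-{n}"
            if candidate not in {r.local_name for r in self._known_locals()}:
                return candidate
        raise AssertionError("unreachable")

    def _known_locals(self):
        return [rid for rid in self._records if rid.namespace_uri == self.org_namespace]

    def _check_new_connector(self, shared_id: QualifiedId) -> None:
        if not shared_id.is_connector_name():
            raise IdentifierError(
                f"connector identifiers must use the reserved "
                f"'{CONNECTOR_SEGMENT}' segment: {shared_id}"
            )
        existing = self._records.get(shared_id)
        if existing is not None:
            if existing.backbone_type is not None and existing.backbone_type.is_connector:
                raise DuplicateConnectorError(
                    f"connector {shared_id} already present in this bundle"
                )
            raise IntegrityError(f"id {shared_id} already declared", shared_id)

    def _ensure_agent(self, agent_id: QualifiedId, role: BackboneType) -> None:
        existing = self._records.get(agent_id)
        if existing is None:
            self._declare(Record(kind="agent", id=agent_id, backbone_type=role))
            return
        if existing.kind != "agent" or existing.backbone_type is not role:
            raise BackboneTypeError(
                f"{agent_id} is already declared as "
                f"{existing.backbone_type.value if existing.backbone_type else existing.kind}; "
                f"use a distinct agent id per role"
            )

    def _relate(self, kind: RelationKind, subject, obj, attributes=()) -> Relation:
        rel = Relation(kind=kind, subject=subject, object=obj, attributes=attributes)
        self._relations.append(rel)
        return rel

    # -- backbone operations ----------------------------------------------

    def record_receipt(
        self,
        shared_id: QualifiedId,
        sender_agent_id: QualifiedId,
        destination_bundle_id: Optional[QualifiedId] = None,
        service_url: Optional[str] = None,
        destination_digest: Optional[str] = None,
    ) -> Tuple[QualifiedId, QualifiedId]:
        """Document the receipt of an object sent by another organization.

        ``shared_id`` is the connector identifier agreed with the sender and
        carries the sender's namespace. Returns ``(receiver_connector_id,
        external_input_id)``. The destination attributes point back at the
        sender's bundle; leaving them unset is legal — traversal will then
        report a missing-navigation hop instead of following the link.
        """
        self._guard()
        if shared_id.namespace_uri == self.org_namespace:
            raise IdentifierError(
                f"received object's shared id {shared_id} must carry the sending "
                f"organization's namespace, not the receiver's"
            )
        self._check_new_connector(shared_id)

        tail = shared_id.local_name[len(CONNECTOR_SEGMENT):]
        ei_id = self._local_id(self._fresh_local(f"input/{shared_id.prefix}-{tail}"))
        receipt_id = self._local_id(self._fresh_local(f"receipt/{shared_id.prefix}-{tail}"))

        self._declare(
            Record(
                kind="entity",
                id=shared_id,
                backbone_type=BackboneType.RECEIVER_CONNECTOR,
                attributes=_destination_attrs(
                    destination_bundle_id, service_url, destination_digest
                ),
            )
        )
        self._declare(
            Record(kind="entity", id=ei_id, backbone_type=BackboneType.EXTERNAL_INPUT)
        )
        self._declare(
            Record(
                kind="activity", id=receipt_id, backbone_type=BackboneType.RECEIPT_ACTIVITY
            )
        )
        self._ensure_agent(sender_agent_id, BackboneType.SENDER_AGENT)
        self._relate(RelationKind.USED, receipt_id, shared_id)
        self._relate(RelationKind.WAS_GENERATED_BY, ei_id, receipt_id)
        self._relate(RelationKind.WAS_INVALIDATED_BY, shared_id, receipt_id)
        self._relate(RelationKind.WAS_DERIVED_FROM, ei_id, shared_id)
        self._relate(RelationKind.WAS_ATTRIBUTED_TO, shared_id, sender_agent_id)
        return shared_id, ei_id

    def record_external_input(self, local_name: str) -> QualifiedId:
        """Document an input whose previous provenance cannot be located.

        Creates a bare *externalInput* with no receiver connector and no
        receipt wiring; backward traversal will terminate at it.
        """
        self._guard()
        if not local_name:
            raise IdentifierError("external input needs a non-empty name")
        ei_id = self._local_id(self._fresh_local(f"input/{local_name}"))
        self._declare(
            Record(kind="entity", id=ei_id, backbone_type=BackboneType.EXTERNAL_INPUT)
        )
        return ei_id

    def record_output(
        self,
        shared_local_name: str,
        receiver_agent_id: Optional[QualifiedId] = None,
        destination_bundle_id: Optional[QualifiedId] = None,
        service_url: Optional[str] = None,
        destination_digest: Optional[str] = None,
    ) -> QualifiedId:
        """Document an output sent (or to be sent) to another organization.

        The *senderConnector* id is minted in this organization's namespace:
        the builder's organization is the sender, and the shared identifier
        always carries the sender's prefix. Destination attributes may be
        absent at creation and added later through a revision.
        """
        self._guard()
        if not shared_local_name:
            raise IdentifierError("output connector needs a non-empty name")
        sc_id = self._local_id(f"{CONNECTOR_SEGMENT}{shared_local_name}")
        self._check_new_connector(sc_id)
        self._declare(
            Record(
                kind="entity",
                id=sc_id,
                backbone_type=BackboneType.SENDER_CONNECTOR,
                attributes=_destination_attrs(
                    destination_bundle_id, service_url, destination_digest
                ),
            )
        )
        self._relate(RelationKind.WAS_GENERATED_BY, sc_id, self.main_activity_id)
        if receiver_agent_id is not None:
            self._ensure_agent(receiver_agent_id, BackboneType.RECEIVER_AGENT)
            self._relate(RelationKind.WAS_ATTRIBUTED_TO, sc_id, receiver_agent_id)
        return sc_id

    def link_derivation(self, sender_connector_id: QualifiedId,
                        external_input_id: QualifiedId) -> Relation:
        """Declare that an output was affected by an input.

        Adds ``senderConnector wasDerivedFrom externalInput`` — the edge the
        traversal algorithm walks. Emitted if and only if the output was
        actually affected by the input, so the caller decides per pair.
        Re-linking an existing pair is a no-op.
        """
        self._guard()
        sc = self._expect(sender_connector_id, BackboneType.SENDER_CONNECTOR)
        ei = self._expect(external_input_id, BackboneType.EXTERNAL_INPUT)
        for rel in self._relations:
            if (
                rel.kind is RelationKind.WAS_DERIVED_FROM
                and rel.subject == sc.id
                and rel.object == ei.id
            ):
                return rel
        return self._relate(RelationKind.WAS_DERIVED_FROM, sc.id, ei.id)

    def add_jump_backward(
        self,
        external_input_id: QualifiedId,
        shared_id: QualifiedId,
        destination_bundle_id: QualifiedId,
        service_url: str,
        referenced_entity_id: QualifiedId,
        destination_digest: Optional[str] = None,
    ) -> QualifiedId:
        """Bridge an input to a non-adjacent *previous* step.

        The jump connector represents the object from which this process's
        input was (transitively) derived; ``referenced_entity_id`` names the
        senderConnector or externalInput it corresponds to inside the
        destination bundle. All destination attributes are mandatory.
        """
        self._guard()
        ei = self._expect(external_input_id, BackboneType.EXTERNAL_INPUT)
        jc_id = self._add_jump(
            shared_id,
            BackboneType.JUMP_BACKWARD_CONNECTOR,
            destination_bundle_id,
            service_url,
            referenced_entity_id,
            destination_digest,
        )
        self._relate(RelationKind.WAS_DERIVED_FROM, ei.id, jc_id)
        return jc_id

    def add_jump_forward(
        self,
        sender_connector_id: QualifiedId,
        shared_id: QualifiedId,
        destination_bundle_id: QualifiedId,
        service_url: str,
        referenced_entity_id: QualifiedId,
        destination_digest: Optional[str] = None,
    ) -> QualifiedId:
        """Bridge an output to a non-adjacent *consecutive* step.

        Symmetric to :meth:`add_jump_backward`:
        ``jumpForwardConnector wasDerivedFrom senderConnector``.
        """
        self._guard()
        sc = self._expect(sender_connector_id, BackboneType.SENDER_CONNECTOR)
        jc_id = self._add_jump(
            shared_id,
            BackboneType.JUMP_FORWARD_CONNECTOR,
            destination_bundle_id,
            service_url,
            referenced_entity_id,
            destination_digest,
        )
        self._relate(RelationKind.WAS_DERIVED_FROM, jc_id, sc.id)
        return jc_id

    def _add_jump(
        self, shared_id, jump_kind, destination_bundle_id, service_url,
        referenced_entity_id, destination_digest,
    ) -> QualifiedId:
        from .errors import IncompleteJumpError

        if destination_bundle_id is None or not service_url or referenced_entity_id is None:
            raise IncompleteJumpError(
                "jump connectors exist solely for navigation and need all three "
                "destination attributes (bundle id, service URL, referenced entity)"
            )
        self._check_new_connector(shared_id)
        attrs = _destination_attrs(destination_bundle_id, service_url, destination_digest)
        attrs.append((ATTR_REFERENCED_ENTITY, referenced_entity_id))
        self._declare(
            Record(kind="entity", id=shared_id, backbone_type=jump_kind, attributes=attrs)
        )
        return shared_id

    # -- auxiliary mutations ----------------------------------------------

    def set_connector_destination(
        self,
        connector_id: QualifiedId,
        destination_bundle_id: Optional[QualifiedId] = None,
        service_url: Optional[str] = None,
        destination_digest: Optional[str] = None,
    ) -> None:
        """Fill in or replace a connector's destination attributes.

        Used when preparing a *revision* of a bundle whose connector was
        created before the destination was known.
        """
        self._guard()
        rec = self._records.get(connector_id)
        if rec is None:
            raise IntegrityError(f"unknown connector {connector_id}", connector_id)
        if rec.backbone_type is None or not rec.backbone_type.is_connector:
            raise BackboneTypeError(f"{connector_id} is not a connector")
        replaced_keys = set()
        for key, value in _destination_attrs(
            destination_bundle_id, service_url, destination_digest
        ):
            replaced_keys.add(key)
        kept = tuple(
            (k, v) for k, v in rec.attributes if k not in replaced_keys
        )
        new_attrs = kept + tuple(
            _destination_attrs(destination_bundle_id, service_url, destination_digest)
        )
        self._records[connector_id] = Record(
            kind=rec.kind, id=rec.id, attributes=new_attrs, backbone_type=rec.backbone_type
        )

    def add_attribute(self, record_id: QualifiedId, key: QualifiedId, value) -> None:
        """Append an attribute pair to an existing record (e.g. a timestamp)."""
        self._guard()
        rec = self._records.get(record_id)
        if rec is None:
            raise IntegrityError(f"unknown record {record_id}", record_id)
        self._records[record_id] = Record(
            kind=rec.kind,
            id=rec.id,
            attributes=rec.attributes + ((key, value),),
            backbone_type=rec.backbone_type,
        )

    def _expect(self, rid: QualifiedId, bbtype: BackboneType) -> Record:
        rec = self._records.get(rid)
        if rec is None:
            raise IntegrityError(f"unknown id {rid}", rid)
        if rec.backbone_type is not bbtype:
            raise BackboneTypeError(
                f"{rid} is {rec.backbone_type.value if rec.backbone_type else rec.kind}, "
                f"expected {bbtype.value}"
            )
        return rec

    @classmethod
    def from_bundle(cls, bundle, new_local_id: str) -> "BundleBuilder":
        """Start a builder pre-loaded with an existing bundle's content.

        The new builder gets a fresh bundle id (and main-activity id) derived
        from ``new_local_id`` in the same organization namespace — this is
        the entry point of the versioning workflow: load, amend, re-finalize
        under a new identifier, then record the revision in the meta-bundle.
        """
        src_id = bundle.bundle_id
        builder = cls(src_id.namespace_uri, src_id.prefix, new_local_id)
        # Replace the auto-created main activity with the source bundle's one.
        del builder._records[builder.main_activity_id]
        for rec in bundle.records:
            builder._records[rec.id] = rec
        mains = builder.backbone_records(BackboneType.MAIN_ACTIVITY)
        builder.main_activity_id = mains[0].id if mains else builder.main_activity_id
        builder._relations = list(bundle.relations)
        builder._passthrough = tuple(bundle.passthrough)
        builder._prefix_hints = tuple(getattr(bundle, "prefix_hints", ()))
        return builder


def start_bundle(org_namespace: str, org_prefix: str, local_id: str) -> BundleBuilder:
    """Open an empty backbone bundle for one documented process.

    The bundle id and the single pre-created *mainActivity* id are derived
    from ``local_id`` in the organization's namespace, so two builders
    started with the same arguments address the same bundle identifier.
    """
    return BundleBuilder(org_namespace, org_prefix, local_id)
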