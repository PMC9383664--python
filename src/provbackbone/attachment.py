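"""Opaque attachment of domain-specific provenance.

The backbone deliberately carries no domain detail: anything potentially
sensitive (patient-related metadata, file hashes, model configurations)
lives in *domain-specific* records attached to the backbone through the
compound-activities pattern. A backbone activity (the mainActivity or a
receiptActivity) is interpreted as a compound of sub-activities listed in
its ``dct:hasPart`` attribute; the sub-activities consume and produce
*interproducts*, and only the first and last of those touch the backbone —
via ``prov:specializationOf`` to the backbone entity the compound activity
consumed (externalInput / receiverConnector) or produced (senderConnector /
externalInput).

Because specialization is the *only* relation allowed across the
backbone/domain boundary, chain traversal never needs to read a single
domain record — the least-privilege property ``check_opaqueness`` verifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

from .errors import (
    AttachmentStructureError,
    BackboneTypeError,
    BoundaryViolationError,
)
from .identifiers import QualifiedId, dct_id
from .model import BackboneType, Record, Relation, RelationKind

HAS_PART = dct_id("hasPart")


@dataclass(frozen=True)
class DomainAttachment:
    """Result of attaching a domain sub-process to a compound activity."""

    compound_activity_id: QualifiedId
    subactivities: Tuple[QualifiedId, ...]
    interproducts: Tuple[QualifiedId, ...]
    boundary_links: Tuple[Tuple[QualifiedId, QualifiedId], ...]  # (domain, backbone)


def _default_boundary(builder, compound_id):
    """Pick the backbone input/output entities for a compound activity.

    For the mainActivity: the bundle's externalInputs and senderConnectors.
    For a receiptActivity: the receiverConnector it used and the
    externalInput it generated.
    """
    compound = builder.record(compound_id)
    if compound is None or compound.backbone_type not in (
        BackboneType.MAIN_ACTIVITY,
        BackboneType.RECEIPT_ACTIVITY,
    ):
        raise BackboneTypeError(
            f"{compound_id} is not a backbone compound activity "
            f"(mainActivity or receiptActivity)"
        )
    if compound.backbone_type is BackboneType.MAIN_ACTIVITY:
        ins = [r.id for r in builder.backbone_records(BackboneType.EXTERNAL_INPUT)]
        outs = [r.id for r in builder.backbone_records(BackboneType.SENDER_CONNECTOR)]
    else:
        ins = [
            rel.object
            for rel in builder.relations
            if rel.kind is RelationKind.USED and rel.subject == compound_id
        ]
        outs = [
            rel.subject
            for rel in builder.relations
            if rel.kind is RelationKind.WAS_GENERATED_BY and rel.object == compound_id
        ]
    return ins, outs


def attach_domain_process(
    builder,
    compound_activity_id: QualifiedId,
    subactivity_specs: Sequence[tuple],
    *,
    input_backbone_id: Optional[QualifiedId] = None,
    output_backbone_id: Optional[QualifiedId] = None,
) -> DomainAttachment:
    """Attach an ordered chain of domain sub-activities to a backbone activity.

    ``subactivity_specs`` is an ordered list of
    ``(activity_id, consumed_entity_ids, produced_entity_ids)``. The specs
    must form a connected consume/produce chain: every sub-activity after
    the first consumes at least one entity produced earlier. Entities and
    activities named in the specs are declared as plain (non-backbone)
    records; referencing a backbone entity as an interproduct is a boundary
    violation.

    The compound activity receives one ``dct:hasPart`` attribute per
    sub-activity, in order. Boundary specialization edges are added from the
    chain's first consumed entity to the compound's input backbone entity
    and from its last produced entity to the output backbone entity; when
    the compound has several candidates (or none), pass
    ``input_backbone_id`` / ``output_backbone_id`` explicitly.

    Raises
    ------
    AttachmentStructureError
        Empty or disconnected spec chain, or ambiguous default boundary.
    BoundaryViolationError
        A spec names a backbone record as a sub-activity or interproduct.
    ImmutabilityError
        If the builder is frozen.
    """
    builder._guard()
    if not subactivity_specs:
        raise AttachmentStructureError("attachment needs at least one sub-activity")

    default_ins, default_outs = _default_boundary(builder, compound_activity_id)

    def resolve_boundary(explicit, candidates, side):
        if explicit is not None:
            rec = builder.record(explicit)
            if rec is None or rec.backbone_type is None or rec.kind != "entity":
                raise BoundaryViolationError(
                    f"{side} boundary {explicit} is not a backbone entity"
                )
            return explicit
        if len(candidates) == 1:
            return candidates[0]
        if not candidates:
            return None  # no backbone entity on this side (e.g. chain start input)
        raise AttachmentStructureError(
            f"compound activity has {len(candidates)} candidate {side} backbone "
            f"entities; pass {side}_backbone_id explicitly"
        )

    input_backbone = resolve_boundary(input_backbone_id, default_ins, "input")
    output_backbone = resolve_boundary(output_backbone_id, default_outs, "output")

    # Declare records, checking the boundary as we go.
    backbone_ids = {r.id for r in builder.records if r.backbone_type is not None}
    produced_so_far: set = set()
    subactivity_ids = []
    interproducts: list = []
    first_consumed = None
    last_produced = None
    for index, (act_id, consumed, produced) in enumerate(subactivity_specs):
        if act_id in backbone_ids:
            raise BoundaryViolationError(
                f"sub-activity {act_id} collides with a backbone record"
            )
        for eid in tuple(consumed) + tuple(produced):
            if eid in backbone_ids:
                raise BoundaryViolationError(
                    f"backbone entity {eid} referenced as a domain interproduct; "
                    f"only specializationOf may cross the boundary"
                )
        if index > 0 and not (set(consumed) & produced_so_far):
            raise AttachmentStructureError(
                f"sub-activity {act_id} consumes nothing produced earlier; "
                f"the spec chain is disconnected"
            )
        if index == 0:
            if not consumed:
                raise AttachmentStructureError("first sub-activity must consume an entity")
            first_consumed = tuple(consumed)[0]
        if produced:
            last_produced = tuple(produced)[-1]
        produced_so_far.update(produced)
        subactivity_ids.append(act_id)

        if builder.record(act_id) is None:
            builder._declare(Record(kind="activity", id=act_id))
        for eid in tuple(consumed) + tuple(produced):
            if builder.record(eid) is None:
                builder._declare(Record(kind="entity", id=eid))
                interproducts.append(eid)
        for eid in consumed:
            builder._relate(RelationKind.USED, act_id, eid)
        for eid in produced:
            builder._relate(RelationKind.WAS_GENERATED_BY, eid, act_id)

    if last_produced is None:
        raise AttachmentStructureError("the sub-activity chain produces no entity")

    for sub_id in subactivity_ids:
        builder.add_attribute(compound_activity_id, HAS_PART, sub_id)

    boundary_links = []
    if input_backbone is not None:
        builder._relate(RelationKind.SPECIALIZATION_OF, first_consumed, input_backbone)
        boundary_links.append((first_consumed, input_backbone))
    if output_backbone is not None:
        builder._relate(RelationKind.SPECIALIZATION_OF, last_produced, output_backbone)
        boundary_links.append((last_produced, output_backbone))

    return DomainAttachment(
        compound_activity_id=compound_activity_id,
        subactivities=tuple(subactivity_ids),
        interproducts=tuple(interproducts),
        boundary_links=tuple(boundary_links),
    )


@dataclass(frozen=True)
class OpaquenessReport:
    """Edges crossing the backbone/domain boundary other than specialization."""

    crossing_edges: Tuple[Relation, ...]

    @property
    def is_opaque_safe(self) -> bool:
        return not self.crossing_edges


def check_opaqueness(bundle) -> OpaquenessReport:
    """List every non-specialization edge between backbone and domain records.

    An empty report means the bundle is *opaque-safe*: a traversal restricted
    to backbone records can never be forced to read domain content.
    """
    typed = {r.id: (r.backbone_type is not None) for r in bundle.records}
    crossing = tuple(
        rel
        for rel in bundle.relations
        if rel.kind is not RelationKind.SPECIALIZATION_OF
        and typed.get(rel.subject, False) != typed.get(rel.object, False)
    )
    return OpaquenessReport(crossing_edges=crossing)
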