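"""Structural conformance checking and chain-position classification.

``validate_backbone`` lints a bundle against rule set R — the structural
constraints the backbone pattern imposes on top of PROV-DM. Problems are
reported, never raised, so third-party documents can be linted wholesale:

====  ====================================================================
R0    referential integrity (every relation endpoint declared, kinds match)
R1    at most one mainActivity per bundle
R2    at most one receiptActivity per (receiverConnector, externalInput) pair
R3    at most one destination bundle per connector
R4    every externalInput generated by a receiptActivity derives from
      exactly one receiverConnector
R5    every senderConnector is generated by the mainActivity
R6    jump connectors carry all three destination attributes
R7    derivations between backbone entities follow the prescribed type pairs
      (SC←EI, EI←RC, EI←jumpBackward, jumpForward←SC)
R8    connector attribution: receiverConnector → senderAgent,
      senderConnector → receiverAgent
R9    backbone records link to non-backbone records only via specializationOf
====  ====================================================================

``classify_position`` labels a valid bundle by which backbone entities it
contains: a bundle with outputs only starts a chain, one with inputs only
ends it, and so on. Mixed bundles (many inputs and outputs in different
states) get a bundle-level label by precedence plus a per-object detail map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import ClassificationError, IntegrityError
from .model import (
    ATTR_DESTINATION_BUNDLE,
    BackboneType,
    RelationKind,
    check_integrity,
)

_ALLOWED_BACKBONE_DERIVATIONS = {
    (BackboneType.SENDER_CONNECTOR, BackboneType.EXTERNAL_INPUT),
    (BackboneType.EXTERNAL_INPUT, BackboneType.RECEIVER_CONNECTOR),
    (BackboneType.EXTERNAL_INPUT, BackboneType.JUMP_BACKWARD_CONNECTOR),
    (BackboneType.JUMP_FORWARD_CONNECTOR, BackboneType.SENDER_CONNECTOR),
}


@dataclass(frozen=True)
class Violation:
    rule: str
    subject_id: Optional[object]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def rules(self) -> set:
        return {v.rule for v in self.violations}

    def __bool__(self) -> bool:  # truthy iff valid, convenient for asserts
        return self.is_valid


class PositionLabel(Enum):
    COMPLETE = "COMPLETE"
    CHAIN_START = "CHAIN_START"
    MISSING_BACKLINK = "MISSING_BACKLINK"
    CHAIN_END = "CHAIN_END"
    ISOLATED_END = "ISOLATED_END"


@dataclass(frozen=True)
class ChainPosition:
    """Bundle-level label plus per-input/per-output detail.

    ``inputs`` maps each externalInput id to ``received`` (a receiver
    connector backs it), ``jump-linked`` (only a jump connector backs it) or
    ``orphan``; ``outputs`` maps each senderConnector id to ``addressed`` /
    ``unaddressed`` by whether its destination attributes are filled.
    """

    label: PositionLabel
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    flags: tuple = ()


def validate_backbone(bundle) -> ValidationReport:
    """Check rule set R over any bundle-like object; never raises."""
    violations = []

    try:
        check_integrity(bundle.records, bundle.relations)
    except IntegrityError as exc:
        violations.append(Violation("R0", exc.missing_id, str(exc)))
        return ValidationReport(tuple(violations))

    by_id = {r.id: r for r in bundle.records}
    by_type: dict = {}
    for rec in bundle.records:
        if rec.backbone_type is not None:
            by_type.setdefault(rec.backbone_type, []).append(rec)

    def typed(rid):
        rec = by_id.get(rid)
        return rec.backbone_type if rec is not None else None

    # R1 — a bundle documents exactly one process
    mains = by_type.get(BackboneType.MAIN_ACTIVITY, [])
    if len(mains) > 1:
        for rec in mains[1:]:
            violations.append(
                Violation("R1", rec.id, "more than one mainActivity in bundle")
            )

    # R2 — at most one receipt activity per (RC, EI) pair
    used_by_receipt: dict = {}
    generated_by_receipt: dict = {}
    for rel in bundle.relations:
        if rel.kind is RelationKind.USED and typed(rel.subject) is BackboneType.RECEIPT_ACTIVITY:
            used_by_receipt.setdefault(rel.subject, []).append(rel.object)
        if (
            rel.kind is RelationKind.WAS_GENERATED_BY
            and typed(rel.object) is BackboneType.RECEIPT_ACTIVITY
        ):
            generated_by_receipt.setdefault(rel.object, []).append(rel.subject)
    pair_receipts: dict = {}
    for receipt in by_type.get(BackboneType.RECEIPT_ACTIVITY, []):
        for rc in used_by_receipt.get(receipt.id, []):
            for ei in generated_by_receipt.get(receipt.id, []):
                pair_receipts.setdefault((rc, ei), []).append(receipt.id)
    for (rc, ei), receipts in pair_receipts.items():
        if len(receipts) > 1:
            violations.append(
                Violation(
                    "R2", rc,
                    f"{len(receipts)} receipt activities mediate the pair ({rc}, {ei})",
                )
            )

    # R3 / R6 — connector destination attributes
    for rec in bundle.records:
        bt = rec.backbone_type
        if bt is None or not bt.is_connector:
            continue
        if len(rec.attr_values(ATTR_DESTINATION_BUNDLE)) > 1:
            violations.append(
                Violation("R3", rec.id, "connector refers to more than one bundle")
            )
        if bt.is_jump:
            from .builder import connector_view

            view = connector_view(rec)
            if not (
                view.destination_bundle_id is not None
                and view.service_url
                and view.referenced_entity_id is not None
            ):
                violations.append(
                    Violation(
                        "R6", rec.id,
                        "jump connector missing a destination attribute",
                    )
                )

    # Derivation indexes
    derived_from: dict = {}
    for rel in bundle.relations:
        if rel.kind is RelationKind.WAS_DERIVED_FROM:
            derived_from.setdefault(rel.subject, []).append(rel.object)

    # R4 — received inputs derive from exactly one receiver connector
    receipt_generated = {ei for eis in generated_by_receipt.values() for ei in eis}
    for ei_rec in by_type.get(BackboneType.EXTERNAL_INPUT, []):
        if ei_rec.id not in receipt_generated:
            continue
        rc_origins = [
            o for o in derived_from.get(ei_rec.id, [])
            if typed(o) is BackboneType.RECEIVER_CONNECTOR
        ]
        if len(rc_origins) != 1:
            violations.append(
                Violation(
                    "R4", ei_rec.id,
                    f"externalInput generated by a receipt derives from "
                    f"{len(rc_origins)} receiver connectors (expected 1)",
                )
            )

    # R5 — sender connectors are generated by the main activity
    main_ids = {rec.id for rec in mains}
    generated_by: dict = {}
    for rel in bundle.relations:
        if rel.kind is RelationKind.WAS_GENERATED_BY:
            generated_by.setdefault(rel.subject, []).append(rel.object)
    for sc_rec in by_type.get(BackboneType.SENDER_CONNECTOR, []):
        gens = generated_by.get(sc_rec.id, [])
        if not main_ids or not (main_ids & set(gens)):
            violations.append(
                Violation("R5", sc_rec.id, "senderConnector not generated by the mainActivity")
            )

    # R7 — backbone derivations follow the prescribed type pairs
    for rel in bundle.relations:
        if rel.kind is not RelationKind.WAS_DERIVED_FROM:
            continue
        ts, to = typed(rel.subject), typed(rel.object)
        if ts is None or to is None:
            continue  # crossing edges are R9's business
        if (ts, to) not in _ALLOWED_BACKBONE_DERIVATIONS:
            violations.append(
                Violation(
                    "R7", rel.subject,
                    f"derivation {ts.value} ← {to.value} is not a backbone path",
                )
            )

    # R8 — attribution direction
    for rel in bundle.relations:
        if rel.kind is not RelationKind.WAS_ATTRIBUTED_TO:
            continue
        ts, to = typed(rel.subject), typed(rel.object)
        if ts is BackboneType.RECEIVER_CONNECTOR and to is not BackboneType.SENDER_AGENT:
            violations.append(
                Violation("R8", rel.subject,
                          "receiverConnector must be attributed to a senderAgent")
            )
        elif ts is BackboneType.SENDER_CONNECTOR and to is not BackboneType.RECEIVER_AGENT:
            violations.append(
                Violation("R8", rel.subject,
                          "senderConnector must be attributed to a receiverAgent")
            )

    # R9 — the opaqueness boundary: only specializationOf may cross
    for rel in bundle.relations:
        if rel.kind is RelationKind.SPECIALIZATION_OF:
            continue
        ts, to = typed(rel.subject), typed(rel.object)
        if (ts is None) != (to is None):
            backbone_end = rel.subject if ts is not None else rel.object
            violations.append(
                Violation(
                    "R9", backbone_end,
                    f"{rel.kind.value} crosses the backbone/domain boundary",
                )
            )

    return ValidationReport(tuple(violations))


def classify_position(bundle) -> ChainPosition:
    """Label a valid bundle by its position in the provenance chain.

    Raises :class:`ClassificationError` for bundles that fail
    ``validate_backbone``. Labels by presence of backbone entity kinds:
    outputs only → CHAIN_START; outputs and inputs without receiver
    connectors → MISSING_BACKLINK; inputs only (with receivers) → CHAIN_END;
    bare inputs → ISOLATED_END; everything present → COMPLETE. A bundle with
    no connectors and no external inputs at all is labeled ISOLATED_END and
    flagged ``no-exchange``.
    """
    report = validate_backbone(bundle)
    if not report.is_valid:
        raise ClassificationError(
            "refusing to classify an invalid bundle: "
            + ", ".join(sorted(report.rules()))
        )

    by_type: dict = {}
    for rec in bundle.records:
        if rec.backbone_type is not None:
            by_type.setdefault(rec.backbone_type, []).append(rec)

    derived_from: dict = {}
    typed = {r.id: r.backbone_type for r in bundle.records if r.backbone_type}
    for rel in bundle.relations:
        if rel.kind is RelationKind.WAS_DERIVED_FROM:
            derived_from.setdefault(rel.subject, []).append(rel.object)

    inputs = {}
    for ei in by_type.get(BackboneType.EXTERNAL_INPUT, []):
        origins = {typed.get(o) for o in derived_from.get(ei.id, [])}
        if BackboneType.RECEIVER_CONNECTOR in origins:
            inputs[ei.id] = "received"
        elif BackboneType.JUMP_BACKWARD_CONNECTOR in origins:
            inputs[ei.id] = "jump-linked"
        else:
            inputs[ei.id] = "orphan"

    from .builder import connector_view

    outputs = {}
    for sc in by_type.get(BackboneType.SENDER_CONNECTOR, []):
        outputs[sc.id] = (
            "addressed" if connector_view(sc).has_destination else "unaddressed"
        )

    n_rc = len(by_type.get(BackboneType.RECEIVER_CONNECTOR, []))
    n_ei = len(inputs)
    n_sc = len(outputs)

    flags = []
    if n_rc and not n_ei:
        flags.append("receiver-without-input")
    if n_rc == n_ei == n_sc == 0:
        flags.append("no-exchange")

    if n_rc and n_ei and n_sc:
        label = PositionLabel.COMPLETE
    elif n_sc and n_ei:
        label = PositionLabel.MISSING_BACKLINK
    elif n_sc:
        label = PositionLabel.CHAIN_START
    elif n_ei and n_rc:
        label = PositionLabel.CHAIN_END
    else:
        label = PositionLabel.ISOLATED_END

    return ChainPosition(label=label, inputs=inputs, outputs=outputs, flags=tuple(flags))
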