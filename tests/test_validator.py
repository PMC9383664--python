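import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from provbackbone import (
    BackboneType,
    ClassificationError,
    PositionLabel,
    QualifiedId,
    RawBundle,
    Record,
    Relation,
    RelationKind,
    classify_position,
    serialize_bundle,
    start_bundle,
    validate_backbone,
)
from provbackbone.model import ATTR_DESTINATION_BUNDLE, ATTR_REFERENCED_ENTITY
from genutil import ext_agent, ext_connector, random_backbone
from oracles import violated_rules

NS = "https://lab.example/ns#"


def qid(local):
    return QualifiedId("lab", NS, local)


def _with(raw: RawBundle, records=None, relations=None) -> RawBundle:
    return RawBundle(
        bundle_id=raw.bundle_id,
        records=tuple(records if records is not None else raw.records),
        relations=tuple(relations if relations is not None else raw.relations),
        passthrough=raw.passthrough,
    )


class TestRules:
    def test_running_example_bundles_have_no_violations(self, example_bundles):
        for bundle in example_bundles:
            report = validate_backbone(bundle)
            assert report.is_valid, (bundle.bundle_id, report.violations)

    def test_two_main_activities_violate_r1(self):
        builder = start_bundle(NS, "lab", "p")
        raw = builder.snapshot()
        extra = Record("activity", qid("activity/second"),
                       backbone_type=BackboneType.MAIN_ACTIVITY)
        report = validate_backbone(_with(raw, records=raw.records + (extra,)))
        assert "R1" in report.rules()

    def test_connector_with_two_destinations_violates_r3(self):
        builder = start_bundle(NS, "lab", "p")
        sc = builder.record_output("out")
        raw = builder.snapshot()
        records = []
        for rec in raw.records:
            if rec.id == sc:
                rec = Record(
                    rec.kind, rec.id,
                    attributes=rec.attributes
                    + ((ATTR_DESTINATION_BUNDLE, qid("bundle/x")),
                       (ATTR_DESTINATION_BUNDLE, qid("bundle/y"))),
                    backbone_type=rec.backbone_type,
                )
            records.append(rec)
        report = validate_backbone(_with(raw, records=records))
        assert "R3" in report.rules()

    def test_sender_connector_not_generated_by_main_violates_r5(self):
        builder = start_bundle(NS, "lab", "p")
        sc = builder.record_output("out")
        raw = builder.snapshot()
        relations = tuple(
            r for r in raw.relations
            if not (r.kind is RelationKind.WAS_GENERATED_BY and r.subject == sc)
        )
        report = validate_backbone(_with(raw, relations=relations))
        assert "R5" in report.rules()

    def test_jump_without_referenced_entity_violates_r6(self):
        builder = start_bundle(NS, "lab", "p")
        _, ei = builder.record_receipt(ext_connector(0, "o"), ext_agent(0))
        jc = builder.add_jump_backward(
            ei, ext_connector(1, "far"),
            destination_bundle_id=qid("bundle/far"),
            service_url="https://far.example/prov",
            referenced_entity_id=ext_connector(1, "ref"),
        )
        raw = builder.snapshot()
        records = []
        for rec in raw.records:
            if rec.id == jc:
                rec = Record(
                    rec.kind, rec.id,
                    attributes=tuple(
                        (k, v) for k, v in rec.attributes if k != ATTR_REFERENCED_ENTITY
                    ),
                    backbone_type=rec.backbone_type,
                )
            records.append(rec)
        report = validate_backbone(_with(raw, records=records))
        assert "R6" in report.rules()

    def test_reversed_backbone_derivation_violates_r7(self):
        builder = start_bundle(NS, "lab", "p")
        rc, ei = builder.record_receipt(ext_connector(0, "o"), ext_agent(0))
        raw = builder.snapshot()
        reversed_edge = Relation(RelationKind.WAS_DERIVED_FROM, rc, ei)
        report = validate_backbone(_with(raw, relations=raw.relations + (reversed_edge,)))
        assert "R7" in report.rules()

    def test_wrong_attribution_direction_violates_r8(self):
        builder = start_bundle(NS, "lab", "p")
        sc = builder.record_output("out")
        raw = builder.snapshot()
        wrong_agent = Record("agent", qid("agent/self"),
                             backbone_type=BackboneType.SENDER_AGENT)
        bad = Relation(RelationKind.WAS_ATTRIBUTED_TO, sc, wrong_agent.id)
        report = validate_backbone(
            _with(raw, records=raw.records + (wrong_agent,),
                  relations=raw.relations + (bad,))
        )
        assert "R8" in report.rules()

    def test_boundary_crossing_use_violates_r9(self):
        builder = start_bundle(NS, "lab", "p")
        raw = builder.snapshot()
        domain = Record("entity", qid("domain/secret"))
        crossing = Relation(RelationKind.USED, builder.main_activity_id, domain.id)
        report = validate_backbone(
            _with(raw, records=raw.records + (domain,),
                  relations=raw.relations + (crossing,))
        )
        assert "R9" in report.rules()

    def test_dangling_reference_reported_as_r0(self):
        raw = RawBundle(
            bundle_id=qid("bundle/b"),
            records=(Record("activity", qid("a")),),
            relations=(Relation(RelationKind.USED, qid("a"), qid("ghost")),),
        )
        report = validate_backbone(raw)
        assert report.rules() == {"R0"}


class TestClassification:
    def test_running_example_positions(self, example_bundles):
        labels = [classify_position(b).label for b in example_bundles]
        assert labels == [
            PositionLabel.CHAIN_START,    # acquisition: outputs only
            PositionLabel.COMPLETE,       # preanalytics
            PositionLabel.CHAIN_END,      # biobanking: inputs only
            PositionLabel.COMPLETE,       # WSI preprocessing
            PositionLabel.COMPLETE,       # AI training
            PositionLabel.CHAIN_END,      # AI testing
        ]

    def test_orphan_input_only_is_isolated_end(self):
        builder = start_bundle(NS, "lab", "p")
        builder.record_external_input("mystery")
        position = classify_position(builder)
        assert position.label is PositionLabel.ISOLATED_END
        assert list(position.inputs.values()) == ["orphan"]

    def test_orphan_input_with_output_is_missing_backlink(self):
        builder = start_bundle(NS, "lab", "p")
        builder.record_external_input("mystery")
        builder.record_output("out")
        assert classify_position(builder).label is PositionLabel.MISSING_BACKLINK

    def test_mixed_bundle_takes_complete_with_detail(self):
        builder = start_bundle(NS, "lab", "p")
        builder.record_receipt(ext_connector(0, "o"), ext_agent(0))
        builder.record_external_input("mystery")
        builder.record_output("out")
        position = classify_position(builder)
        assert position.label is PositionLabel.COMPLETE
        assert sorted(position.inputs.values()) == ["orphan", "received"]
        assert list(position.outputs.values()) == ["unaddressed"]

    def test_invalid_bundle_refused(self):
        raw = RawBundle(
            bundle_id=qid("bundle/b"),
            records=(Record("activity", qid("a")),),
            relations=(Relation(RelationKind.USED, qid("a"), qid("ghost")),),
        )
        with pytest.raises(ClassificationError):
            classify_position(raw)


# ---------------------------------------------------------------------------
# Oracle equivalence: implementation vs independent JSON-level re-check
# ---------------------------------------------------------------------------


def _mutations(raw: RawBundle, rng: random.Random):
    """Applicable structure-breaking mutations of a valid bundle."""
    by_type = {}
    for rec in raw.records:
        if rec.backbone_type is not None:
            by_type.setdefault(rec.backbone_type, []).append(rec)

    yield _with(
        raw,
        records=raw.records
        + (Record("activity", qid("activity/dup-main"),
                  backbone_type=BackboneType.MAIN_ACTIVITY),),
    )

    connectors = [
        r for r in raw.records
        if r.backbone_type is not None and r.backbone_type.is_connector
    ]
    if connectors:
        victim = rng.choice(connectors)
        records = tuple(
            Record(
                r.kind, r.id,
                attributes=r.attributes
                + ((ATTR_DESTINATION_BUNDLE, qid("bundle/extra1")),
                   (ATTR_DESTINATION_BUNDLE, qid("bundle/extra2"))),
                backbone_type=r.backbone_type,
            )
            if r.id == victim.id else r
            for r in raw.records
        )
        yield _with(raw, records=records)

    scs = by_type.get(BackboneType.SENDER_CONNECTOR, [])
    if scs:
        victim = rng.choice(scs)
        yield _with(
            raw,
            relations=tuple(
                r for r in raw.relations
                if not (r.kind is RelationKind.WAS_GENERATED_BY and r.subject == victim.id)
            ),
        )

    eis = by_type.get(BackboneType.EXTERNAL_INPUT, [])
    rcs = by_type.get(BackboneType.RECEIVER_CONNECTOR, [])
    if eis and rcs:
        yield _with(
            raw,
            relations=raw.relations
            + (Relation(RelationKind.WAS_DERIVED_FROM, rng.choice(rcs).id,
                        rng.choice(eis).id),),
        )

    domain = Record("entity", qid("domain/leak"))
    mains = by_type.get(BackboneType.MAIN_ACTIVITY, [])
    if mains:
        yield _with(
            raw,
            records=raw.records + (domain,),
            relations=raw.relations
            + (Relation(RelationKind.USED, mains[0].id, domain.id),),
        )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_validator_agrees_with_independent_recheck(seed):
    """Rule codes from validate_backbone equal a from-scratch JSON scan,
    on valid bundles and on structure-breaking mutants alike."""
    rng = random.Random(seed)
    raw = random_backbone(rng, with_payload=True).snapshot()
    assert validate_backbone(raw).rules() == violated_rules(serialize_bundle(raw)) == set()
    for mutant in _mutations(raw, rng):
        impl = validate_backbone(mutant).rules()
        oracle = violated_rules(serialize_bundle(mutant))
        assert impl == oracle and impl
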