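import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from provbackbone import (
    BackboneType,
    BackboneTypeError,
    ChainStore,
    PositionLabel,
    StartMissingError,
    TraceOptions,
    build_random_chain,
    build_running_example,
    classify_position,
    drop_bundle,
    finalize,
    local_inputs,
    local_outputs,
    make_qualified_id,
    start_bundle,
    trace_backward,
    trace_forward,
)
from provbackbone.model import RelationKind
from oracles import pasted_graph, reachable


# ---------------------------------------------------------------------------
# Local length-2 derivation-path queries
# ---------------------------------------------------------------------------


class TestLocalQueries:
    def test_wsi_preprocessing_output_traces_to_its_input(
        self, example_store, example_blueprint
    ):
        """The patch-dataset output derives from the WSI-dataset input via the
        receiver connector shared with the pathology department."""
        step = example_blueprint.steps[3]
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        patch_sc = example_blueprint.connector_id(3, 4)
        wsi_ei = example_blueprint.external_input_id(1, 3)
        wsi_rc = example_blueprint.connector_id(1, 3)
        assert local_inputs(bundle, patch_sc) == {(wsi_ei, wsi_rc)}

    def test_reverse_query_finds_the_affected_output(
        self, example_store, example_blueprint
    ):
        step = example_blueprint.steps[3]
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        wsi_rc = example_blueprint.connector_id(1, 3)
        patch_sc = example_blueprint.connector_id(3, 4)
        assert local_outputs(bundle, wsi_rc) == {(patch_sc, ())}

    def test_chain_start_output_has_no_traceable_inputs(
        self, example_store, example_blueprint
    ):
        step = example_blueprint.steps[0]
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        assert local_inputs(bundle, example_blueprint.connector_id(0, 1)) == set()

    def test_chain_end_input_affects_no_outputs(self, example_store, example_blueprint):
        step = example_blueprint.steps[5]
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        assert local_outputs(bundle, example_blueprint.external_input_id(4, 5)) == set()

    def test_non_sender_start_is_a_type_error(self, example_store, example_blueprint):
        step = example_blueprint.steps[3]
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        with pytest.raises(BackboneTypeError):
            local_inputs(bundle, example_blueprint.external_input_id(1, 3))
        with pytest.raises(BackboneTypeError):
            local_outputs(bundle, example_blueprint.connector_id(3, 4))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_equals_exhaustive_length2_path_enumeration(self, seed):
        """Random backbone with up to 5 inputs / 3 outputs and a random
        derivation subset: local queries equal brute-force enumeration of
        directed wasDerivedFrom paths of length two."""
        from genutil import random_backbone

        rng = random.Random(seed)
        builder = random_backbone(rng)
        derivs = [
            (r.subject, r.object)
            for r in builder.relations
            if r.kind is RelationKind.WAS_DERIVED_FROM
        ]
        typed = {r.id: r.backbone_type for r in builder.records}
        for sc in (r.id for r in builder.backbone_records(BackboneType.SENDER_CONNECTOR)):
            expected = set()
            for a, b in derivs:  # first hop: SC -> EI
                if a != sc or typed.get(b) is not BackboneType.EXTERNAL_INPUT:
                    continue
                origins = [
                    d for c, d in derivs
                    if c == b and typed.get(d) in (
                        BackboneType.RECEIVER_CONNECTOR,
                        BackboneType.JUMP_BACKWARD_CONNECTOR,
                    )
                ]
                expected |= {(b, o) for o in origins} if origins else {(b, None)}
            assert local_inputs(builder, sc) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_reverse_query_equals_reverse_enumeration(self, seed):
        from genutil import random_backbone

        builder = random_backbone(random.Random(seed))
        derivs = [
            (r.subject, r.object)
            for r in builder.relations
            if r.kind is RelationKind.WAS_DERIVED_FROM
        ]
        typed = {r.id: r.backbone_type for r in builder.records}
        for ei in (r.id for r in builder.backbone_records(BackboneType.EXTERNAL_INPUT)):
            expected = set()
            for a, b in derivs:
                if b != ei or typed.get(a) is not BackboneType.SENDER_CONNECTOR:
                    continue
                jumps = tuple(sorted(
                    c for c, d in derivs
                    if d == a and typed.get(c) is BackboneType.JUMP_FORWARD_CONNECTOR
                ))
                expected.add((a, jumps))
            assert local_outputs(builder, ei) == expected


# ---------------------------------------------------------------------------
# Cross-bundle traversal on the running example
# ---------------------------------------------------------------------------


class TestRunningExampleTraces:
    def test_backward_walk_spans_the_whole_pipeline(
        self, example_store, example_blueprint
    ):
        """From the AI-testing input back to specimen acquisition: five
        bundles, terminating at the chain start."""
        testing = example_blueprint.steps[5]
        result = trace_backward(
            example_store,
            testing.service_url,
            testing.bundle_id,
            example_blueprint.external_input_id(4, 5),
        )
        visited = {str(b) for b in result.bundles()}
        assert visited == {
            "test:bundle/ai-testing",
            "train:bundle/ai-training",
            "prep:bundle/wsi-preprocessing",
            "path:bundle/preanalytics",
            "clin:bundle/acquisition",
        }
        assert not result.frontier
        acquisition = example_store.fetch(
            example_blueprint.steps[0].service_url, example_blueprint.steps[0].bundle_id
        )
        assert classify_position(acquisition).label is PositionLabel.CHAIN_START

    def test_forward_walk_reaches_both_branches(self, example_store, example_blueprint):
        """The specimen forks: biobanking on one branch, AI testing on the other."""
        acquisition = example_blueprint.steps[0]
        result = trace_forward(
            example_store,
            acquisition.service_url,
            acquisition.bundle_id,
            example_blueprint.connector_id(0, 1),
        )
        visited = {str(b) for b in result.bundles()}
        assert "bbk:bundle/biobanking" in visited
        assert "test:bundle/ai-testing" in visited
        assert len(visited) == 6

    def test_forward_from_chain_end_input_is_single_bundle(
        self, example_store, example_blueprint
    ):
        testing = example_blueprint.steps[5]
        result = trace_forward(
            example_store,
            testing.service_url,
            testing.bundle_id,
            example_blueprint.external_input_id(4, 5),
        )
        assert result.bundles() == {testing.bundle_id}
        assert result.edges == []

    def test_domain_entity_start_resolves_through_specialization(
        self, example_store, example_blueprint
    ):
        step = example_blueprint.steps[3]
        domain_out = make_qualified_id(step.prefix, step.namespace,
                                       "domain/wsi-preprocessing/product0")
        # product0 specializes the input side; the *last* product the output.
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        spec_edges = [
            r for r in bundle.relations if r.kind is RelationKind.SPECIALIZATION_OF
        ]
        assert spec_edges, "fixture should attach a domain payload"
        some_domain = spec_edges[0].subject
        result = trace_backward(
            example_store, step.service_url, step.bundle_id, some_domain
        )
        assert step.bundle_id in result.bundles()

    def test_start_not_found_raises(self, example_store, example_blueprint):
        step = example_blueprint.steps[0]
        with pytest.raises(StartMissingError):
            trace_backward(
                example_store,
                step.service_url,
                make_qualified_id("clin", step.namespace, "bundle/ghost"),
                example_blueprint.connector_id(0, 1),
            )


class TestFaultTolerance:
    def _gapped(self):
        store, blueprint = build_running_example(seed=3)
        prep = blueprint.steps[3]
        drop_bundle(store, prep.service_url, prep.bundle_id)
        return store, blueprint

    def test_jump_bridges_the_missing_preprocessing_bundle(self):
        store, blueprint = self._gapped()
        training = blueprint.steps[4]
        result = trace_backward(
            store, training.service_url, training.bundle_id,
            blueprint.connector_id(4, 5),
        )
        visited = {str(b) for b in result.bundles()}
        assert "clin:bundle/acquisition" in visited
        assert "jump" in result.hop_kinds()
        assert "missing" in result.hop_kinds()  # the normal route still breaks

    def test_without_jumps_the_branch_ends_with_a_missing_hop(self):
        store, blueprint = self._gapped()
        training = blueprint.steps[4]
        result = trace_backward(
            store, training.service_url, training.bundle_id,
            blueprint.connector_id(4, 5),
            TraceOptions(use_jumps=False),
        )
        visited = {str(b) for b in result.bundles()}
        assert visited == {"train:bundle/ai-training"}
        assert result.frontier and "missing" in result.hop_kinds()

    def test_both_routes_reported_when_jump_and_receiver_coexist(
        self, example_store, example_blueprint
    ):
        """The AI-training dataset input carries a receiver connector AND a
        jumpBackward to acquisition: the trace reports both."""
        training = example_blueprint.steps[4]
        result = trace_backward(
            example_store, training.service_url, training.bundle_id,
            example_blueprint.connector_id(4, 5),
        )
        kinds = result.hop_kinds()
        assert "jump" in kinds and "cross" in kinds

    def test_unaddressed_receipt_yields_missing_navigation_hop(self):
        sender_ns = "https://a.example/ns#"
        shared = make_qualified_id("a", sender_ns, "connector/obj")
        receiver = start_bundle("https://b.example/ns#", "b", "proc")
        _, ei = receiver.record_receipt(
            shared, make_qualified_id("a", sender_ns, "agent/a")
        )  # no destination attributes on purpose
        sc = receiver.record_output("out")
        receiver.link_derivation(sc, ei)
        store = ChainStore()
        store.register("https://b.example/prov", finalize(receiver))
        result = trace_backward(
            store, "https://b.example/prov", receiver.bundle_id, sc
        )
        assert result.hop_kinds() == {"internal", "missing"}
        assert [c for _, c, _ in result.frontier] == [shared]

    def test_forward_fallback_by_global_connector_search(self):
        """A sender without destination attributes is resolvable forward only
        through the opt-in shared-identifier search."""
        sender_ns = "https://a.example/ns#"
        sender = start_bundle(sender_ns, "a", "proc")
        sc = sender.record_output("obj")  # never learned where it went
        receiver = start_bundle("https://b.example/ns#", "b", "proc")
        receiver.record_receipt(sc, make_qualified_id("a", sender_ns, "agent/a"))
        store = ChainStore()
        store.register("https://a.example/prov", finalize(sender))
        store.register("https://b.example/prov", finalize(receiver))
        plain = trace_forward(store, "https://a.example/prov", sender.bundle_id, sc)
        assert plain.bundles() == {sender.bundle_id}
        searched = trace_forward(
            store, "https://a.example/prov", sender.bundle_id, sc,
            TraceOptions(connector_search=True),
        )
        assert receiver.bundle_id in searched.bundles()

    def test_cyclic_exchange_terminates(self):
        """An object sent back and forth between two organizations must not
        loop the walk: the visited set closes the cycle."""
        ns_a, ns_b = "https://a.example/ns#", "https://b.example/ns#"
        svc_a, svc_b = "https://a.example/prov", "https://b.example/prov"
        a = start_bundle(ns_a, "a", "round1")
        b = start_bundle(ns_b, "b", "round2")
        agent_a = make_qualified_id("a", ns_a, "agent/a")
        agent_b = make_qualified_id("b", ns_b, "agent/b")
        sc_a = a.record_output("ping", destination_bundle_id=b.bundle_id, service_url=svc_b)
        rc_b, ei_b = b.record_receipt(
            sc_a, agent_a, destination_bundle_id=a.bundle_id, service_url=svc_a
        )
        sc_b = b.record_output("pong", destination_bundle_id=a.bundle_id, service_url=svc_a)
        b.link_derivation(sc_b, ei_b)
        rc_a, ei_a = a.record_receipt(
            sc_b, agent_b, destination_bundle_id=b.bundle_id, service_url=svc_b
        )
        a.link_derivation(sc_a, ei_a)  # the cycle: ping derives from pong
        store = ChainStore()
        store.register(svc_a, finalize(a))
        store.register(svc_b, finalize(b))
        back = trace_backward(store, svc_a, a.bundle_id, sc_a)
        forward = trace_forward(store, svc_b, b.bundle_id, ei_b)
        assert back.bundles() == {a.bundle_id, b.bundle_id}
        assert forward.bundles() == {a.bundle_id, b.bundle_id}


# ---------------------------------------------------------------------------
# Least privilege: traversal never touches domain records
# ---------------------------------------------------------------------------


def test_traversal_reads_only_backbone_records():
    store, blueprint = build_running_example(seed=4)
    log = store.start_access_log()
    testing = blueprint.steps[5]
    trace_backward(
        store, testing.service_url, testing.bundle_id,
        blueprint.external_input_id(4, 5),
    )
    acquisition = blueprint.steps[0]
    trace_forward(
        store, acquisition.service_url, acquisition.bundle_id,
        blueprint.connector_id(0, 1),
    )
    record_reads = [entry for entry in log if entry[0] == "record"]
    assert record_reads, "traversal should have materialized records"
    assert all(rec.backbone_type is not None for _, _, rec in record_reads)


def test_local_expansions_bounded_by_connector_counts(example_store, example_blueprint):
    """Per bundle, the number of length-2 expansions is at most #SC x #EI,
    independent of the attached domain payload size."""
    for step in example_blueprint.steps:
        bundle = example_store.fetch(step.service_url, step.bundle_id)
        scs = bundle.backbone_records(BackboneType.SENDER_CONNECTOR)
        eis = bundle.backbone_records(BackboneType.EXTERNAL_INPUT)
        expansions = sum(
            len({ei for ei, _ in local_inputs(bundle, sc.id)}) for sc in scs
        )
        assert expansions <= max(1, len(scs)) * max(1, len(eis))


# ---------------------------------------------------------------------------
# Oracle equivalence on randomized branched/gapped stores
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(12))
def test_trace_node_sets_equal_pasted_graph_reachability(seed):
    store, blueprint = build_random_chain(
        n_steps=9, branch_prob=0.4, gap_prob=0.3, jump_prob=0.6, seed=seed
    )
    graph_back = pasted_graph(store, "backward")
    graph_fwd = pasted_graph(store, "forward")
    for step in blueprint.steps:
        if step.index in blueprint.gaps:
            continue
        bundle = store.fetch(step.service_url, step.bundle_id)
        for rec in bundle.backbone_records(BackboneType.SENDER_CONNECTOR):
            result = trace_backward(store, step.service_url, step.bundle_id, rec.id)
            assert {e.key for e in result.entity_ids()} == reachable(
                graph_back, rec.id.key, forward=False
            )
        for rec in bundle.backbone_records(BackboneType.EXTERNAL_INPUT):
            result = trace_forward(store, step.service_url, step.bundle_id, rec.id)
            assert {e.key for e in result.entity_ids()} == reachable(
                graph_fwd, rec.id.key, forward=True
            )
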