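"""Navigation through distributed provenance chains.

Within one bundle, the question "which traceable inputs affected this
output" is answered by finding directed length-2 ``wasDerivedFrom`` paths:
``senderConnector → externalInput → (receiverConnector | jumpBackward)``.
That is the whole local algorithm — its cost is bounded by the number of
documented inputs and outputs, never by the size of the attached domain
provenance, which is not read at all.

Across bundles, the connector reached at the end of a local path carries
destination attributes (bundle id, service URL): the destination bundle is
fetched, the shared identifier (or, for jump connectors, the referenced
entity) is matched inside it, and the same local algorithm repeats. A
visited set over (bundle, entity) guarantees termination on cyclic
exchanges. Every degradation is data, not an exception: a connector with no
destination, an unreachable bundle, or an unmatched shared id produces a
``missing`` hop that terminates that branch; a destination that has newer
versions produces a ``version-redirect`` hop (and, when requested, the walk
continues on the latest version).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Set, Tuple

from .builder import connector_view
from .errors import BackboneTypeError, StartMissingError
from .identifiers import QualifiedId
from .model import BackboneType, RelationKind
from .store import MISSING, ChainStore

#: Hop kinds appearing in a trace.
HOP_INTERNAL = "internal"
HOP_CROSS = "cross"
HOP_JUMP = "jump"
HOP_MISSING = "missing"
HOP_VERSION = "version-redirect"

_BACKWARD_ORIGIN_TYPES = (
    BackboneType.RECEIVER_CONNECTOR,
    BackboneType.JUMP_BACKWARD_CONNECTOR,
)


@dataclass(frozen=True)
class TraceOptions:
    """Traversal policy.

    ``use_jumps`` enables jump-connector bridging; ``follow_versions``
    switches from reproducing the chain as referenced (the default: newer
    versions are only *reported*) to walking the latest version;
    ``connector_search`` allows the global shared-identifier lookup as a
    forward-navigation fallback when a senderConnector has no destination
    attributes; ``max_depth`` bounds the number of cross-bundle hops.
    """

    use_jumps: bool = True
    follow_versions: bool = False
    max_depth: Optional[int] = None
    connector_search: bool = False


Node = Tuple[QualifiedId, QualifiedId]  # (bundle_id, entity_id)


@dataclass(frozen=True)
class Hop:
    kind: str
    source: Optional[Node]
    target: Optional[Node]
    connector_id: Optional[QualifiedId] = None
    note: str = ""


@dataclass
class TraceResult:
    """Cross-bundle trace graph."""

    nodes: Set[Node] = field(default_factory=set)
    edges: list = field(default_factory=list)
    #: connectors whose destination could not be resolved: (bundle_id,
    #: connector_id, reason)
    frontier: list = field(default_factory=list)

    def bundles(self) -> set:
        return {bundle_id for bundle_id, _ in self.nodes}

    def entity_ids(self) -> set:
        """Entity identifiers visited, with shared ids merged across bundles."""
        return {entity_id for _, entity_id in self.nodes}

    def hop_kinds(self) -> set:
        return {hop.kind for hop in self.edges}

    def to_node_link(self) -> dict:
        """Plain node-link dict (machine-readable CLI output)."""
        nodes = sorted(self.nodes, key=lambda n: (n[0].key, n[1].key))
        index = {node: i for i, node in enumerate(nodes)}
        return {
            "nodes": [
                {"bundle": str(b), "entity": str(e)} for b, e in nodes
            ],
            "links": [
                {
                    "kind": hop.kind,
                    "source": index.get(hop.source),
                    "target": index.get(hop.target),
                    "connector": str(hop.connector_id) if hop.connector_id else None,
                    "note": hop.note,
                }
                for hop in self.edges
            ],
            "frontier": [
                {"bundle": str(b), "connector": str(c), "reason": reason}
                for b, c, reason in self.frontier
            ],
        }


# --------------------------------------------------------------------------
# Local (single-bundle) queries
# --------------------------------------------------------------------------


def _derivation_index(bundle) -> Tuple[dict, dict]:
    forward: dict = {}   # subject -> [objects]   (derived -> source)
    reverse: dict = {}   # object  -> [subjects]
    for rel in bundle.relations:
        if rel.kind is RelationKind.WAS_DERIVED_FROM:
            forward.setdefault(rel.subject, []).append(rel.object)
            reverse.setdefault(rel.object, []).append(rel.subject)
    return forward, reverse


def _typed(bundle, rid: QualifiedId) -> Optional[BackboneType]:
    rec = bundle.record(rid)
    return rec.backbone_type if rec is not None else None


def local_inputs(bundle, sender_connector_id: QualifiedId) -> set:
    """Traceable inputs that affected one output, with their origins.

    Walks length-2 derivation paths from the senderConnector: the first hop
    reaches the externalInputs the output was derived from, the second hop
    each input's origin connector (receiverConnector or jumpBackward), or
    ``None`` for an orphan input. Returns
    ``{(external_input_id, origin_connector_id | None), ...}``; an input
    backed by both a receiver and a jump connector contributes one pair per
    route.
    """
    if _typed(bundle, sender_connector_id) is not BackboneType.SENDER_CONNECTOR:
        raise BackboneTypeError(f"{sender_connector_id} is not a senderConnector here")
    forward, _ = _derivation_index(bundle)
    result = set()
    for ei in forward.get(sender_connector_id, []):
        if _typed(bundle, ei) is not BackboneType.EXTERNAL_INPUT:
            continue
        origins = [
            o for o in forward.get(ei, []) if _typed(bundle, o) in _BACKWARD_ORIGIN_TYPES
        ]
        if origins:
            result.update((ei, o) for o in origins)
        else:
            result.add((ei, None))
    return result


def local_outputs(bundle, entity_id: QualifiedId) -> set:
    """Outputs affected by one input — the reverse of :func:`local_inputs`.

    ``entity_id`` may be an externalInput or a receiverConnector (in the
    latter case the query first steps to the externalInput derived from it).
    Returns ``{(sender_connector_id, (jump_forward_ids...)), ...}`` where the
    jump-forward tuple lists jumpForwardConnectors derived from that output.
    """
    entity_type = _typed(bundle, entity_id)
    if entity_type not in (BackboneType.EXTERNAL_INPUT, BackboneType.RECEIVER_CONNECTOR):
        raise BackboneTypeError(
            f"{entity_id} is not an input-side backbone entity here"
        )
    _, reverse = _derivation_index(bundle)
    eis = [entity_id]
    if entity_type is BackboneType.RECEIVER_CONNECTOR:
        eis = [
            s for s in reverse.get(entity_id, [])
            if _typed(bundle, s) is BackboneType.EXTERNAL_INPUT
        ]
    result = set()
    for ei in eis:
        for sc in reverse.get(ei, []):
            if _typed(bundle, sc) is not BackboneType.SENDER_CONNECTOR:
                continue
            jumps = tuple(
                sorted(
                    j for j in reverse.get(sc, [])
                    if _typed(bundle, j) is BackboneType.JUMP_FORWARD_CONNECTOR
                )
            )
            result.add((sc, jumps))
    return result


# --------------------------------------------------------------------------
# Cross-bundle traversal
# --------------------------------------------------------------------------


class _Tracer:
    def __init__(self, store: ChainStore, options: TraceOptions, direction: str):
        self.store = store
        self.options = options
        self.direction = direction  # "backward" | "forward"
        self.result = TraceResult()
        self.visited: set = set()

    # -- bookkeeping -------------------------------------------------------

    def _touch(self, bundle, bundle_id, entity_id) -> Node:
        node = (bundle_id, entity_id)
        self.result.nodes.add(node)
        rec = bundle.record(entity_id) if bundle is not None else None
        if rec is not None:
            self.store.note_record_access(bundle_id, rec)
        return node

    def _seen(self, bundle_id, entity_id) -> bool:
        key = (bundle_id.key, entity_id.key)
        if key in self.visited:
            return True
        self.visited.add(key)
        return False

    def _missing(self, source: Node, connector_id, reason: str):
        self.result.edges.append(
            Hop(HOP_MISSING, source, None, connector_id=connector_id, note=reason)
        )
        self.result.frontier.append((source[0], connector_id, reason))

    # -- destination resolution (shared by both directions) ----------------

    def _fetch_destination(self, source: Node, view):
        """Fetch a connector's destination bundle, handling versions.

        Returns ``(service_url, bundle_id, bundle)`` or None after emitting
        the appropriate missing hop.
        """
        dest_id = view.destination_bundle_id
        url = view.service_url
        if dest_id is None or not url:
            self._missing(source, view.id, "no destination attributes")
            return None
        bundle = self.store.fetch(url, dest_id, view.destination_bundle_digest)
        if bundle is MISSING:
            # The named service cannot serve it; try a global lookup and
            # flag the discrepancy rather than failing the branch outright.
            found = self.store.find_bundle(dest_id)
            if found is None:
                self._missing(source, view.id, f"bundle {dest_id} not retrievable")
                return None
            url, bundle = found
        # Version awareness: report newer versions; follow them on request.
        meta = self.store.meta_of(url)
        if meta is not None and meta.has(dest_id):
            from .versioning import latest

            head = latest(meta, dest_id)
            if head != dest_id:
                self.result.edges.append(
                    Hop(
                        HOP_VERSION,
                        source,
                        None,
                        connector_id=view.id,
                        note=f"newer version {head} of {dest_id} exists",
                    )
                )
                if self.options.follow_versions:
                    newer = self.store.fetch(url, head)
                    if newer is not MISSING:
                        return url, head, newer
        return url, dest_id, bundle

    def _depth_ok(self, depth: int) -> bool:
        return self.options.max_depth is None or depth < self.options.max_depth

    # -- backward ----------------------------------------------------------

    def run_backward(self, service_url, bundle_id, bundle, entity_id):
        stack = [(service_url, bundle_id, bundle, entity_id, 0)]
        while stack:
            url, bid, b, eid, depth = stack.pop()
            if self._seen(bid, eid):
                continue
            node = self._touch(b, bid, eid)
            etype = _typed(b, eid)
            if etype is BackboneType.SENDER_CONNECTOR:
                pairs = local_inputs(b, eid)
                for ei, origin in sorted(
                    pairs, key=lambda p: (p[0].key, p[1].key if p[1] else ("", ""))
                ):
                    ei_node = self._touch(b, bid, ei)
                    self.result.edges.append(Hop(HOP_INTERNAL, node, ei_node))
                    self._expand_origins(url, bid, b, ei, ei_node, stack, depth)
            elif etype is BackboneType.EXTERNAL_INPUT:
                self._expand_origins(url, bid, b, eid, node, stack, depth)
            elif etype in _BACKWARD_ORIGIN_TYPES:
                # Starting directly at a receiver or jump connector (cross
                # arrivals resolve connectors before pushing, so only a
                # trace start lands here).
                self._resolve_backward_connector(bid, b, eid, node, stack, depth)

    def _expand_origins(self, url, bid, bundle, ei, ei_node, stack, depth):
        forward, _ = _derivation_index(bundle)
        origins = [
            o for o in forward.get(ei, []) if _typed(bundle, o) in _BACKWARD_ORIGIN_TYPES
        ]
        for origin in sorted(origins):
            otype = _typed(bundle, origin)
            if otype is BackboneType.JUMP_BACKWARD_CONNECTOR and not self.options.use_jumps:
                continue
            origin_node = self._touch(bundle, bid, origin)
            self.result.edges.append(Hop(HOP_INTERNAL, ei_node, origin_node))
            if self._seen(bid, origin):
                continue
            self._resolve_backward_connector(bid, bundle, origin, origin_node, stack, depth)

    def _resolve_backward_connector(self, bid, bundle, origin, origin_node, stack, depth):
        otype = _typed(bundle, origin)
        if not self._depth_ok(depth):
            self.result.frontier.append((bid, origin, "max depth reached"))
            return
        view = connector_view(bundle.record(origin))
        dest = self._fetch_destination(origin_node, view)
        if dest is None:
            return
        dest_url, dest_id, dest_bundle = dest
        if otype is BackboneType.RECEIVER_CONNECTOR:
            # The shared identifier names the sender's connector.
            target = dest_bundle.record(origin)
            if target is None or target.backbone_type is not BackboneType.SENDER_CONNECTOR:
                self._missing(
                    origin_node, origin,
                    f"shared id not found as senderConnector in {dest_id}",
                )
                return
            target_node = self._touch(dest_bundle, dest_id, target.id)
            self.result.edges.append(
                Hop(HOP_CROSS, origin_node, target_node, connector_id=origin)
            )
            stack.append((dest_url, dest_id, dest_bundle, target.id, depth + 1))
        else:  # jump backward
            ref = view.referenced_entity_id
            target = dest_bundle.record(ref) if ref is not None else None
            if target is None or target.backbone_type not in (
                BackboneType.SENDER_CONNECTOR,
                BackboneType.EXTERNAL_INPUT,
            ):
                self._missing(
                    origin_node, origin,
                    f"referenced entity {ref} not found in {dest_id}",
                )
                return
            target_node = self._touch(dest_bundle, dest_id, target.id)
            self.result.edges.append(
                Hop(HOP_JUMP, origin_node, target_node, connector_id=origin)
            )
            stack.append((dest_url, dest_id, dest_bundle, target.id, depth + 1))

    # -- forward -----------------------------------------------------------

    def run_forward(self, service_url, bundle_id, bundle, entity_id):
        stack = [(service_url, bundle_id, bundle, entity_id, 0)]
        while stack:
            url, bid, b, eid, depth = stack.pop()
            if self._seen(bid, eid):
                continue
            node = self._touch(b, bid, eid)
            etype = _typed(b, eid)
            _, reverse = _derivation_index(b)
            if etype is BackboneType.RECEIVER_CONNECTOR:
                for ei in sorted(
                    s for s in reverse.get(eid, [])
                    if _typed(b, s) is BackboneType.EXTERNAL_INPUT
                ):
                    ei_node = self._touch(b, bid, ei)
                    self.result.edges.append(Hop(HOP_INTERNAL, node, ei_node))
                    stack.append((url, bid, b, ei, depth))
            elif etype is BackboneType.EXTERNAL_INPUT:
                for sc in sorted(
                    s for s in reverse.get(eid, [])
                    if _typed(b, s) is BackboneType.SENDER_CONNECTOR
                ):
                    sc_node = self._touch(b, bid, sc)
                    self.result.edges.append(Hop(HOP_INTERNAL, node, sc_node))
                    stack.append((url, bid, b, sc, depth))
            elif etype is BackboneType.SENDER_CONNECTOR:
                if self.options.use_jumps:
                    for jf in sorted(
                        s for s in reverse.get(eid, [])
                        if _typed(b, s) is BackboneType.JUMP_FORWARD_CONNECTOR
                    ):
                        jf_node = self._touch(b, bid, jf)
                        self.result.edges.append(Hop(HOP_INTERNAL, node, jf_node))
                        self._resolve_jump_forward(url, bid, b, jf, jf_node, stack, depth)
                self._resolve_sender_forward(url, bid, b, eid, node, stack, depth)

    def _resolve_sender_forward(self, url, bid, bundle, sc, sc_node, stack, depth):
        if not self._depth_ok(depth):
            self.result.frontier.append((bid, sc, "max depth reached"))
            return
        view = connector_view(bundle.record(sc))
        if view.destination_bundle_id is None or not view.service_url:
            if self.options.connector_search:
                hits = [
                    (svc, b_id)
                    for svc, b_id, kind in self.store.find_by_connector(sc)
                    if kind is BackboneType.RECEIVER_CONNECTOR
                ]
                for svc, dest_id in sorted(hits, key=lambda h: (h[0], h[1].key)):
                    dest_bundle = self.store.fetch(svc, dest_id)
                    if dest_bundle is MISSING:
                        continue
                    target_node = self._touch(dest_bundle, dest_id, sc)
                    self.result.edges.append(
                        Hop(HOP_CROSS, sc_node, target_node, connector_id=sc,
                            note="resolved by global connector search")
                    )
                    stack.append((svc, dest_id, dest_bundle, sc, depth + 1))
                if not hits:
                    self._missing(sc_node, sc, "no destination attributes, no match")
            else:
                self._missing(sc_node, sc, "no destination attributes")
            return
        dest = self._fetch_destination(sc_node, view)
        if dest is None:
            return
        dest_url, dest_id, dest_bundle = dest
        target = dest_bundle.record(sc)
        if target is None or target.backbone_type is not BackboneType.RECEIVER_CONNECTOR:
            self._missing(
                sc_node, sc, f"shared id not found as receiverConnector in {dest_id}"
            )
            return
        target_node = self._touch(dest_bundle, dest_id, target.id)
        self.result.edges.append(Hop(HOP_CROSS, sc_node, target_node, connector_id=sc))
        stack.append((dest_url, dest_id, dest_bundle, target.id, depth + 1))

    def _resolve_jump_forward(self, url, bid, bundle, jf, jf_node, stack, depth):
        if self._seen(bid, jf):
            return
        if not self._depth_ok(depth):
            self.result.frontier.append((bid, jf, "max depth reached"))
            return
        view = connector_view(bundle.record(jf))
        dest = self._fetch_destination(jf_node, view)
        if dest is None:
            return
        dest_url, dest_id, dest_bundle = dest
        ref = view.referenced_entity_id
        target = dest_bundle.record(ref) if ref is not None else None
        if target is None or target.backbone_type not in (
            BackboneType.EXTERNAL_INPUT,
            BackboneType.RECEIVER_CONNECTOR,
        ):
            self._missing(jf_node, jf, f"referenced entity {ref} not found in {dest_id}")
            return
        target_node = self._touch(dest_bundle, dest_id, target.id)
        self.result.edges.append(Hop(HOP_JUMP, jf_node, target_node, connector_id=jf))
        stack.append((dest_url, dest_id, dest_bundle, target.id, depth + 1))


def _resolve_start(store, service_url, bundle_id, entity_id, wanted_types):
    bundle = store.fetch(service_url, bundle_id)
    if bundle is MISSING:
        found = store.find_bundle(bundle_id)
        if found is None:
            raise StartMissingError(f"start bundle {bundle_id} not found")
        service_url, bundle = found
    rec = bundle.record(entity_id)
    if rec is None:
        raise StartMissingError(f"{entity_id} not present in {bundle_id}")
    if rec.backbone_type is None:
        # A domain entity: climb its specialization link to the backbone.
        for rel in bundle.relations:
            if rel.kind is RelationKind.SPECIALIZATION_OF and rel.subject == entity_id:
                general = bundle.record(rel.object)
                if general is not None and general.backbone_type in wanted_types:
                    return service_url, bundle, general.id
        raise BackboneTypeError(
            f"{entity_id} is a domain entity with no backbone specialization"
        )
    if rec.backbone_type not in wanted_types:
        raise BackboneTypeError(
            f"{entity_id} is a {rec.backbone_type.value}; expected one of "
            f"{[t.value for t in wanted_types]}"
        )
    return service_url, bundle, entity_id


def trace_backward(
    store: ChainStore,
    service_url: str,
    bundle_id: QualifiedId,
    output_id: QualifiedId,
    options: TraceOptions = TraceOptions(),
) -> TraceResult:
    """All traceable inputs, across the whole chain, for one output.

    ``output_id`` normally resolves to a senderConnector in the start bundle
    (a domain entity is accepted and resolved through its specialization
    link). A chain-end bundle has no outputs, so input-side starts
    (externalInput / receiverConnector) are accepted too and the walk begins
    at the second hop. Raises :class:`StartMissingError` only when the start
    itself cannot be fetched; every other failure is encoded in the result.
    """
    service_url, bundle, start = _resolve_start(
        store,
        service_url,
        bundle_id,
        output_id,
        (
            BackboneType.SENDER_CONNECTOR,
            BackboneType.EXTERNAL_INPUT,
            BackboneType.RECEIVER_CONNECTOR,
            BackboneType.JUMP_BACKWARD_CONNECTOR,
        ),
    )
    tracer = _Tracer(store, options, "backward")
    tracer.run_backward(service_url, bundle.bundle_id, bundle, start)
    return tracer.result


def trace_forward(
    store: ChainStore,
    service_url: str,
    bundle_id: QualifiedId,
    input_id: QualifiedId,
    options: TraceOptions = TraceOptions(),
) -> TraceResult:
    """All outputs, across the whole chain, affected by one input.

    ``input_id`` normally resolves to an externalInput or receiverConnector;
    a senderConnector start is accepted for chain-start bundles, which have
    no input side.
    """
    service_url, bundle, start = _resolve_start(
        store,
        service_url,
        bundle_id,
        input_id,
        (
            BackboneType.EXTERNAL_INPUT,
            BackboneType.RECEIVER_CONNECTOR,
            BackboneType.SENDER_CONNECTOR,
        ),
    )
    tracer = _Tracer(store, options, "forward")
    tracer.run_forward(service_url, bundle.bundle_id, bundle, start)
    return tracer.result
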