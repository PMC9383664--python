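"""Independent oracles for property tests.

Everything here deliberately avoids the package's model classes: bundles are
re-read from their serialized PROV-JSON bytes with the plain ``json`` module
and interpreted with separately written logic (networkx graph reachability,
per-rule structural scans), so agreement with the implementation is a real
two-route check.
"""

from __future__ import annotations

import json
from collections import Counter

import networkx as nx

BB_NS = "https://w3id.org/distributed-provenance/backbone#"
ENTITY_BB = {
    "senderConnector",
    "receiverConnector",
    "jumpForwardConnector",
    "jumpBackwardConnector",
    "externalInput",
}
CONNECTOR_BB = ENTITY_BB - {"externalInput"}


def parse_doc(data: bytes):
    """(prefix_map, bundle_qname, sections) from PROV-JSON bytes."""
    doc = json.loads(data.decode("utf-8"))
    prefixes = doc.get("prefix", {})
    (bundle_qname, sections), = doc["bundle"].items()
    return prefixes, bundle_qname, sections


def expand(qname: str, prefixes: dict):
    prefix, local = qname.split(":", 1)
    return prefixes[prefix], local


def _type_values(body, prefixes):
    raw = body.get("prov:type", [])
    if not isinstance(raw, list):
        raw = [raw]
    out = []
    for item in raw:
        if isinstance(item, dict) and item.get("type") == "prov:QUALIFIED_NAME":
            ns, local = expand(item["$"], prefixes)
            out.append((ns, local))
    return out


def backbone_types(data: bytes) -> dict:
    """(ns, local) entity/activity/agent key → backbone type name."""
    prefixes, _, sections = parse_doc(data)
    typed = {}
    for section in ("entity", "activity", "agent"):
        for qname, body in sections.get(section, {}).items():
            for ns, local in _type_values(body or {}, prefixes):
                if ns == BB_NS:
                    typed[expand(qname, prefixes)] = local
    return typed


def _attr_qnames(body, key_qname, prefixes):
    raw = body.get(key_qname, [])
    if not isinstance(raw, list):
        raw = [raw]
    out = []
    for item in raw:
        if isinstance(item, dict) and item.get("type") == "prov:QUALIFIED_NAME":
            out.append(expand(item["$"], prefixes))
    return out


def _bb_attr_key(prefixes, local):
    """The serialized qname of a backbone-namespace attribute key."""
    for prefix, ns in prefixes.items():
        if ns == BB_NS:
            return f"{prefix}:{local}"
    return f"__absent__:{local}"


def pasted_graph(store, direction: str, use_jumps: bool = True) -> nx.DiGraph:
    """Merge every registered bundle on shared identifiers.

    Nodes are (namespace, local) entity keys restricted to backbone-typed
    entities; edges follow the derivation direction (derived → source):
    intra-bundle ``wasDerivedFrom`` statements plus, for jump connectors,
    the edge implied by their referenced-entity attribute (jumpBackward →
    referenced; referenced → jumpForward). Only the jump kind navigable in
    ``direction`` is pasted: a backward walk can follow a jumpBackward held
    in its own bundle, but a jumpForward lives in another organization's
    bundle and is undiscoverable backward (and symmetrically forward).
    """
    from provbackbone.model import serialize_bundle

    assert direction in ("backward", "forward")
    wanted_jump = (
        "jumpBackwardConnector" if direction == "backward" else "jumpForwardConnector"
    )
    graph = nx.DiGraph()
    jump_edges = []
    for url in store.services():
        for bundle in store._services[url].bundles.values():
            data = serialize_bundle(bundle)
            prefixes, _, sections = parse_doc(data)
            typed = backbone_types(data)
            entity_typed = {k: v for k, v in typed.items() if v in ENTITY_BB}
            entity_typed = {
                k: v
                for k, v in entity_typed.items()
                if not v.startswith("jump") or (use_jumps and v == wanted_jump)
            }
            graph.add_nodes_from(entity_typed)
            for body in sections.get("wasDerivedFrom", {}).values():
                subj = expand(body["prov:generatedEntity"], prefixes)
                obj = expand(body["prov:usedEntity"], prefixes)
                if subj in entity_typed and obj in entity_typed:
                    graph.add_edge(subj, obj)
            ref_key = _bb_attr_key(prefixes, "referencedEntity")
            for qname, body in sections.get("entity", {}).items():
                key = expand(qname, prefixes)
                kind = entity_typed.get(key)
                if kind not in ("jumpBackwardConnector", "jumpForwardConnector"):
                    continue
                for ref in _attr_qnames(body or {}, ref_key, prefixes):
                    if kind == "jumpBackwardConnector":
                        jump_edges.append((key, ref))
                    else:
                        jump_edges.append((ref, key))
    # A jump edge pastes only onto entities that exist in some registered
    # bundle — a jump into a missing bundle resolves nowhere.
    for src, dst in jump_edges:
        if src in graph and dst in graph:
            graph.add_edge(src, dst)
    return graph


def reachable(graph: nx.DiGraph, start, forward: bool) -> set:
    """Backward trace = descendants along derivation edges; forward = ancestors."""
    if start not in graph:
        return {start}
    related = nx.descendants(graph, start) if not forward else nx.ancestors(graph, start)
    return related | {start}


# ---------------------------------------------------------------------------
# Independent re-check of validator rule set R, over serialized PROV-JSON
# ---------------------------------------------------------------------------


def violated_rules(data: bytes) -> set:
    """Rule codes violated by a bundle document (re-derived from scratch)."""
    prefixes, _, sections = parse_doc(data)
    typed = backbone_types(data)
    entities = sections.get("entity", {})
    bad = set()

    def t(qname):
        return typed.get(expand(qname, prefixes))

    # R1
    mains = [k for k, v in typed.items() if v == "mainActivity"]
    if len(mains) > 1:
        bad.add("R1")

    # R2: receipts per (RC, EI) pair
    used = [
        (b["prov:activity"], b["prov:entity"])
        for b in sections.get("used", {}).values()
    ]
    gen = [
        (b["prov:entity"], b["prov:activity"])
        for b in sections.get("wasGeneratedBy", {}).values()
    ]
    pair_counter = Counter()
    for receipt in (k for k, v in typed.items() if v == "receiptActivity"):
        for act, rc in used:
            if expand(act, prefixes) != receipt or t(rc) != "receiverConnector":
                continue
            for ei, act2 in gen:
                if expand(act2, prefixes) == receipt and t(ei) == "externalInput":
                    pair_counter[(expand(rc, prefixes), expand(ei, prefixes))] += 1
    if any(n > 1 for n in pair_counter.values()):
        bad.add("R2")

    dest_key = _bb_attr_key(prefixes, "destinationBundle")
    ref_key = _bb_attr_key(prefixes, "referencedEntity")
    url_key = _bb_attr_key(prefixes, "serviceUrl")

    for qname, body in entities.items():
        kind = typed.get(expand(qname, prefixes))
        if kind not in CONNECTOR_BB:
            continue
        body = body or {}
        # R3
        if len(_attr_qnames(body, dest_key, prefixes)) > 1:
            bad.add("R3")
        # R6
        if kind.startswith("jump"):
            url_raw = body.get(url_key)
            if (
                not _attr_qnames(body, dest_key, prefixes)
                or not _attr_qnames(body, ref_key, prefixes)
                or not url_raw
            ):
                bad.add("R6")

    derivations = [
        (b["prov:generatedEntity"], b["prov:usedEntity"])
        for b in sections.get("wasDerivedFrom", {}).values()
    ]

    # R4: receipt-generated inputs derive from exactly one RC
    receipt_generated = {
        expand(ei, prefixes)
        for ei, act in gen
        if t(act) == "receiptActivity" and t(ei) == "externalInput"
    }
    for ei_key in receipt_generated:
        n_rc = sum(
            1
            for subj, obj in derivations
            if expand(subj, prefixes) == ei_key and t(obj) == "receiverConnector"
        )
        if n_rc != 1:
            bad.add("R4")

    # R5: every SC generated by a mainActivity-typed activity
    main_set = set(mains)
    for qname in entities:
        if t(qname) != "senderConnector":
            continue
        gens = {
            expand(act, prefixes)
            for ent, act in gen
            if expand(ent, prefixes) == expand(qname, prefixes)
        }
        if not (main_set & gens):
            bad.add("R5")

    # R7: backbone derivations follow the four allowed type pairs
    allowed = {
        ("senderConnector", "externalInput"),
        ("externalInput", "receiverConnector"),
        ("externalInput", "jumpBackwardConnector"),
        ("jumpForwardConnector", "senderConnector"),
    }
    for subj, obj in derivations:
        ts, to = t(subj), t(obj)
        if ts in ENTITY_BB and to in ENTITY_BB and (ts, to) not in allowed:
            bad.add("R7")

    # R8: attribution direction
    for body in sections.get("wasAttributedTo", {}).values():
        ts, to = t(body["prov:entity"]), t(body["prov:agent"])
        if ts == "receiverConnector" and to != "senderAgent":
            bad.add("R8")
        if ts == "senderConnector" and to != "receiverAgent":
            bad.add("R8")

    # R9: only specializationOf crosses the backbone/domain boundary
    role_pairs = {
        "used": ("prov:activity", "prov:entity"),
        "wasGeneratedBy": ("prov:entity", "prov:activity"),
        "wasInvalidatedBy": ("prov:entity", "prov:activity"),
        "wasDerivedFrom": ("prov:generatedEntity", "prov:usedEntity"),
        "wasAttributedTo": ("prov:entity", "prov:agent"),
    }
    for section, (sr, orr) in role_pairs.items():
        for body in sections.get(section, {}).values():
            ts, to = t(body[sr]), t(body[orr])
            if (ts is None) != (to is None):
                bad.add("R9")

    return bad
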