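"""Seeded generators of random backbone bundles for property tests."""

from __future__ import annotations

import random

from provbackbone import attach_domain_process, make_qualified_id, start_bundle


def ext_connector(i: int, obj: str):
    return make_qualified_id(f"ext{i}", f"https://ext{i}.example/ns#", f"connector/{obj}")


def ext_agent(i: int):
    return make_qualified_id(f"ext{i}", f"https://ext{i}.example/ns#", f"agent/org{i}")


def random_backbone(rng: random.Random, *, org_index: int = 0,
                    with_payload: bool = False):
    """A random valid bundle builder: receipts, orphans, outputs, links, jumps.

    Exercises every builder operation with randomized multiplicities; the
    result is valid by construction.
    """
    ns = f"https://org{org_index}.example/ns#"
    builder = start_bundle(ns, f"org{org_index}", f"proc{rng.randrange(10_000)}")

    eis = []
    for i in range(rng.randint(0, 4)):
        kwargs = {}
        if rng.random() < 0.7:
            kwargs = dict(
                destination_bundle_id=make_qualified_id(
                    f"ext{i}", f"https://ext{i}.example/ns#", f"bundle/prev{i}"
                ),
                service_url=f"https://ext{i}.example/prov",
            )
        _, ei = builder.record_receipt(ext_connector(i, f"obj{i}"), ext_agent(i), **kwargs)
        eis.append(ei)
    for i in range(rng.randint(0, 2)):
        eis.append(builder.record_external_input(f"orphan{i}"))

    scs = []
    for i in range(rng.randint(0, 3)):
        receiver = ext_agent(10 + i) if rng.random() < 0.5 else None
        scs.append(
            builder.record_output(
                f"out{i}",
                receiver_agent_id=receiver,
                destination_bundle_id=make_qualified_id(
                    "next", "https://next.example/ns#", f"bundle/next{i}"
                )
                if rng.random() < 0.7
                else None,
                service_url=f"https://next.example/prov" if rng.random() < 0.7 else None,
            )
        )

    for sc in scs:
        for ei in eis:
            if rng.random() < 0.6:
                builder.link_derivation(sc, ei)

    if eis and rng.random() < 0.4:
        builder.add_jump_backward(
            rng.choice(eis),
            make_qualified_id("far", "https://far.example/ns#", "connector/far-back"),
            destination_bundle_id=make_qualified_id(
                "far", "https://far.example/ns#", "bundle/far"
            ),
            service_url="https://far.example/prov",
            referenced_entity_id=make_qualified_id(
                "far", "https://far.example/ns#", "connector/far-obj"
            ),
        )
    if scs and rng.random() < 0.4:
        builder.add_jump_forward(
            rng.choice(scs),
            make_qualified_id(builder.org_prefix, ns, "connector/far-forward"),
            destination_bundle_id=make_qualified_id(
                "fut", "https://future.example/ns#", "bundle/future"
            ),
            service_url="https://future.example/prov",
            referenced_entity_id=make_qualified_id(
                "fut", "https://future.example/ns#", "input/future-obj"
            ),
        )

    if with_payload and rng.random() < 0.7:
        mk = lambda local: make_qualified_id(builder.org_prefix, ns, local)  # noqa: E731
        n = rng.randint(1, 3)
        specs = []
        prev = mk("domain/p0")
        for i in range(n):
            nxt = mk(f"domain/p{i + 1}")
            specs.append((mk(f"domain/a{i + 1}"), (prev,), (nxt,)))
            prev = nxt
        attach_domain_process(
            builder,
            builder.main_activity_id,
            specs,
            input_backbone_id=rng.choice(eis) if eis else None,
            output_backbone_id=rng.choice(scs) if scs else None,
        )
    return builder
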