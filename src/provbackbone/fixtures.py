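"""Deterministic chain generators with machine-readable ground truth.

Two substrates:

* :func:`build_running_example` — the six-step digital-pathology pipeline
  used throughout the package's documentation: specimen acquisition →
  pre-analytics/diagnostics → {biobanking | WSI preprocessing → AI model
  training → AI model testing}, spread over a hospital, a biobank and a
  data-science institute. Each pipeline step is run by its own department
  (own namespace and prefix) hosted at its organization's service. The
  AI-training bundle carries a jumpBackwardConnector straight to the
  acquisition bundle, so the origin of the training data can be confirmed
  even if intermediate provenance goes missing.

* :func:`build_random_chain` — randomized branched chains with optional
  gaps (bundles built, wired, then dropped from their service) and jump
  links bridging every length-2 step path when ``jump_prob`` fires. The
  returned :class:`ChainBlueprint` alone determines the store content and
  carries step-level reachability ground truth for oracle tests.

Domain payloads are synthetic compound-activity chains (2–5 sub-activities
with checksum-like attribute strings) standing in for the real WSI hashes,
git references and training-epoch records; nothing domain-specific is
reproduced. Generation is a pure function of (blueprint, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Tuple

from .attachment import attach_domain_process
from .builder import BundleBuilder, start_bundle
from .finalization import finalize
from .identifiers import QualifiedId, make_qualified_id
from .store import ChainStore


@dataclass(frozen=True)
class StepInfo:
    index: int
    name: str
    prefix: str
    namespace: str
    service_url: str
    bundle_id: QualifiedId
    parents: Tuple[int, ...]
    children: Tuple[int, ...]


@dataclass(frozen=True)
class ChainBlueprint:
    """Topology, gaps, and jump links of a generated chain.

    ``jumps`` holds ``(grandparent, parent, child)`` step triples: the child
    bundle carries a jumpBackwardConnector to the grandparent and the
    grandparent a jumpForwardConnector to the child, bridging the parent.
    Reachability ground truth is derivable from the blueprint alone (every
    output is linked to every input of its bundle).
    """

    steps: Tuple[StepInfo, ...]
    gaps: frozenset
    jumps: Tuple[Tuple[int, int, int], ...]
    seed: int

    def step(self, index: int) -> StepInfo:
        return self.steps[index]

    def edges(self) -> list:
        return [(p, s.index) for s in self.steps for p in s.parents]

    def connector_id(self, parent: int, child: int) -> QualifiedId:
        p = self.steps[parent]
        return make_qualified_id(
            p.prefix, p.namespace, f"connector/{_object_name(self, parent, child)}"
        )

    def external_input_id(self, parent: int, child: int) -> QualifiedId:
        p, c = self.steps[parent], self.steps[child]
        return make_qualified_id(
            c.prefix, c.namespace, f"input/{p.prefix}-{_object_name(self, parent, child)}"
        )

    # -- step-level reachability ground truth ------------------------------

    def backward_reachable_steps(self, start: int, use_jumps: bool = True) -> set:
        """Steps whose bundles a backward trace from ``start`` can enter."""
        reached = {start}
        frontier = [start]
        while frontier:
            s = frontier.pop()
            for p in self.steps[s].parents:
                if p not in self.gaps and p not in reached:
                    reached.add(p)
                    frontier.append(p)
            if use_jumps:
                for g, _, c in self.jumps:
                    if c == s and g not in self.gaps and g not in reached:
                        reached.add(g)
                        frontier.append(g)
        return reached

    def forward_reachable_steps(self, start: int, use_jumps: bool = True) -> set:
        reached = {start}
        frontier = [start]
        while frontier:
            s = frontier.pop()
            for c in self.steps[s].children:
                if c not in self.gaps and c not in reached:
                    reached.add(c)
                    frontier.append(c)
            if use_jumps:
                for g, _, c in self.jumps:
                    if g == s and c not in self.gaps and c not in reached:
                        reached.add(c)
                        frontier.append(c)
        return reached


def _object_name(blueprint: ChainBlueprint, parent: int, child: int) -> str:
    return f"obj-{blueprint.steps[parent].name}-{blueprint.steps[child].name}"


def _agent_id(step: StepInfo, role: str) -> QualifiedId:
    return make_qualified_id(step.prefix, step.namespace, f"agent/{step.name}-{role}")


def _attach_payload(builder: BundleBuilder, step: StepInfo, rng: random.Random,
                    input_backbone=None, output_backbone=None) -> None:
    """Synthetic compound-activity domain payload (2–5 sub-activities)."""
    n_sub = rng.randint(2, 5)
    mk = lambda local: make_qualified_id(step.prefix, step.namespace, local)  # noqa: E731
    specs = []
    prev = mk(f"domain/{step.name}/product0")
    for i in range(n_sub):
        act = mk(f"domain/{step.name}/subactivity{i + 1}")
        nxt = mk(f"domain/{step.name}/product{i + 1}")
        specs.append((act, (prev,), (nxt,)))
        prev = nxt
    attach_domain_process(
        builder,
        builder.main_activity_id,
        specs,
        input_backbone_id=input_backbone,
        output_backbone_id=output_backbone,
    )
    checksum_key = mk("checksum")
    for act, _, produced in specs:
        builder.add_attribute(produced[0], checksum_key, f"{rng.getrandbits(64):016x}")


def _payload_rng(seed: int, tag: str) -> random.Random:
    return random.Random(f"{seed}/{tag}")


def _build_step_bundle(blueprint: ChainBlueprint, step: StepInfo) -> BundleBuilder:
    """Assemble one step's backbone: receipts, outputs, derivations, jumps."""
    builder = start_bundle(step.namespace, step.prefix, step.name)

    ei_ids = {}
    for p in step.parents:
        sender = blueprint.steps[p]
        _, ei = builder.record_receipt(
            blueprint.connector_id(p, step.index),
            _agent_id(sender, "sender"),
            destination_bundle_id=sender.bundle_id,
            service_url=sender.service_url,
        )
        ei_ids[p] = ei

    sc_ids = {}
    for c in step.children:
        receiver = blueprint.steps[c]
        sc = builder.record_output(
            _object_name(blueprint, step.index, c),
            receiver_agent_id=_agent_id(receiver, "receiver"),
            destination_bundle_id=receiver.bundle_id,
            service_url=receiver.service_url,
        )
        sc_ids[c] = sc

    # Every documented output was affected by every documented input.
    for sc in sc_ids.values():
        for ei in ei_ids.values():
            builder.link_derivation(sc, ei)

    for g, p, c in blueprint.jumps:
        if c == step.index:
            grand = blueprint.steps[g]
            builder.add_jump_backward(
                ei_ids[p],
                make_qualified_id(
                    grand.prefix, grand.namespace,
                    f"connector/jump-{grand.name}-{blueprint.steps[p].name}-{step.name}-b",
                ),
                destination_bundle_id=grand.bundle_id,
                service_url=grand.service_url,
                referenced_entity_id=blueprint.connector_id(g, p),
            )
        if g == step.index:
            child = blueprint.steps[c]
            builder.add_jump_forward(
                sc_ids[p],
                make_qualified_id(
                    step.prefix, step.namespace,
                    f"connector/jump-{step.name}-{blueprint.steps[p].name}-{child.name}-f",
                ),
                destination_bundle_id=child.bundle_id,
                service_url=child.service_url,
                referenced_entity_id=blueprint.external_input_id(p, c),
            )

    rng = _payload_rng(blueprint.seed, step.name)
    eis = sorted(ei_ids.values())
    scs = sorted(sc_ids.values())
    _attach_payload(
        builder,
        step,
        rng,
        input_backbone=eis[0] if eis else None,
        output_backbone=scs[0] if scs else None,
    )
    return builder


def build_from_blueprint(blueprint: ChainBlueprint) -> ChainStore:
    """Materialize a store from a blueprint; pure in (blueprint, seed)."""
    store = ChainStore()
    for step in blueprint.steps:
        store.add_service(step.service_url, step.namespace, step.prefix)
        bundle = finalize(_build_step_bundle(blueprint, step))
        store.register(step.service_url, bundle)
    for gap in sorted(blueprint.gaps):
        step = blueprint.steps[gap]
        store.drop_bundle(step.service_url, step.bundle_id)
    return store


# --------------------------------------------------------------------------
# The six-step running example
# --------------------------------------------------------------------------

HOSPITAL_SERVICE = "https://hospital.example/prov"
BIOBANK_SERVICE = "https://biobank.example/prov"
INSTITUTE_SERVICE = "https://institute.example/prov"

_RUNNING_STEPS = (
    # name, prefix, namespace, service, parents
    ("acquisition", "clin", "https://hospital.example/clinic#", HOSPITAL_SERVICE, ()),
    ("preanalytics", "path", "https://hospital.example/pathology#", HOSPITAL_SERVICE, (0,)),
    ("biobanking", "bbk", "https://biobank.example/ns#", BIOBANK_SERVICE, (1,)),
    ("wsi-preprocessing", "prep", "https://institute.example/preproc#", INSTITUTE_SERVICE, (1,)),
    ("ai-training", "train", "https://institute.example/training#", INSTITUTE_SERVICE, (3,)),
    ("ai-testing", "test", "https://institute.example/testing#", INSTITUTE_SERVICE, (4,)),
)


def running_example_blueprint(seed: int = 0) -> ChainBlueprint:
    children: dict = {i: [] for i in range(len(_RUNNING_STEPS))}
    for i, (_, _, _, _, parents) in enumerate(_RUNNING_STEPS):
        for p in parents:
            children[p].append(i)
    steps = tuple(
        StepInfo(
            index=i,
            name=name,
            prefix=prefix,
            namespace=ns,
            service_url=svc,
            bundle_id=make_qualified_id(prefix, ns, f"bundle/{name}"),
            parents=tuple(parents),
            children=tuple(children[i]),
        )
        for i, (name, prefix, ns, svc, parents) in enumerate(_RUNNING_STEPS)
    )
    # The AI-training step (index 4) jump-links its dataset input back to the
    # specimen acquisition bundle (index 0), bridging steps 1–3.
    return ChainBlueprint(steps=steps, gaps=frozenset(), jumps=(), seed=seed)


def build_running_example(seed: int = 0):
    """The six-bundle digital-pathology chain across three services.

    Returns ``(store, blueprint)``. Step 1 (acquisition) is a chain start;
    biobanking and AI testing are chain ends. Besides the step-to-step
    connectors, the AI-training bundle carries a jumpBackwardConnector whose
    destination is the acquisition bundle and whose referenced entity is the
    specimen senderConnector — the "is the training data real?" shortcut.
    """
    blueprint = running_example_blueprint(seed)
    store = ChainStore()
    for step in blueprint.steps:
        store.add_service(step.service_url, step.namespace, step.prefix)
        builder = _build_step_bundle(blueprint, step)
        if step.name == "ai-training":
            acquisition = blueprint.steps[0]
            builder.add_jump_backward(
                blueprint.external_input_id(3, 4),
                make_qualified_id(
                    acquisition.prefix, acquisition.namespace,
                    "connector/specimen-jump-training",
                ),
                destination_bundle_id=acquisition.bundle_id,
                service_url=acquisition.service_url,
                referenced_entity_id=blueprint.connector_id(0, 1),
            )
        store.register(step.service_url, finalize(builder))
    return store, blueprint


# --------------------------------------------------------------------------
# Randomized chains
# --------------------------------------------------------------------------


def random_blueprint(
    n_steps: int,
    branch_prob: float = 0.3,
    gap_prob: float = 0.0,
    jump_prob: float = 0.0,
    seed: int = 0,
) -> ChainBlueprint:
    """Sample a branched chain topology, gap set, and jump links."""
    if n_steps < 1:
        raise ValueError("a chain needs at least one step")
    rng = random.Random(seed)
    parents: dict = {0: ()}
    for i in range(1, n_steps):
        base = rng.randrange(i)
        extra = {j for j in range(i) if j != base and rng.random() < branch_prob}
        parents[i] = tuple(sorted({base} | extra))
    children: dict = {i: [] for i in range(n_steps)}
    for i, ps in parents.items():
        for p in ps:
            children[p].append(i)

    steps = []
    for i in range(n_steps):
        prefix = f"org{i}"
        ns = f"https://org{i}.example/ns#"
        steps.append(
            StepInfo(
                index=i,
                name=f"step{i}",
                prefix=prefix,
                namespace=ns,
                service_url=f"https://org{i}.example/prov",
                bundle_id=make_qualified_id(prefix, ns, f"bundle/step{i}"),
                parents=parents[i],
                children=tuple(children[i]),
            )
        )

    # Gaps are sampled over interior steps but kept non-adjacent: a jump
    # connector bridges exactly one missing step, so two consecutive missing
    # bundles would make endpoint reachability impossible by construction.
    interior = [i for i in range(n_steps) if parents[i] and children[i]]
    gap_set: set = set()
    for i in interior:
        neighbours = set(parents[i]) | set(children[i])
        if neighbours & gap_set:
            continue
        if rng.random() < gap_prob:
            gap_set.add(i)
    gaps = frozenset(gap_set)

    jumps = []
    for p in range(n_steps):
        for g in parents[p]:
            for c in children[p]:
                if rng.random() < jump_prob:
                    jumps.append((g, p, c))
    return ChainBlueprint(
        steps=tuple(steps), gaps=gaps, jumps=tuple(sorted(set(jumps))), seed=seed
    )


def linear_blueprint(n_steps: int, *, jump_linked: bool = False,
                     seed: int = 0) -> ChainBlueprint:
    """A strictly linear chain 0 → 1 → … → n-1.

    With ``jump_linked`` every length-2 step path carries both jump kinds, so
    any single interior bundle can go missing without severing endpoint
    reachability.
    """
    steps = []
    for i in range(n_steps):
        prefix = f"org{i}"
        ns = f"https://org{i}.example/ns#"
        steps.append(
            StepInfo(
                index=i,
                name=f"step{i}",
                prefix=prefix,
                namespace=ns,
                service_url=f"https://org{i}.example/prov",
                bundle_id=make_qualified_id(prefix, ns, f"bundle/step{i}"),
                parents=(i - 1,) if i else (),
                children=(i + 1,) if i < n_steps - 1 else (),
            )
        )
    jumps = (
        tuple((i - 1, i, i + 1) for i in range(1, n_steps - 1)) if jump_linked else ()
    )
    return ChainBlueprint(steps=tuple(steps), gaps=frozenset(), jumps=jumps, seed=seed)


def build_random_chain(
    n_steps: Optional[int] = None,
    branch_prob: float = 0.3,
    gap_prob: float = 0.0,
    jump_prob: float = 0.0,
    seed: int = 0,
    blueprint: Optional[ChainBlueprint] = None,
):
    """Generate a random chain store, or materialize a given blueprint.

    Returns ``(store, blueprint)``. Gaps are realized by building the full
    chain — jump links included — and then dropping the gapped bundles from
    their services, exactly the situation of an organization that processed
    an object but never published provenance.
    """
    if blueprint is None:
        if n_steps is None:
            raise ValueError("pass n_steps or a blueprint")
        blueprint = random_blueprint(n_steps, branch_prob, gap_prob, jump_prob, seed)
    return build_from_blueprint(blueprint), blueprint


def drop_bundle(store: ChainStore, service_url: str, bundle_id: QualifiedId,
                *, keep_meta: bool = True) -> ChainStore:
    """Remove a bundle from its service, keeping the meta-bundle entry."""
    return store.drop_bundle(service_url, bundle_id, keep_meta=keep_meta)
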