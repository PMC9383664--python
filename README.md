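# provbackbone

A lightweight library for building, validating, finalizing, versioning and
traversing **distributed provenance chains** built on the W3C PROV data
model.

## The problem

Research objects — biological samples, imaging datasets, trained models —
pass through many organizations, and each organization can document only its
own part of the object's life cycle. To make a dataset traceable back to the
specimen it came from (and a specimen traceable forward to everything derived
from it), the per-organization provenance bundles must interconnect into a
chain that a *single* algorithm can walk, without understanding any
organization's internal vocabulary and without reading anything sensitive.

`provbackbone` implements such a scheme: every bundle contains a small,
standardized **backbone** subgraph, and everything domain-specific hangs off
it opaquely. The package is aimed at provenance tooling for multi-site
pipelines (the bundled example models a digital-pathology pipeline from
prostate-biopsy acquisition to AI tumor-detection testing), but the backbone
is domain-agnostic.

## The model

Within one PROV bundle, for a documented process *P*:

* each object received from another organization appears twice — as a
  **receiverConnector** `rc` (its state when sent, under a *shared
  identifier* minted in the sender's namespace) and as an **externalInput**
  `ei` (its state when received), wired through a **receiptActivity**:
  `used(receipt, rc)`, `wasGeneratedBy(ei, receipt)`,
  `wasInvalidatedBy(rc, receipt)`, `wasDerivedFrom(ei, rc)`;
* each object sent onward appears as a **senderConnector** `sc` generated by
  the single **mainActivity**, with `wasDerivedFrom(sc, ei)` emitted if and
  only if that output was affected by that input;
* connectors carry *destination attributes* — the identifier of the bundle
  on the other side of the exchange and the URL of the service holding it;
* **jumpBackward/jumpForward connectors** bridge non-adjacent steps so a
  missing intermediate bundle does not sever the chain.

"Which inputs affected this output?" is then the set of directed
`wasDerivedFrom` paths of length two, `sc → ei → rc`, so local query cost is
bounded by the number of documented inputs and outputs — never by the volume
of attached domain provenance. Cross-bundle navigation fetches the
destination bundle named by the connector, matches the shared identifier,
and repeats; a query cannot be forced to read domain records because those
attach to the backbone exclusively via `prov:specializationOf`.

Bundles are **finalized** — validated, canonicalized, serialized to
deterministic PROV-JSON bytes and digested with SHA-256 — and immutable
from then on. Corrections are **revisions**: a new bundle under a new
identifier, recorded in the organization's meta-bundle with a
revision-typed derivation, with every old version kept fetchable so
existing references and digests stay valid.

## Worked example

```python
from provbackbone import (
    build_running_example, classify_position, trace_backward,
)

store, chain = build_running_example(seed=1)

for step in chain.steps:
    bundle = store.fetch(step.service_url, step.bundle_id)
    label = classify_position(bundle).label.value
    print(f"{str(bundle.bundle_id):28s} {label:12s} sha256:{bundle.digest[:12]}")

testing = chain.steps[5]
trace = trace_backward(
    store, testing.service_url, testing.bundle_id,
    chain.external_input_id(4, 5),          # the trained model, as received
)
print(f"\nbackward trace visited {len(trace.bundles())} bundles, "
      f"hop kinds: {sorted(trace.hop_kinds())}")
```

prints

```
clin:bundle/acquisition      CHAIN_START  sha256:d22bdb51968d
path:bundle/preanalytics     COMPLETE     sha256:251bf807617a
bbk:bundle/biobanking        CHAIN_END    sha256:3b425c9963f2
prep:bundle/wsi-preprocessing COMPLETE     sha256:e048914dfc60
train:bundle/ai-training     COMPLETE     sha256:0675ca065617
test:bundle/ai-testing       CHAIN_END    sha256:d2cd664764f9

backward trace visited 5 bundles, hop kinds: ['cross', 'internal', 'jump']
```

Reading the output: the acquisition bundle has outputs but no external
inputs (`CHAIN_START`); biobanking and AI testing consume without forwarding
(`CHAIN_END`); each digest is the SHA-256 of the bundle's canonical
PROV-JSON bytes. The backward trace from the AI-testing input walks the
whole pipeline back to the specimen — five bundles (the biobanking branch is
not an ancestor) — crossing bundles via shared connector identifiers
(`cross`) and, from the training bundle, directly to the acquisition bundle
via its jumpBackward connector (`jump`).

The same operations are available from a shell:

```
provbackbone example --seed 1 -o store/
provbackbone validate store/https-hospital.example-prov__bundle-acquisition.provjson
provbackbone traverse --store store/ --bundle test:bundle/ai-testing \
    --entity test:input/train-obj-ai-training-ai-testing --direction back
provbackbone history --store store/ --bundle clin:bundle/acquisition
```

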