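# Methods

## Scope and model

`provbackbone` implements a provenance *backbone*: the domain-agnostic
subgraph that every bundle in a distributed provenance chain must contain so
that one traversal algorithm works across organizations. A bundle documents
exactly one process (one `mainActivity`); exchanged objects are represented
by connector entities with identifiers shared between sender and receiver;
harmonized derivation paths of length two (`senderConnector → externalInput
→ receiverConnector | jumpBackwardConnector`) encode which outputs were
affected by which inputs. The nine backbone record types map onto the three
PROV-DM base kinds: five entity types (four connector kinds plus the
external input), two activity types (main and receipt activity), two agent
types (sender- and receiver-side responsible organizations).

Assumptions the model makes about its environment:

* connector identifiers really are shared — sender and receiver agree on
  one qualified name, minted in the **sender's** namespace, before or during
  the exchange. Identity of a qualified name is `(namespace URI, local
  name)`; the prefix is a rendering convenience. Connector local names are
  kept in a reserved `connector/` path segment to avoid collisions with
  ordinary records;
* every organization finalizes its bundle at a well-defined event, after
  which the content never changes; corrections go through revisions;
* the two organizations on either side of an exchange can name each other's
  bundle and provenance service in connector attributes. When they cannot,
  the model still admits the bundle (that is precisely the
  `MISSING_BACKLINK` chain position) and traversal degrades to a reported
  missing hop.

## Derivation-path contract

The receipt operation emits exactly five relations (use, generation,
invalidation, the input-from-connector derivation, and the sender
attribution). Usage edges from the main activity to its inputs are *not*
emitted: neither the traversal algorithm nor the structural rule set
consults them, and keeping the emitted relation multiset minimal makes the
builder's output contract exact and testable. The
`externalInput wasDerivedFrom receiverConnector` edge is mandatory wiring —
without it the length-2 path query cannot terminate at a navigable
connector.

Attribution direction is a design choice the conceptual schema leaves open:
we attribute the receiverConnector to the *sending* organization's agent
(it describes the object as the sender dispatched it) and the
senderConnector to the *receiving* organization's agent (it describes the
object as handed over). The validator enforces this as rule R8; a
deployment preferring the opposite convention would need to relax that rule
only.

Receiver connectors are always invalidated by the receipt activity, even
when the physical object continues to exist — invalidation here closes the
*snapshot*, not the object.

## Validation and chain positions

`validate_backbone` reports violations of rules R0–R9 (referential
integrity; one main activity; one receipt per connector/input pair; at most
one destination bundle per connector; received inputs derive from exactly
one receiver connector; sender connectors generated by the main activity;
jump connectors fully addressed; derivations restricted to the four
backbone type pairs; attribution direction; specialization-only boundary
crossing). Validation never raises: the CLI lints third-party documents and
needs the full list, not the first failure.

Chain-position classification is by presence of backbone entity kinds, with
bundle-level precedence `COMPLETE > MISSING_BACKLINK > others` and a
per-object detail map (each input labeled `received`/`jump-linked`/`orphan`,
each output `addressed`/`unaddressed`), because real bundles mix situations
that whole-bundle labels cannot express. A bundle with no connectors and no
external inputs at all — a purely internal process — is legal but unusual;
it classifies `ISOLATED_END` and is flagged `no-exchange`.

## Finalization and digests

Finalization validates (unless an explicit `allow_invalid` lint flag is
set), freezes the builder, canonicalizes, serializes and digests. The
canonical statement order is: statement class (records, relations, opaque
pass-through), then kind, then subject, then object, then sorted attribute
pairs, with identifiers compared in expanded form — a total order, so two
statement-equal bundles have byte-identical serializations regardless of
construction order. PROV-JSON is the normative dialect for digests (the
model is serialization-agnostic; one dialect had to be fixed for hashing
and PROV-JSON is the simplest deterministic one). The digest is SHA-256
over those bytes. The algorithm name travels in the meta-bundle entry, not
inside the digested bundle, to avoid self-reference; the `finalized_at`
timestamp is metadata about the event and is excluded from the digested
bytes. Digital signatures and non-repudiation protocols are deliberately
out of scope — immutability and digests are the substrate they would sit
on.

Prefix bindings in the serialization are reconstructed deterministically
from the identifiers in use (lexicographically smallest observed prefix per
namespace, suffixed on collision), which keeps round-trips byte-identical.
PROV relations outside the modeled six (e.g. `wasAssociatedWith`) are
parsed into opaque pass-through statements and re-emitted verbatim, so
linting foreign documents does not destroy information; genuinely unknown
section names are parse errors.

## Traversal

Backward and forward traversal repeat the local length-2 query and resolve
connectors through their destination attributes: fetch the destination
bundle at the named service (falling back to a global bundle lookup, with
the discrepancy noted, if the named service cannot serve it), match the
shared identifier — for jump connectors, the explicitly referenced entity —
and continue. All degradations are data in the `TraceResult` (hop kinds
`internal`, `cross`, `jump`, `missing`, `version-redirect`; unresolved
connectors in the frontier); the only exception raised is for an
unfetchable *start*. A visited set over (bundle, entity) guarantees
termination on cyclic exchanges. `max_depth` defaults to unlimited.

Version policy: by default a trace walks the exact version a connector
names — reproducing the chain as referenced — and *reports* newer versions
as `version-redirect` hops; `follow_versions=True` switches to the latest
version. The global shared-identifier search (`connector_search`) that
resolves unaddressed sender connectors forward is off by default: it
answers a question the attribute-driven model cannot, at the cost of a
store-wide scan, and corresponds to infrastructure (registries, pingback)
the model does not presume.

Jump connectors are direction-specific by construction: a backward walk can
follow a `jumpBackwardConnector` because it sits in the bundle being
walked, but a `jumpForwardConnector` lives in the upstream organization's
bundle and is undiscoverable backward (and symmetrically forward). The
reachability oracle used in the tests pastes jump-attribute edges per
direction accordingly.

Least privilege: traversal touches only backbone-typed records. The chain
store's optional access log records every record materialization, and the
test suite asserts that a full walk of the running example reads no domain
record.

## Versioning

Each service keeps a meta-bundle: one entity per finalized bundle
(attributes: content digest, hash algorithm, finalization time) and
revision-typed `wasDerivedFrom` edges, newer → older, loosely following PAV
revision semantics without importing the ontology. Revision edges are
constrained to a forest of *linear* chains — at most one direct predecessor
**and** one direct successor per bundle. The successor constraint is
implied by the history contract (querying any member of a chain must return
one ordered list); merging two histories is rejected pending a use case.
The meta-bundle serializes as an ordinary PROV bundle so it travels with
store exports.

## Synthetic data

The running example reconstructs a six-step digital-pathology pipeline:
specimen acquisition → pre-analytics/diagnostics → {biobanking |
WSI preprocessing → AI training → AI testing}, hosted on three services
(hospital, biobank, data-science institute). Each step is modeled as its
own department with its own namespace (`clin`, `path`, `bbk`, `prep`,
`train`, `test`) grouped under its organization's service — exchanges are
inter-department, which is what gives every shared identifier a sender
namespace distinct from the receiver's. Biobanking is modeled as a chain
end (no onward connector toward future sample requests). The AI-training
bundle carries a jumpBackwardConnector pointing at the acquisition bundle's
specimen connector, the "is the training data real?" shortcut.

Domain payloads are synthetic compound-activity chains — 2–5 sub-activities
with seeded hex "checksum" attributes — standing in for real WSI file
hashes, git references and per-epoch training records. They exercise the
attachment and opaqueness machinery but carry no domain semantics, so
passing tests demonstrate the chain mechanics, not fidelity to any real
pathology workflow. Real-world features the generator does not emulate:
heterogeneous PROV emitted by third-party tools, clock skew between
organizations, partially shared identifiers, and access-control failures
(distinct from absence).

Randomized chains sample a parent DAG (`branch_prob` extra parents per
step), link every documented input to every output of a bundle (so
blueprint-level reachability is exact ground truth), optionally insert both
jump kinds on length-2 step paths (`jump_prob`), and realize gaps by
building bundles — jump links included — and then dropping them from their
service (`gap_prob`). Gaps are kept non-adjacent because a jump connector
bridges exactly one missing step; two consecutive missing bundles are
unrecoverable by construction, which is a property of the model, not of the
generator. Generation is a pure function of (blueprint, seed).

Test and acceptance problem sizes — chains of 3–12 bundles, 100 randomized
stores, 100-permutation canonicalization checks, ~120-example property
suites — were chosen so the full suite completes in a few seconds while
still covering every branching/gap/jump regime; the structures involved are
small graphs, so nothing changes qualitatively at larger scale.

## Known limitations

* Live PID resolution is out of scope; identifiers are qualified names and
  the chain store's lookup stands in for a resolver.
* No digital signatures, access control, or HTTP deployment; the chain
  store contract is in-memory with a directory exchange format, and an HTTP
  client could implement the same interface.
* Revision histories are linear; merges are rejected.
* The forward-discovery problem (who consumed my output?) is only solvable
  here via the opt-in global connector search; a deployment would need a
  registry or pingback service.
* One `mainActivity` per bundle: multi-process bundles and PROV collections
  are not modeled.
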