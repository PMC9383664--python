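"""Meta-bundles: per-organization registry of finalized bundles and revisions.

A finalized bundle is immutable, yet knowledge evolves — a destination
attribute becomes known, an error is found. The resolution is versioning by
*revision*: a corrected copy is finalized under a new identifier and the
organization's meta-bundle records a revision-typed derivation from the new
bundle to the old one. The original stays registered and fetchable forever,
because other organizations' connectors reference it by id (and possibly by
digest); deleting or editing it would sever the chain and invalidate any
hashes taken over it.

The meta-bundle is itself an ordinary PROV bundle — one entity per
finalized bundle (carrying its digest, hash algorithm and finalization
time) and revision edges expressed as ``wasDerivedFrom`` typed with a
revision type, loosely following PAV semantics. Revision edges form a
forest of linear chains: no cycles, at most one direct predecessor and one
direct successor per bundle, so every version's history is a single ordered
list however it is queried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import ForestViolationError, VersioningError
from .finalization import DIGEST_ALGORITHM
from .identifiers import QualifiedId, backbone_id
from .model import (
    PROV_TYPE,
    FinalizedBundle,
    RawBundle,
    Record,
    Relation,
    RelationKind,
)

ATTR_DIGEST = backbone_id("contentDigest")
ATTR_ALGORITHM = backbone_id("digestAlgorithm")
ATTR_FINALIZED_AT = backbone_id("finalizedAt")
REVISION_TYPE = backbone_id("Revision")
FINALIZED_TYPE = backbone_id("FinalizedBundle")


@dataclass
class MetaEntry:
    bundle_id: QualifiedId
    digest: str
    algorithm: str = DIGEST_ALGORITHM
    finalized_at: Optional[str] = None


@dataclass
class MetaBundle:
    """Registry of one organization's finalized bundles and their revisions."""

    org_namespace: str
    org_prefix: str
    entries: Dict[QualifiedId, MetaEntry] = field(default_factory=dict)
    #: revision edges, newer → older
    revisions: List[Tuple[QualifiedId, QualifiedId]] = field(default_factory=list)

    # -- queries -----------------------------------------------------------

    def has(self, bundle_id: QualifiedId) -> bool:
        return bundle_id in self.entries

    def predecessor(self, bundle_id: QualifiedId) -> Optional[QualifiedId]:
        for newer, older in self.revisions:
            if newer == bundle_id:
                return older
        return None

    def successor(self, bundle_id: QualifiedId) -> Optional[QualifiedId]:
        for newer, older in self.revisions:
            if older == bundle_id:
                return newer
        return None

    # -- serialization to an ordinary bundle -------------------------------

    def as_bundle(self) -> RawBundle:
        """The meta-bundle as a serializable PROV bundle."""
        records = []
        for entry in self.entries.values():
            attrs = [
                (PROV_TYPE, FINALIZED_TYPE),
                (ATTR_DIGEST, entry.digest),
                (ATTR_ALGORITHM, entry.algorithm),
            ]
            if entry.finalized_at is not None:
                attrs.append((ATTR_FINALIZED_AT, entry.finalized_at))
            records.append(Record(kind="entity", id=entry.bundle_id, attributes=attrs))
        relations = [
            Relation(
                kind=RelationKind.WAS_DERIVED_FROM,
                subject=newer,
                object=older,
                attributes=((PROV_TYPE, REVISION_TYPE),),
            )
            for newer, older in self.revisions
        ]
        meta_id = QualifiedId(self.org_prefix, self.org_namespace, "bundle/meta")
        return RawBundle(
            bundle_id=meta_id, records=tuple(records), relations=tuple(relations)
        )

    @classmethod
    def from_bundle(cls, bundle, org_namespace: str, org_prefix: str) -> "MetaBundle":
        meta = cls(org_namespace=org_namespace, org_prefix=org_prefix)
        for rec in bundle.records:
            if FINALIZED_TYPE not in rec.attr_values(PROV_TYPE):
                continue
            meta.entries[rec.id] = MetaEntry(
                bundle_id=rec.id,
                digest=rec.attr(ATTR_DIGEST),
                algorithm=rec.attr(ATTR_ALGORITHM) or DIGEST_ALGORITHM,
                finalized_at=rec.attr(ATTR_FINALIZED_AT),
            )
        for rel in bundle.relations:
            if rel.kind is RelationKind.WAS_DERIVED_FROM and any(
                k == PROV_TYPE and v == REVISION_TYPE for k, v in rel.attributes
            ):
                meta.revisions.append((rel.subject, rel.object))
        return meta


def register_finalized(meta: MetaBundle, bundle: FinalizedBundle) -> MetaBundle:
    """Record a finalized bundle as a meta-bundle entity.

    Raises :class:`VersioningError` on duplicate registration — finalized
    bundles are immutable, so a second registration under the same id can
    only be an attempt to overwrite.
    """
    if meta.has(bundle.bundle_id):
        raise VersioningError(f"bundle {bundle.bundle_id} is already registered")
    meta.entries[bundle.bundle_id] = MetaEntry(
        bundle_id=bundle.bundle_id,
        digest=bundle.digest,
        finalized_at=bundle.finalized_at,
    )
    return meta


def revise(meta: MetaBundle, old_bundle_id: QualifiedId,
           new_bundle: FinalizedBundle) -> MetaBundle:
    """Register ``new_bundle`` as the revision replacing ``old_bundle_id``.

    The old entry is kept — connectors referencing the old id must keep
    resolving — and a revision edge new→old is added. Rejects unknown old
    ids, duplicate new ids, same-id revisions, and any edge that would break
    the linear-forest property (a second successor, a second predecessor,
    or a cycle).
    """
    if not meta.has(old_bundle_id):
        raise VersioningError(f"cannot revise unknown bundle {old_bundle_id}")
    if new_bundle.bundle_id == old_bundle_id:
        raise VersioningError("a revision must carry a new bundle id")
    if meta.successor(old_bundle_id) is not None:
        raise ForestViolationError(
            f"{old_bundle_id} already has a revision; revise its head instead"
        )
    if meta.has(new_bundle.bundle_id):
        # Known id: either a duplicate or an attempt to create a cycle.
        if new_bundle.bundle_id in _component(meta, old_bundle_id):
            raise ForestViolationError(
                "revision edge would create a cycle in the version history"
            )
        raise VersioningError(f"bundle {new_bundle.bundle_id} is already registered")
    register_finalized(meta, new_bundle)
    meta.revisions.append((new_bundle.bundle_id, old_bundle_id))
    return meta


def _component(meta: MetaBundle, bundle_id: QualifiedId) -> list:
    """The full linear version chain containing ``bundle_id``, oldest first."""
    oldest = bundle_id
    while (prev := meta.predecessor(oldest)) is not None:
        oldest = prev
    chain = [oldest]
    while (nxt := meta.successor(chain[-1])) is not None:
        chain.append(nxt)
    return chain


def history(meta: MetaBundle, bundle_id: QualifiedId) -> list:
    """All versions in ``bundle_id``'s chain, oldest → newest.

    Querying any member of the chain — head, middle, or tail — returns the
    same list. After *k* revisions the list has length *k + 1*.
    """
    if not meta.has(bundle_id):
        raise VersioningError(f"unknown bundle {bundle_id}")
    return _component(meta, bundle_id)


def latest(meta: MetaBundle, bundle_id: QualifiedId) -> QualifiedId:
    """The newest version in ``bundle_id``'s revision chain."""
    return history(meta, bundle_id)[-1]
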