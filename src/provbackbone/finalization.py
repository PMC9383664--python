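"""The provenance finalization event.

Provenance is assembled incrementally in a builder; at a well-defined moment
(end of a process, on request) it is *finalized*: validated against the
backbone rules, canonicalized, serialized, digested, and frozen. From then
on the bundle is a fixed, immutable snapshot of the organization's
knowledge — any later change is a new version recorded through the
meta-bundle, never an in-place edit. Immutability is what keeps digests (and
any signatures layered on top of them, which are out of scope here) valid
for the lifetime of the chain.

The digest is SHA-256 over the canonical PROV-JSON bytes. The hash algorithm
name is recorded alongside the digest in the meta-bundle entry rather than
inside the digested bundle, which would be self-referential. The
``finalized_at`` timestamp describes the finalization event, not the bundle
content, and is excluded from the digested bytes.
"""

from __future__ import annotations

import hashlib
from typing import Optional

from .errors import FinalizationRefusedError
from .model import FinalizedBundle, serialize_bundle

#: Algorithm recorded in meta-bundle entries.
DIGEST_ALGORITHM = "sha256"


def compute_digest(data: bytes) -> str:
    """Hex SHA-256 of ``data``; a pure function of the bytes."""
    return hashlib.sha256(data).hexdigest()


def finalize(
    builder,
    *,
    allow_invalid: bool = False,
    finalized_at: Optional[str] = None,
) -> FinalizedBundle:
    """Freeze ``builder`` and return its immutable, digested snapshot.

    Parameters
    ----------
    builder:
        A :class:`~provbackbone.builder.BundleBuilder`. It is frozen as a
        side effect: every later mutation attempt raises.
    allow_invalid:
        Skip the backbone validation gate. Meant for lint workflows that
        want to serialize and inspect a non-conforming bundle; normal
        pipelines leave this off.
    finalized_at:
        Optional ISO-8601 timestamp of the finalization event. Stored as
        metadata only — two finalizations of equal content at different
        times carry equal digests.

    Raises
    ------
    FinalizationRefusedError
        If validation fails and ``allow_invalid`` is not set; the exception
        carries the validation report.
    """
    from .validator import validate_backbone

    report = validate_backbone(builder)
    if not report.is_valid and not allow_invalid:
        raise FinalizationRefusedError(report)
    builder.freeze()
    snapshot = builder.snapshot()
    digest = compute_digest(serialize_bundle(snapshot))
    return FinalizedBundle(
        bundle_id=snapshot.bundle_id,
        records=snapshot.records,
        relations=snapshot.relations,
        digest=digest,
        passthrough=snapshot.passthrough,
        finalized_at=finalized_at,
        prefix_hints=snapshot.prefix_hints,
    )


def digest_of(bundle: FinalizedBundle) -> str:
    """The bundle's content digest: ``sha256(serialize_bundle(bundle))``.

    Equal to the stored digest by construction; recomputing via this
    function is how callers verify a fetched bundle has not been altered.
    """
    return compute_digest(serialize_bundle(bundle))
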