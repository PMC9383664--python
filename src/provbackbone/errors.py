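"""Exception hierarchy.

Structural problems found by the validator are reported, not raised (see
:mod:`provbackbone.validator`); exceptions are reserved for contract
violations — malformed identifiers, dangling references, mutation of frozen
objects, and parse failures.
"""

from __future__ import annotations


class ProvBackboneError(Exception):
    """Base class for all errors raised by this package."""


class IdentifierError(ProvBackboneError):
    """Malformed qualified identifier (empty part or invalid namespace URI)."""


class IntegrityError(ProvBackboneError):
    """Referential integrity broken: a relation endpoint is not declared."""

    def __init__(self, message: str, missing_id: object = None):
        super().__init__(message)
        self.missing_id = missing_id


class ParseError(ProvBackboneError):
    """Malformed PROV-JSON document; ``location`` points at the offender."""

    def __init__(self, message: str, location: str = ""):
        super().__init__(f"{message}" + (f" (at {location})" if location else ""))
        self.location = location


class ImmutabilityError(ProvBackboneError):
    """Attempted mutation of a frozen builder, finalized bundle, or registry."""


class DuplicateConnectorError(ProvBackboneError):
    """A connector with the same shared identifier already exists in the bundle."""


class BackboneTypeError(ProvBackboneError):
    """A record does not carry the backbone type required by the operation."""


class IncompleteJumpError(ProvBackboneError):
    """Jump connector missing a destination attribute.

    Jump connectors exist solely for navigation, so all three destination
    attributes (bundle id, service URL, referenced entity) are mandatory.
    """


class FinalizationRefusedError(ProvBackboneError):
    """Finalization refused because backbone validation failed."""

    def __init__(self, report):
        super().__init__(
            "bundle failed backbone validation: "
            + "; ".join(f"{v.rule}:{v.message}" for v in report.violations)
        )
        self.report = report


class AttachmentStructureError(ProvBackboneError):
    """Domain attachment specs do not form a connected consume/produce chain."""


class BoundaryViolationError(ProvBackboneError):
    """A domain attachment touches backbone records other than via specialization."""


class ClassificationError(ProvBackboneError):
    """Refused to classify a bundle that fails backbone validation."""


class IntegrityAlarmError(ProvBackboneError):
    """Fetched bundle bytes do not match the digest the connector carried.

    Deliberately distinct from a MISSING result: a missing bundle degrades the
    trace, a digest mismatch signals tampering and must not be silently
    tolerated.
    """


class StartMissingError(ProvBackboneError):
    """The bundle a trace was asked to start from cannot be fetched."""


class VersioningError(ProvBackboneError):
    """Meta-bundle misuse: unknown bundle id or duplicate registration."""


class ForestViolationError(VersioningError):
    """A revision edge would create a cycle or a branching/merging history."""
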