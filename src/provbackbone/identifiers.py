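"""Qualified identifiers.

Every record, relation endpoint, and bundle in a provenance chain is named by
a *qualified name*: a short prefix bound to an absolute namespace URI plus a
local name. Identity is defined by ``(namespace_uri, local_name)`` only — the
prefix is a rendering convenience, so the same object referenced from two
organizations' documents under different prefix bindings still compares
equal. Connector identifiers are shared between sender and receiver and carry
the *sender's* prefix; to keep them from colliding with ordinary records
their local names live under a reserved ``connector/`` path segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import urlparse

from .errors import IdentifierError

#: Reserved local-name path segment for connector entities.
CONNECTOR_SEGMENT = "connector/"

# Namespaces used by the backbone vocabulary itself.
PROV_NS = "http://www.w3.org/ns/prov#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"
BACKBONE_NS = "https://w3id.org/distributed-provenance/backbone#"
DCT_NS = "http://purl.org/dc/terms/"

PROV_PREFIX = "prov"
XSD_PREFIX = "xsd"
BACKBONE_PREFIX = "pbb"
DCT_PREFIX = "dct"


@dataclass(frozen=True)
class QualifiedId:
    """A namespaced identifier ``prefix:local_name``.

    Equality and hashing ignore ``prefix``: two ids are the same identifier
    iff their namespace URI and local name agree.
    """

    prefix: str
    namespace_uri: str
    local_name: str
    _key: tuple = field(init=False, repr=False, compare=True)

    def __post_init__(self):
        object.__setattr__(self, "_key", (self.namespace_uri, self.local_name))

    def __eq__(self, other):
        if not isinstance(other, QualifiedId):
            return NotImplemented
        return self._key == other._key

    def __hash__(self):
        return hash(self._key)

    def __lt__(self, other):
        if not isinstance(other, QualifiedId):
            return NotImplemented
        return self._key < other._key

    def __str__(self):
        return f"{self.prefix}:{self.local_name}"

    @property
    def key(self) -> tuple:
        """Prefix-independent identity ``(namespace_uri, local_name)``."""
        return self._key

    @property
    def uri(self) -> str:
        """Expanded form: namespace URI concatenated with the local name."""
        return self.namespace_uri + self.local_name

    def is_connector_name(self) -> bool:
        return self.local_name.startswith(CONNECTOR_SEGMENT)


def _check_absolute_uri(uri: str) -> None:
    parsed = urlparse(uri)
    if not parsed.scheme or not (parsed.netloc or parsed.path):
        raise IdentifierError(f"namespace is not an absolute URI: {uri!r}")


def make_qualified_id(prefix: str, namespace_uri: str, local_name: str) -> QualifiedId:
    """Construct a :class:`QualifiedId`, validating each part.

    Parameters
    ----------
    prefix:
        Short namespace label (non-empty, no colon or whitespace).
    namespace_uri:
        Absolute URI of the namespace.
    local_name:
        Name unique within the namespace (non-empty).

    Raises
    ------
    IdentifierError
        If any part is empty, the prefix contains a colon or whitespace, or
        the namespace URI is not absolute.
    """
    if not prefix:
        raise IdentifierError("prefix must be non-empty")
    if ":" in prefix or any(c.isspace() for c in prefix):
        raise IdentifierError(f"prefix may not contain ':' or whitespace: {prefix!r}")
    if not local_name:
        raise IdentifierError("local name must be non-empty")
    if not namespace_uri:
        raise IdentifierError("namespace URI must be non-empty")
    _check_absolute_uri(namespace_uri)
    return QualifiedId(prefix, namespace_uri, local_name)


def prov_id(local_name: str) -> QualifiedId:
    return QualifiedId(PROV_PREFIX, PROV_NS, local_name)


def backbone_id(local_name: str) -> QualifiedId:
    return QualifiedId(BACKBONE_PREFIX, BACKBONE_NS, local_name)


def dct_id(local_name: str) -> QualifiedId:
    return QualifiedId(DCT_PREFIX, DCT_NS, local_name)
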