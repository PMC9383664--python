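"""Chain store: the retrieval substrate for distributed provenance.

In deployment, each organization runs a provenance service; a connector's
``serviceUrl`` attribute names the service where its destination bundle can
be requested. This module provides that contract as an in-memory reference
implementation — a registry of services, each holding finalized bundles and
the organization's meta-bundle — so chains can be built and traversed
without a network. An HTTP-backed client could satisfy the same interface.

Absence is a *value*, not an error: ``fetch`` returns the :data:`MISSING`
sentinel for unknown services or bundles, which is what lets traversal
degrade gracefully when parts of a chain were never generated. A digest
mismatch, by contrast, raises an integrity alarm: the bundle exists but is
not the bytes the connector vouched for.

Stores round-trip through a directory of PROV-JSON files plus a JSON index
(the fixture exchange format).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .errors import ImmutabilityError, IntegrityAlarmError, VersioningError
from .finalization import digest_of
from .identifiers import QualifiedId
from .model import (
    BackboneType,
    FinalizedBundle,
    deserialize_bundle,
    serialize_bundle,
)
from . import versioning


class _Missing:
    """Singleton returned when a service or bundle cannot be found."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = _Missing()


@dataclass
class _Service:
    url: str
    org_namespace: str
    org_prefix: str
    bundles: Dict[QualifiedId, FinalizedBundle] = field(default_factory=dict)
    meta: versioning.MetaBundle = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.meta is None:
            self.meta = versioning.MetaBundle(
                org_namespace=self.org_namespace, org_prefix=self.org_prefix
            )


class ChainStore:
    """Registry of provenance services and their finalized bundles."""

    def __init__(self):
        self._services: Dict[str, _Service] = {}
        self.access_log: Optional[list] = None

    # -- access logging (least-privilege verification) ---------------------

    def start_access_log(self) -> list:
        """Record every fetch and record materialization from now on."""
        self.access_log = []
        return self.access_log

    def note_record_access(self, bundle_id: QualifiedId, record) -> None:
        if self.access_log is not None:
            self.access_log.append(("record", bundle_id, record))

    # -- registration ------------------------------------------------------

    def add_service(self, url: str, org_namespace: str, org_prefix: str) -> None:
        if url not in self._services:
            self._services[url] = _Service(url, org_namespace, org_prefix)

    def services(self) -> Tuple[str, ...]:
        return tuple(self._services)

    def register(self, service_url: str, bundle: FinalizedBundle) -> "ChainStore":
        """Make ``bundle`` retrievable at ``service_url``.

        The service is created on first use (its namespace taken from the
        bundle id). Re-registering an id at the same service is rejected —
        published bundles are immutable; updates go through :meth:`revise`.
        The same bundle may be registered at several services (mirroring).
        """
        if service_url not in self._services:
            self.add_service(
                service_url, bundle.bundle_id.namespace_uri, bundle.bundle_id.prefix
            )
        service = self._services[service_url]
        if bundle.bundle_id in service.bundles:
            raise ImmutabilityError(
                f"{bundle.bundle_id} is already registered at {service_url}; "
                f"publish a revision instead"
            )
        service.bundles[bundle.bundle_id] = bundle
        versioning.register_finalized(service.meta, bundle)
        return self

    def revise(
        self, service_url: str, old_bundle_id: QualifiedId, new_bundle: FinalizedBundle
    ) -> "ChainStore":
        """Publish ``new_bundle`` as the revision of an already-served bundle."""
        service = self._services.get(service_url)
        if service is None:
            raise VersioningError(f"unknown service {service_url}")
        versioning.revise(service.meta, old_bundle_id, new_bundle)
        service.bundles[new_bundle.bundle_id] = new_bundle
        return self

    def drop_bundle(
        self, service_url: str, bundle_id: QualifiedId, *, keep_meta: bool = True
    ) -> "ChainStore":
        """Remove a bundle's content, simulating provenance that was never
        published (or was lost). The meta-bundle entry is retained by default:
        the organization still *knows of* the bundle even if it cannot serve it.
        """
        service = self._services.get(service_url)
        if service is None or bundle_id not in service.bundles:
            raise VersioningError(f"no bundle {bundle_id} at {service_url}")
        del service.bundles[bundle_id]
        if not keep_meta and service.meta.has(bundle_id):
            del service.meta.entries[bundle_id]
        return self

    # -- retrieval ---------------------------------------------------------

    def fetch(
        self,
        service_url: str,
        bundle_id: QualifiedId,
        expected_digest: Optional[str] = None,
    ):
        """Return the bundle, or :data:`MISSING` if service or id is unknown.

        When the requesting connector carried a destination digest, pass it
        as ``expected_digest``: the content digest is recomputed from the
        stored bundle and a mismatch raises :class:`IntegrityAlarmError`
        (tampering is not a form of absence).
        """
        service = self._services.get(service_url)
        if service is None:
            return MISSING
        bundle = service.bundles.get(bundle_id)
        if bundle is None:
            return MISSING
        if self.access_log is not None:
            self.access_log.append(("fetch", service_url, bundle_id))
        if expected_digest is not None:
            actual = digest_of(bundle)
            if actual != expected_digest:
                raise IntegrityAlarmError(
                    f"digest mismatch for {bundle_id} at {service_url}: "
                    f"expected {expected_digest[:12]}…, got {actual[:12]}…"
                )
        return bundle

    def meta_of(self, service_url: str) -> Optional[versioning.MetaBundle]:
        service = self._services.get(service_url)
        return service.meta if service is not None else None

    def find_bundle(self, bundle_id: QualifiedId):
        """Global lookup: first service (in registration order) serving the id."""
        for url, service in self._services.items():
            if bundle_id in service.bundles:
                return url, service.bundles[bundle_id]
        return None

    def find_by_connector(
        self, shared_connector_id: QualifiedId
    ) -> List[Tuple[str, QualifiedId, BackboneType]]:
        """Every registered bundle containing a connector with this shared id.

        Returns ``(service_url, bundle_id, connector_backbone_type)`` triples
        — the forward-navigation fallback when a senderConnector's
        destination attributes were never filled in.
        """
        hits = []
        for url, service in self._services.items():
            for bundle_id, bundle in service.bundles.items():
                for rec in bundle.records:
                    if (
                        rec.backbone_type is not None
                        and rec.backbone_type.is_connector
                        and rec.id == shared_connector_id
                    ):
                        hits.append((url, bundle_id, rec.backbone_type))
        return hits

    # -- directory exchange format ----------------------------------------

    def export_dir(self, path) -> None:
        """Write the store as PROV-JSON files plus ``index.json``.

        Deterministic: the same store content produces byte-identical trees.
        """
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        index: dict = {"services": {}}
        for url in sorted(self._services):
            service = self._services[url]
            svc_slug = _slug(url)
            bundle_entries = []
            for bundle_id in sorted(service.bundles):
                bundle = service.bundles[bundle_id]
                filename = f"{svc_slug}__{_slug(bundle_id.local_name)}.provjson"
                (root / filename).write_bytes(serialize_bundle(bundle))
                bundle_entries.append(
                    {
                        "prefix": bundle_id.prefix,
                        "namespace": bundle_id.namespace_uri,
                        "local_name": bundle_id.local_name,
                        "file": filename,
                        "finalized_at": bundle.finalized_at,
                    }
                )
            meta_file = f"{svc_slug}__meta.provjson"
            (root / meta_file).write_bytes(serialize_bundle(service.meta.as_bundle()))
            index["services"][url] = {
                "org_namespace": service.org_namespace,
                "org_prefix": service.org_prefix,
                "bundles": bundle_entries,
                "meta": meta_file,
            }
        (root / "index.json").write_text(
            json.dumps(index, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def import_dir(cls, path) -> "ChainStore":
        root = Path(path)
        index = json.loads((root / "index.json").read_text(encoding="utf-8"))
        store = cls()
        for url, svc in index["services"].items():
            store.add_service(url, svc["org_namespace"], svc["org_prefix"])
            service = store._services[url]
            for entry in svc["bundles"]:
                parsed = deserialize_bundle((root / entry["file"]).read_bytes())
                if entry.get("finalized_at"):
                    parsed = FinalizedBundle(
                        bundle_id=parsed.bundle_id,
                        records=parsed.records,
                        relations=parsed.relations,
                        digest=parsed.digest,
                        passthrough=parsed.passthrough,
                        finalized_at=entry["finalized_at"],
                        prefix_hints=parsed.prefix_hints,
                    )
                service.bundles[parsed.bundle_id] = parsed
            meta_bundle = deserialize_bundle((root / svc["meta"]).read_bytes())
            service.meta = versioning.MetaBundle.from_bundle(
                meta_bundle, svc["org_namespace"], svc["org_prefix"]
            )
        return store


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "-", text).strip("-")


# Functional aliases matching the operation names used in the docs.

def register(store: ChainStore, service_url: str, bundle: FinalizedBundle) -> ChainStore:
    return store.register(service_url, bundle)


def fetch(store: ChainStore, service_url: str, bundle_id: QualifiedId,
          expected_digest: Optional[str] = None):
    return store.fetch(service_url, bundle_id, expected_digest)


def find_by_connector(store: ChainStore, shared_connector_id: QualifiedId):
    return store.find_by_connector(shared_connector_id)
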