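"""DICOM network ingress (storage SCP) and egress (storage SCU).

The ingress SCP is the entry point of the stack: all composite objects
C-STOREd within one association are packed into one bundle when the
association is released, the bundle is stored, and an ingest message
(bundle UID, file count, calling AE) is published.  The egress SCU drains
finished flows: every DICOM file of the final bundle is C-STOREd to every
configured destination, with per-destination reports and isolation of
per-destination failures.

Transport: associations run over :class:`DicomNetwork`, an in-process
registry mapping (host, port) to a listening SCP.  It models the
association lifecycle the services rely on — open (refused when nothing
listens), any number of C-STOREs, release (commits the bundle) or abort
(discards it, sender retries) — while staying free of real sockets; a
wire-protocol transport can implement the same surface.  The fixture
destination SCP used in tests and demos records exactly what a PACS or
TPS would receive.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Protocol

import pydicom

from .broker import SCHEMAS, MemoryBroker
from .flows import DestinationSpec
from .storage import BundleStore, pack_bundle, unpack_bundle

log = logging.getLogger(__name__)

__all__ = [
    "ScpConfig",
    "SendReport",
    "AssociationRefused",
    "AssociationAborted",
    "Association",
    "ScpHandler",
    "DicomNetwork",
    "StoreScp",
    "RecordingScp",
    "StoreScu",
    "EgressService",
]


class AssociationRefused(Exception):
    """No SCP is listening at the requested (host, port)."""


class AssociationAborted(Exception):
    """The SCP aborted the association; the sender should retry."""


@dataclass(frozen=True)
class ScpConfig:
    ae_title: str
    port: int
    host: str = "127.0.0.1"

    def __post_init__(self) -> None:
        if not (0 < len(self.ae_title) <= 16 and self.ae_title.isascii()):
            raise ValueError("AE title must be 1-16 ASCII characters")
        if not (1 <= self.port <= 65535):
            raise ValueError("port out of range")


@dataclass
class SendReport:
    """Per-destination outcome of one egress dispatch."""

    destination: DestinationSpec
    attempted: int = 0
    succeeded: int = 0
    failed: int = 0
    per_file: list[tuple[str, bool]] = field(default_factory=list)

    def record(self, path: str, ok: bool) -> None:
        self.attempted += 1
        if ok:
            self.succeeded += 1
        else:
            self.failed += 1
        self.per_file.append((path, ok))

    @property
    def all_succeeded(self) -> bool:
        return self.failed == 0


class ScpHandler(Protocol):
    """What a listening SCP must implement."""

    def on_c_store(self, association: "Association", name: str, data: bytes) -> None: ...
    def on_release(self, association: "Association") -> None: ...
    def on_abort(self, association: "Association") -> None: ...


@dataclass
class Association:
    """One association from a calling AE to a listening SCP."""

    calling_ae: str
    handler: ScpHandler
    received: list[tuple[str, bytes]] = field(default_factory=list)
    open: bool = True

    def c_store(self, name: str, data: bytes) -> None:
        if not self.open:
            raise AssociationAborted("association is closed")
        self.handler.on_c_store(self, name, data)

    def release(self) -> None:
        if self.open:
            self.open = False
            self.handler.on_release(self)

    def abort(self) -> None:
        if self.open:
            self.open = False
            self.handler.on_abort(self)

    def __enter__(self) -> "Association":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.release()
        else:
            self.abort()


class DicomNetwork:
    """In-process association transport: (host, port) -> listening SCP."""

    def __init__(self) -> None:
        self._listeners: dict[tuple[str, int], ScpHandler] = {}

    def listen(self, host: str, port: int, handler: ScpHandler) -> None:
        key = (host, port)
        if key in self._listeners:
            raise ValueError(f"port already bound: {host}:{port}")
        self._listeners[key] = handler

    def associate(self, host: str, port: int, calling_ae: str) -> Association:
        handler = self._listeners.get((host, port))
        if handler is None:
            raise AssociationRefused(f"no SCP listening at {host}:{port}")
        return Association(calling_ae=calling_ae, handler=handler)


def _looks_like_dicom(data: bytes) -> bool:
    try:
        ds = pydicom.dcmread(io.BytesIO(data), stop_before_pixels=True)
        return bool(getattr(ds, "SOPInstanceUID", ""))
    except Exception:  # noqa: BLE001
        return False


class StoreScp:
    """Ingress SCP: one association -> one bundle -> one ingest message.

    Files are stored as received (malformed datasets included; the
    fingerprinter will orphan them).  A storage failure aborts the
    association so the sender can retry; an aborted association's files
    are discarded.  Empty associations publish nothing.
    """

    def __init__(
        self,
        config: ScpConfig,
        store: BundleStore,
        broker: MemoryBroker,
        network: DicomNetwork,
    ) -> None:
        self.config = config
        self.store = store
        self.broker = broker
        network.listen(config.host, config.port, self)

    # -- ScpHandler ----------------------------------------------------
    def on_c_store(self, association: Association, name: str, data: bytes) -> None:
        # keep member names unique within the association bundle
        if any(existing == name for existing, _ in association.received):
            name = f"{len(association.received):06d}_{name}"
        association.received.append((name, data))

    def on_release(self, association: Association) -> None:
        if not association.received:
            return
        try:
            bundle = pack_bundle(association.received)
            bundle_uid = self.store.put(bundle)
        except Exception:
            log.exception("storage failure on association release; aborting")
            association.received.clear()
            raise AssociationAborted("storage failure, retry the send") from None
        self.broker.publish(
            "ingest",
            {
                "schema": SCHEMAS["ingest"],
                "bundle_uid": bundle_uid,
                "file_count": len(bundle.manifest),
                "calling_ae": association.calling_ae,
            },
        )
        log.info(
            "ingest bundle=%s files=%d calling_ae=%s",
            bundle_uid, len(bundle.manifest), association.calling_ae,
        )

    def on_abort(self, association: Association) -> None:
        log.warning(
            "association aborted calling_ae=%s files_discarded=%d",
            association.calling_ae, len(association.received),
        )
        association.received.clear()


class RecordingScp:
    """Fixture destination SCP (PACS/TPS stand-in): records every file
    committed by a released association."""

    def __init__(
        self,
        config: ScpConfig,
        network: DicomNetwork,
        refuse_stores: bool = False,
    ) -> None:
        self.config = config
        self.refuse_stores = refuse_stores
        self.received: list[tuple[str, bytes]] = []
        network.listen(config.host, config.port, self)

    def on_c_store(self, association: Association, name: str, data: bytes) -> None:
        if self.refuse_stores:
            raise AssociationAborted("C-STORE refused by destination")
        association.received.append((name, data))

    def on_release(self, association: Association) -> None:
        self.received.extend(association.received)

    def on_abort(self, association: Association) -> None:
        association.received.clear()

    @property
    def received_checksums(self) -> set[str]:
        import hashlib

        return {hashlib.sha256(d).hexdigest() for _, d in self.received}


class StoreScu:
    """Egress SCU: sends the files of a bundle to DICOM destinations."""

    def __init__(
        self,
        store: BundleStore,
        network: DicomNetwork,
        calling_ae: str = "DICOMFLOW",
    ) -> None:
        self.store = store
        self.network = network
        self.calling_ae = calling_ae

    def dispatch_egress(
        self,
        bundle_uid: str,
        destinations: list[DestinationSpec],
    ) -> list[SendReport]:
        """C-STORE every DICOM file of the bundle to every destination.

        Non-DICOM members are skipped with a warning and never counted in
        ``attempted``.  Failure at one destination does not block others.
        """
        files = unpack_bundle(self.store.get(bundle_uid))
        dicom_files = []
        for path, data in files:
            if _looks_like_dicom(data):
                dicom_files.append((path, data))
            else:
                log.warning("skipping non-DICOM member %s in bundle %s",
                            path, bundle_uid)

        reports = []
        for dest in destinations:
            report = SendReport(destination=dest)
            try:
                assoc = self.network.associate(dest.host, dest.port, self.calling_ae)
            except AssociationRefused:
                for path, _ in dicom_files:
                    report.record(path, False)
                log.error("destination unreachable host=%s port=%d ae=%s",
                          dest.host, dest.port, dest.ae_title)
                reports.append(report)
                continue
            try:
                for path, data in dicom_files:
                    assoc.c_store(path, data)
                assoc.release()
                for path, _ in dicom_files:
                    report.record(path, True)
            except AssociationAborted:
                assoc.abort()
                # an aborted association commits nothing at the receiver
                report = SendReport(destination=dest)
                for path, _ in dicom_files:
                    report.record(path, False)
            reports.append(report)
        return reports


@dataclass
class EgressService:
    """Consumes egress messages; raises on any delivery failure so the
    broker redelivers (receivers tolerate duplicate SOP instances)."""

    broker: MemoryBroker
    scu: StoreScu

    def attach(self) -> None:
        self.broker.subscribe("egress", self.handle)

    def handle(self, message) -> None:
        body = message.body
        destinations = [DestinationSpec.model_validate(d) for d in body["destinations"]]
        reports = self.scu.dispatch_egress(body["bundle_uid"], destinations)
        failed = [r for r in reports if not r.all_succeeded]
        for r in reports:
            log.info(
                "egress flow_instance_id=%s dest=%s:%d attempted=%d succeeded=%d failed=%d",
                body.get("flow_instance_id"), r.destination.host,
                r.destination.port, r.attempted, r.succeeded, r.failed,
            )
        if failed:
            raise AssociationRefused(
                f"{len(failed)} destination(s) failed for bundle {body['bundle_uid']}"
            )
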