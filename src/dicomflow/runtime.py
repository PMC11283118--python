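"""Process entrypoints and the single-process all-in-one stack.

``build_stack`` wires every service — ingress SCP, fingerprinter,
scheduler, consumers, egress SCU — to a shared broker, bundle store and
in-process DICOM network, reproducing the full message topology in one
process.  With the deterministic in-memory broker, ``pump_until_idle``
drains all queues to quiescence, which turns the stack's asynchronous
message flow into a sequential, fully testable program; this all-in-one
mode is the primary test and demo harness.

Fixture destination SCPs are auto-bound for every destination referenced
by the loaded flows (unless already listening), so a demo run ends with
inspectable "PACS-received" files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .broker import MemoryBroker
from .consumer import Runner, StubRunner, Worker, WorkerConfig, run_worker_loop
from .edge import (
    DicomNetwork,
    EgressService,
    RecordingScp,
    ScpConfig,
    StoreScp,
    StoreScu,
)
from .fingerprint import FingerprinterService
from .flows import FlowDefinition, load_flow_dir
from .scheduler import (
    FileStateStore,
    MemoryStateStore,
    Scheduler,
    SchedulerService,
    StateStore,
)
from .storage import BundleStore, FileBundleStore, MemoryBundleStore

log = logging.getLogger(__name__)

__all__ = ["StackConfig", "Stack", "build_stack", "run_service", "run_all_in_one"]

SERVICE_NAMES = ("scp", "fingerprinter", "scheduler", "consumer", "scu")


class StackConfig(BaseModel):
    """Configuration for one stack (the deploy-file stand-in)."""

    model_config = ConfigDict(extra="forbid")

    broker_backend: Literal["memory"] = "memory"
    storage_backend: Literal["memory", "file"] = "memory"
    storage_root: Optional[Path] = None
    state_backend: Literal["memory", "file"] = "memory"
    state_root: Optional[Path] = None
    scp_ae_title: str = Field(default="DICOMFLOW", min_length=1, max_length=16)
    scp_port: int = Field(default=11112, ge=1, le=65535)
    scp_host: str = "127.0.0.1"
    flow_dir: Optional[Path] = None
    cpu_workers: int = Field(default=1, ge=0)
    gpu_workers: int = Field(default=1, ge=0)
    scratch_root: Optional[Path] = None
    bind_fixture_destinations: bool = True
    log_level: str = "INFO"

    def make_store(self) -> BundleStore:
        if self.storage_backend == "file":
            if self.storage_root is None:
                raise ValueError("storage_root required for the file backend")
            return FileBundleStore(self.storage_root)
        return MemoryBundleStore()

    def make_state_store(self) -> StateStore:
        if self.state_backend == "file":
            if self.state_root is None:
                raise ValueError("state_root required for the file state backend")
            return FileStateStore(self.state_root)
        return MemoryStateStore()


@dataclass
class Stack:
    """All services of one deployment plus their shared infrastructure."""

    config: StackConfig
    broker: MemoryBroker
    store: BundleStore
    network: DicomNetwork
    scheduler: Scheduler
    scp: StoreScp
    fingerprinter: FingerprinterService
    scheduler_service: SchedulerService
    egress: EgressService
    workers: list[Worker]
    runner: Runner
    destinations: dict[tuple[str, int], RecordingScp] = field(default_factory=dict)

    def pump_until_idle(self, max_steps: int = 100_000) -> int:
        """Drain every queue to quiescence; returns deliveries made."""
        return self.broker.pump_until_idle(max_steps=max_steps)

    def send_study(
        self, files: Sequence[tuple[str, bytes]], calling_ae: str = "MODSCANNER"
    ) -> None:
        """Push files into the stack's own SCP within one association."""
        with self.network.associate(
            self.config.scp_host, self.config.scp_port, calling_ae
        ) as assoc:
            for path, data in files:
                assoc.c_store(Path(path).name, data)

    def destination_files(self) -> dict[tuple[str, int], list[tuple[str, bytes]]]:
        return {key: list(scp.received) for key, scp in self.destinations.items()}

    def dump_state(self) -> list[dict]:
        return self.scheduler.dump_state()


def build_stack(
    config: StackConfig,
    flows: Optional[Sequence[FlowDefinition]] = None,
    runner: Optional[Runner] = None,
    network: Optional[DicomNetwork] = None,
    broker: Optional[MemoryBroker] = None,
    store: Optional[BundleStore] = None,
    state_store: Optional[StateStore] = None,
) -> Stack:
    """Wire the full service topology in one process.

    ``flows`` defaults to the YAML files under ``config.flow_dir``; an
    empty flow set is legal (ingest messages then produce no dispatches).
    """
    if flows is None:
        flows = load_flow_dir(config.flow_dir) if config.flow_dir else []
    broker = broker or MemoryBroker()
    store = store or config.make_store()
    network = network or DicomNetwork()
    runner = runner or StubRunner()

    scp = StoreScp(
        ScpConfig(
            ae_title=config.scp_ae_title,
            port=config.scp_port,
            host=config.scp_host,
        ),
        store,
        broker,
        network,
    )
    fingerprinter = FingerprinterService(broker, store, flows)
    fingerprinter.attach()

    scheduler = Scheduler(store, state_store or config.make_state_store())
    scheduler_service = SchedulerService(broker, scheduler)
    scheduler_service.attach()

    workers = run_worker_loop(
        WorkerConfig(
            cpu_workers=config.cpu_workers,
            gpu_workers=config.gpu_workers,
            scratch_root=config.scratch_root,
        ),
        runner,
        broker,
        store,
    )

    scu = StoreScu(store, network, calling_ae=config.scp_ae_title)
    egress = EgressService(broker, scu)
    egress.attach()

    destinations: dict[tuple[str, int], RecordingScp] = {}
    if config.bind_fixture_destinations:
        for flow in flows:
            for dest in flow.destinations:
                key = (dest.host, dest.port)
                if key in destinations or key == (config.scp_host, config.scp_port):
                    continue
                destinations[key] = RecordingScp(
                    ScpConfig(ae_title=dest.ae_title, port=dest.port, host=dest.host),
                    network,
                )

    return Stack(
        config=config,
        broker=broker,
        store=store,
        network=network,
        scheduler=scheduler,
        scp=scp,
        fingerprinter=fingerprinter,
        scheduler_service=scheduler_service,
        egress=egress,
        workers=workers,
        runner=runner,
        destinations=destinations,
    )


def run_all_in_one(
    config: Optional[StackConfig] = None,
    flows: Optional[Sequence[FlowDefinition]] = None,
    **kwargs,
) -> Stack:
    """Build the all-in-one stack (in-memory backends by default)."""
    return build_stack(config or StackConfig(), flows=flows, **kwargs)


def run_service(name: str, config: StackConfig, stack: Optional[Stack] = None) -> object:
    """Return the named service of a stack, building the stack if needed.

    With the in-memory broker all services share one process; this
    accessor exists so each service can also be driven (and restarted)
    individually in tests and scripts.  A networked broker backend would
    let each returned service run as its own process.
    """
    if name not in SERVICE_NAMES:
        raise ValueError(f"unknown service {name!r}; choose from {SERVICE_NAMES}")
    stack = stack or build_stack(config)
    return {
        "scp": stack.scp,
        "fingerprinter": stack.fingerprinter,
        "scheduler": stack.scheduler_service,
        "consumer": stack.workers,
        "scu": stack.egress,
    }[name]
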