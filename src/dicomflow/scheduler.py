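"""Flow-state bookkeeping and DAG job scheduling.

The scheduler is the only stateful service of the stack.  For every
dispatch record it creates a flow instance whose *mount table* maps mount
names to bundle UIDs; trigger mounts are pre-filled (each trigger's
matched series packed as its own bundle so a multi-modality model
addresses each input by mount name), and model outputs fill in the rest
as results arrive.  A model job is emitted exactly when all of its input
mounts are bound — the asynchronous ready-set execution of the flow DAG —
and routed to the CPU or GPU work queue by its device request.  When all
models are done the sink-mount bundles are merged into the final bundle
and an egress event is published.

Idempotency under at-least-once messaging:

* ``flow_instance_id`` is a deterministic hash of (flow_id, source
  bundle UID), so a redelivered dispatch message re-registers nothing;
* results for unknown jobs or already-done models are dropped;
* state is persisted through a pluggable key-value store after every
  transition, so a scheduler restarted mid-flow resumes where it left
  off.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .broker import SCHEMAS, MemoryBroker, Message
from .fingerprint import DispatchRecord
from .flows import FlowDefinition, FlowValidationError, ModelSpec, validate_flow
from .storage import BundleStore, pack_bundle, unpack_bundle

log = logging.getLogger(__name__)

__all__ = [
    "ModelJob",
    "ModelResult",
    "FlowState",
    "SchedulerOutcome",
    "StateStore",
    "MemoryStateStore",
    "FileStateStore",
    "Scheduler",
    "SchedulerService",
    "flow_instance_id_for",
]

PENDING, QUEUED, DONE, FAILED = "pending", "queued", "done", "failed"


def flow_instance_id_for(flow_id: str, source_bundle_uid: str) -> str:
    digest = hashlib.sha256(f"{flow_id}\x00{source_bundle_uid}".encode()).hexdigest()
    return digest[:16]


@dataclass(frozen=True)
class ModelJob:
    job_id: str
    flow_instance_id: str
    model: ModelSpec
    inputs: Mapping[str, str]  # mount name -> bundle UID
    queue: str
    attempt: int = 1

    def to_body(self) -> dict:
        return {
            "schema": "work.v1",
            "job_id": self.job_id,
            "flow_instance_id": self.flow_instance_id,
            "model": self.model.model_dump(exclude_none=True),
            "inputs": dict(self.inputs),
            "queue": self.queue,
            "attempt": self.attempt,
        }

    @classmethod
    def from_body(cls, body: Mapping) -> "ModelJob":
        return cls(
            job_id=body["job_id"],
            flow_instance_id=body["flow_instance_id"],
            model=ModelSpec.model_validate(body["model"]),
            inputs=dict(body["inputs"]),
            queue=body["queue"],
            attempt=int(body["attempt"]),
        )


@dataclass(frozen=True)
class ModelResult:
    job_id: str
    flow_instance_id: str
    model_name: str
    status: str  # "succeeded" | "failed"
    outputs: Mapping[str, str] = field(default_factory=dict)
    exit_code: Optional[int] = None
    log_tail: str = ""

    @property
    def succeeded(self) -> bool:
        return self.status == "succeeded"

    def to_body(self) -> dict:
        return {
            "schema": SCHEMAS["result"],
            "job_id": self.job_id,
            "flow_instance_id": self.flow_instance_id,
            "model_name": self.model_name,
            "status": self.status,
            "outputs": dict(self.outputs),
            "exit_code": self.exit_code,
            "log_tail": self.log_tail,
        }

    @classmethod
    def from_body(cls, body: Mapping) -> "ModelResult":
        return cls(
            job_id=body["job_id"],
            flow_instance_id=body["flow_instance_id"],
            model_name=body["model_name"],
            status=body["status"],
            outputs=dict(body["outputs"]),
            exit_code=body.get("exit_code"),
            log_tail=body.get("log_tail", ""),
        )


@dataclass
class FlowState:
    """Scheduler-side record of one running flow instance."""

    flow_instance_id: str
    flow: FlowDefinition
    source_bundle_uid: str
    mounts: dict[str, str] = field(default_factory=dict)
    model_status: dict[str, str] = field(default_factory=dict)
    model_attempts: dict[str, int] = field(default_factory=dict)
    jobs: dict[str, str] = field(default_factory=dict)  # job_id -> model name
    job_queued_at: dict[str, float] = field(default_factory=dict)
    status: str = "running"  # running | finished | failed
    final_bundle_uid: Optional[str] = None
    created: float = 0.0
    updated: float = 0.0

    @property
    def finished(self) -> bool:
        return self.status == "finished"

    @property
    def failed(self) -> bool:
        return self.status == "failed"

    def active_jobs(self) -> dict[str, str]:
        """job_id -> model for jobs queued but without a recorded result."""
        return {
            jid: mdl
            for jid, mdl in self.jobs.items()
            if self.model_status.get(mdl) == QUEUED and jid in self.job_queued_at
        }

    def to_json(self) -> str:
        doc = {
            "flow_instance_id": self.flow_instance_id,
            "flow": self.flow.model_dump(exclude_none=True),
            "source_bundle_uid": self.source_bundle_uid,
            "mounts": self.mounts,
            "model_status": self.model_status,
            "model_attempts": self.model_attempts,
            "jobs": self.jobs,
            "job_queued_at": self.job_queued_at,
            "status": self.status,
            "final_bundle_uid": self.final_bundle_uid,
            "created": self.created,
            "updated": self.updated,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FlowState":
        doc = json.loads(text)
        return cls(
            flow_instance_id=doc["flow_instance_id"],
            flow=FlowDefinition.model_validate(doc["flow"]),
            source_bundle_uid=doc["source_bundle_uid"],
            mounts=dict(doc["mounts"]),
            model_status=dict(doc["model_status"]),
            model_attempts=dict(doc["model_attempts"]),
            jobs=dict(doc["jobs"]),
            job_queued_at={k: float(v) for k, v in doc["job_queued_at"].items()},
            status=doc["status"],
            final_bundle_uid=doc["final_bundle_uid"],
            created=float(doc["created"]),
            updated=float(doc["updated"]),
        )


@dataclass(frozen=True)
class SchedulerOutcome:
    """What one scheduler transition produced."""

    jobs: tuple[ModelJob, ...] = ()
    finished_bundle_uid: Optional[str] = None
    flow_failed: bool = False
    state: Optional[FlowState] = None


class StateStore:
    """Key-value persistence contract for flow states."""

    def load(self, flow_instance_id: str) -> Optional[FlowState]:
        raise NotImplementedError

    def save(self, state: FlowState) -> None:
        raise NotImplementedError

    def all_states(self) -> list[FlowState]:
        raise NotImplementedError


class MemoryStateStore(StateStore):
    def __init__(self) -> None:
        self._states: dict[str, str] = {}

    def load(self, flow_instance_id: str) -> Optional[FlowState]:
        text = self._states.get(flow_instance_id)
        return FlowState.from_json(text) if text else None

    def save(self, state: FlowState) -> None:
        self._states[state.flow_instance_id] = state.to_json()

    def all_states(self) -> list[FlowState]:
        return [FlowState.from_json(t) for t in self._states.values()]


class FileStateStore(StateStore):
    """One JSON file per flow instance; survives scheduler restarts."""

    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, flow_instance_id: str) -> Path:
        return self.root / f"{flow_instance_id}.json"

    def load(self, flow_instance_id: str) -> Optional[FlowState]:
        path = self._path(flow_instance_id)
        if not path.is_file():
            return None
        return FlowState.from_json(path.read_text())

    def save(self, state: FlowState) -> None:
        path = self._path(state.flow_instance_id)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(state.to_json())
        tmp.rename(path)

    def all_states(self) -> list[FlowState]:
        return [FlowState.from_json(p.read_text()) for p in sorted(self.root.glob("*.json"))]


class Scheduler:
    """Pure scheduling logic over a bundle store and a state store.

    ``retry_limit`` is the number of *re*-tries a failed or timed-out
    model gets before its flow is failed (default 1).
    """

    def __init__(
        self,
        store: BundleStore,
        state_store: Optional[StateStore] = None,
        retry_limit: int = 1,
        clock=time.time,
    ) -> None:
        self.store = store
        self.state_store = state_store or MemoryStateStore()
        self.retry_limit = retry_limit
        self.clock = clock

    # -- registration --------------------------------------------------
    def register_dispatch(self, record: DispatchRecord) -> SchedulerOutcome:
        """Create a flow instance from a dispatch record and emit every
        model whose inputs are all trigger mounts.  A duplicate (flow_id,
        source bundle) registration is ignored."""
        report = validate_flow(record.flow)
        if not report.ok:
            raise FlowValidationError(
                f"dispatch for invalid flow {record.flow_id}: {sorted(report.codes())}"
            )
        fid = flow_instance_id_for(record.flow_id, record.source_bundle_uid)
        existing = self.state_store.load(fid)
        if existing is not None:
            log.info(
                "duplicate dispatch ignored flow_instance_id=%s flow_id=%s",
                fid, record.flow_id,
            )
            return SchedulerOutcome(state=existing)

        now = self.clock()
        state = FlowState(
            flow_instance_id=fid,
            flow=record.flow,
            source_bundle_uid=record.source_bundle_uid,
            model_status={m.name: PENDING for m in record.flow.models},
            model_attempts={m.name: 0 for m in record.flow.models},
            created=now,
            updated=now,
        )
        # bind each trigger mount to its own sub-bundle
        files = dict(unpack_bundle(self.store.get(record.bundle_uid)))
        for trigger_name, assigned in sorted(record.assignment.items()):
            sub = pack_bundle((p, files[p]) for p in assigned.file_paths)
            state.mounts[trigger_name] = self.store.put(sub)

        jobs = self._emit_ready(state)
        self._save(state)
        log.info(
            "flow registered flow_instance_id=%s flow_id=%s initial_jobs=%d",
            fid, record.flow_id, len(jobs),
        )
        return SchedulerOutcome(jobs=tuple(jobs), state=state)

    # -- result handling -----------------------------------------------
    def on_model_result(self, result: ModelResult) -> SchedulerOutcome:
        state = self.state_store.load(result.flow_instance_id)
        if state is None:
            log.warning("result for unknown flow instance %s dropped",
                        result.flow_instance_id)
            return SchedulerOutcome()
        model = state.jobs.get(result.job_id)
        if model is None:
            log.warning("result for unknown job %s dropped (stale redelivery)",
                        result.job_id)
            return SchedulerOutcome(state=state)
        if state.model_status.get(model) in (DONE, FAILED) or state.status != "running":
            log.info("duplicate/late result for model=%s ignored", model)
            return SchedulerOutcome(state=state)

        state.job_queued_at.pop(result.job_id, None)
        if result.succeeded:
            spec = self._model_spec(state, model)
            missing = [m for m in spec.output_mounts if m not in result.outputs]
            if missing:
                return self._fail_or_retry(
                    state, model, f"result missing output mounts {missing}"
                )
            for mount in spec.output_mounts:
                state.mounts[mount] = result.outputs[mount]
            state.model_status[model] = DONE
            log.info(
                "model done flow_instance_id=%s model=%s",
                state.flow_instance_id, model,
            )
            jobs = self._emit_ready(state)
            finished_uid = None
            if all(s == DONE for s in state.model_status.values()):
                finished_uid = self.assemble_final_bundle(state)
            self._save(state)
            return SchedulerOutcome(
                jobs=tuple(jobs), finished_bundle_uid=finished_uid, state=state
            )
        return self._fail_or_retry(
            state, model,
            f"exit_code={result.exit_code} log_tail={result.log_tail[-200:]!r}",
        )

    def _fail_or_retry(self, state: FlowState, model: str, why: str) -> SchedulerOutcome:
        attempts = state.model_attempts.get(model, 1)
        if attempts <= self.retry_limit:
            state.model_status[model] = PENDING
            job = self._emit(state, self._model_spec(state, model))
            self._save(state)
            log.warning(
                "model retry flow_instance_id=%s model=%s attempt=%d reason=%s",
                state.flow_instance_id, model, attempts + 1, why,
            )
            return SchedulerOutcome(jobs=(job,), state=state)
        state.model_status[model] = FAILED
        state.status = "failed"
        self._save(state)
        log.error(
            "flow failed flow_instance_id=%s model=%s reason=%s",
            state.flow_instance_id, model, why,
        )
        return SchedulerOutcome(flow_failed=True, state=state)

    # -- job emission --------------------------------------------------
    @staticmethod
    def select_queue(model: ModelSpec) -> str:
        return "work.gpu" if model.device == "gpu" else "work.cpu"

    def _model_spec(self, state: FlowState, name: str) -> ModelSpec:
        for m in state.flow.models:
            if m.name == name:
                return m
        raise KeyError(name)

    def _emit(self, state: FlowState, spec: ModelSpec) -> ModelJob:
        attempt = state.model_attempts.get(spec.name, 0) + 1
        state.model_attempts[spec.name] = attempt
        job_id = f"{state.flow_instance_id}:{spec.name}:{attempt}"
        state.jobs[job_id] = spec.name
        state.job_queued_at[job_id] = self.clock()
        state.model_status[spec.name] = QUEUED
        state.updated = self.clock()
        return ModelJob(
            job_id=job_id,
            flow_instance_id=state.flow_instance_id,
            model=spec,
            inputs={m: state.mounts[m] for m in spec.input_mounts},
            queue=self.select_queue(spec),
            attempt=attempt,
        )

    def _emit_ready(self, state: FlowState) -> list[ModelJob]:
        """Emit every pending model whose input mounts are all bound.
        Sorted by name for reproducible job order."""
        if state.status != "running":
            return []
        jobs = []
        for spec in sorted(state.flow.models, key=lambda m: m.name):
            if state.model_status.get(spec.name) != PENDING:
                continue
            if all(mnt in state.mounts for mnt in spec.input_mounts):
                jobs.append(self._emit(state, spec))
        return jobs

    # -- completion ----------------------------------------------------
    def assemble_final_bundle(self, state: FlowState) -> str:
        """Merge all sink-mount bundles into the flow's final bundle.

        Paths occurring in more than one sink bundle are kept under a
        ``<mount>/`` prefix; unique paths keep their original name."""
        sink_mounts = state.flow.effective_sink_mounts()
        per_mount: dict[str, list[tuple[str, bytes]]] = {}
        for mount in sink_mounts:
            uid = state.mounts.get(mount)
            if uid is None:
                state.status = "failed"
                self._save(state)
                raise RuntimeError(
                    f"sink mount {mount!r} unbound in finished flow "
                    f"{state.flow_instance_id}"
                )
            per_mount[mount] = unpack_bundle(self.store.get(uid))

        counts: dict[str, int] = {}
        for members in per_mount.values():
            for path, _ in members:
                counts[path] = counts.get(path, 0) + 1
        merged: list[tuple[str, bytes]] = []
        for mount, members in per_mount.items():
            for path, data in members:
                name = f"{mount}/{path}" if counts[path] > 1 else path
                merged.append((name, data))
        final_uid = self.store.put(pack_bundle(merged))
        state.status = "finished"
        state.final_bundle_uid = final_uid
        state.updated = self.clock()
        log.info(
            "flow finished flow_instance_id=%s final_bundle=%s files=%d",
            state.flow_instance_id, final_uid, len(merged),
        )
        return final_uid

    # -- stale-job sweep -----------------------------------------------
    def sweep_stale(self, now: Optional[float] = None) -> list[ModelJob]:
        """Re-queue or fail jobs older than their model's timeout.

        Idempotent: a job is only acted on once (its queue timestamp is
        consumed).  Returns the re-emitted jobs."""
        now = self.clock() if now is None else now
        reissued: list[ModelJob] = []
        for state in self.state_store.all_states():
            if state.status != "running":
                continue
            changed = False
            for job_id, model in list(state.active_jobs().items()):
                queued_at = state.job_queued_at[job_id]
                spec = self._model_spec(state, model)
                if now - queued_at <= spec.timeout:
                    continue
                del state.job_queued_at[job_id]
                changed = True
                outcome = self._fail_or_retry(
                    state, model, f"timeout after {now - queued_at:.0f}s"
                )
                reissued.extend(outcome.jobs)
                if outcome.flow_failed:
                    break
            if changed:
                self._save(state)
        return reissued

    def _save(self, state: FlowState) -> None:
        state.updated = self.clock()
        self.state_store.save(state)

    def dump_state(self) -> list[dict]:
        """JSON-ready snapshot of every flow instance (dashboard feed)."""
        return [json.loads(s.to_json()) for s in self.state_store.all_states()]


class SchedulerService:
    """Broker wiring: dispatch/result in, work/egress out."""

    def __init__(self, broker: MemoryBroker, scheduler: Scheduler) -> None:
        self.broker = broker
        self.scheduler = scheduler

    def attach(self) -> None:
        self.broker.subscribe("dispatch", self.handle_dispatch)
        self.broker.subscribe("result", self.handle_result)

    def _publish_outcome(self, state_flow: FlowDefinition, outcome: SchedulerOutcome) -> None:
        for job in outcome.jobs:
            self.broker.publish(job.queue, job.to_body())
        if outcome.finished_bundle_uid is not None and outcome.state is not None:
            self.broker.publish(
                "egress",
                {
                    "schema": SCHEMAS["egress"],
                    "flow_instance_id": outcome.state.flow_instance_id,
                    "flow_id": state_flow.flow_id,
                    "bundle_uid": outcome.finished_bundle_uid,
                    "destinations": [
                        d.model_dump() for d in state_flow.destinations
                    ],
                },
            )

    def handle_dispatch(self, message: Message) -> None:
        record = DispatchRecord.from_body(message.body)
        outcome = self.scheduler.register_dispatch(record)
        self._publish_outcome(record.flow, outcome)

    def handle_result(self, message: Message) -> None:
        result = ModelResult.from_body(message.body)
        outcome = self.scheduler.on_model_result(result)
        if outcome.state is not None:
            self._publish_outcome(outcome.state.flow, outcome)


def replay_messages(broker: MemoryBroker, messages: Iterable[Message]) -> None:
    """Re-publish captured messages verbatim (resilience testing aid)."""
    for m in messages:
        broker.publish(m.queue, m.body)
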