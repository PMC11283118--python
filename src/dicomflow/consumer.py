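"""Worker pool executing model containers.

A worker takes one job at a time from its device queue, stages each input
bundle into a read-only per-mount directory, invokes a *runner* on the
model image, packs each output directory into its own bundle, and reports
a result.  The filesystem contract seen by a model is fixed: inputs at
``/input/<mount>``, outputs at ``/output/<mount>`` (host-side scratch
dirs in the stub/process runners), with ``INPUT_<MOUNT>`` /
``OUTPUT_<MOUNT>`` environment variables carrying the concrete paths.

Error semantics distinguish infrastructure failures from model failures:
a storage miss or engine failure raises (message nack -> redelivery),
while a model exiting nonzero, timing out, or writing no output produces
an acknowledged *failed* result — a broken model must not loop forever on
the queue.
"""

from __future__ import annotations

import logging
import shutil
import stat
import subprocess
import tempfile
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

from .broker import MemoryBroker, Message
from .scheduler import ModelJob, ModelResult
from .storage import BundleNotFoundError, BundleStore, pack_bundle, unpack_bundle

log = logging.getLogger(__name__)

__all__ = [
    "RunResult",
    "Runner",
    "StubRunner",
    "ProcessRunner",
    "DockerRunner",
    "RunnerInfrastructureError",
    "WorkerConfig",
    "execute_job",
    "Worker",
    "run_worker_loop",
]


class RunnerInfrastructureError(Exception):
    """The runner itself failed (engine down, image missing) — retriable."""


@dataclass(frozen=True)
class RunResult:
    exit_code: int
    log: str = ""


class Runner:
    """Behavior contract every runner implements.

    Output dirs exist and are empty before the run; input dirs are staged
    read-only and must never be modified.
    """

    def run(
        self,
        image: str,
        command: Optional[list[str]],
        input_dirs: Mapping[str, Path],
        output_dirs: Mapping[str, Path],
        env: Mapping[str, str],
        device: str,
        timeout: float,
    ) -> RunResult:
        raise NotImplementedError


StubFn = Callable[[Mapping[str, Path], Mapping[str, Path], Mapping[str, str]], int]


def _mount_env(
    input_dirs: Mapping[str, Path], output_dirs: Mapping[str, Path]
) -> dict[str, str]:
    env = {}
    for mount, path in input_dirs.items():
        env[f"INPUT_{mount.upper()}"] = str(path)
    for mount, path in output_dirs.items():
        env[f"OUTPUT_{mount.upper()}"] = str(path)
    return env


class StubRunner(Runner):
    """Maps image names to registered local callables — desk-scale model
    execution without a container engine.

    Built-ins: ``stub/identity`` copies the union of all input-mount files
    into every output mount; ``stub/fail`` exits 7; ``stub/noop`` writes
    nothing (exercising the empty-output contract).
    """

    def __init__(self) -> None:
        self._registry: dict[str, StubFn] = {
            "stub/identity": _identity_stub,
            "stub/fail": lambda i, o, e: 7,
            "stub/noop": lambda i, o, e: 0,
        }

    def register(self, image: str, fn: StubFn) -> None:
        self._registry[image] = fn

    def run(self, image, command, input_dirs, output_dirs, env, device, timeout):
        fn = self._registry.get(image)
        if fn is None:
            raise RunnerInfrastructureError(f"no stub registered for image {image!r}")
        merged = {**_mount_env(input_dirs, output_dirs), **env}
        try:
            code = fn(input_dirs, output_dirs, merged)
        except Exception as exc:  # stub crash == model crash, not infra
            log.exception("stub model crashed image=%s", image)
            return RunResult(exit_code=1, log=f"stub crashed: {exc}")
        return RunResult(exit_code=int(code), log=f"stub {image} exit={code}")


def _identity_stub(
    input_dirs: Mapping[str, Path],
    output_dirs: Mapping[str, Path],
    env: Mapping[str, str],
) -> int:
    for out_dir in output_dirs.values():
        for mount in sorted(input_dirs):
            src = input_dirs[mount]
            for f in sorted(p for p in src.rglob("*") if p.is_file()):
                rel = f.relative_to(src)
                dest = out_dir / rel
                dest.parent.mkdir(parents=True, exist_ok=True)
                dest.write_bytes(f.read_bytes())
    return 0


class ProcessRunner(Runner):
    """Runs the model command as a local subprocess (``image`` is
    informational).  Mount paths are passed via environment variables."""

    def run(self, image, command, input_dirs, output_dirs, env, device, timeout):
        if not command:
            raise RunnerInfrastructureError("process runner requires a command")
        merged = {**_mount_env(input_dirs, output_dirs), **env}
        try:
            proc = subprocess.run(
                command,
                env={**merged, "PATH": "/usr/bin:/bin:/usr/local/bin"},
                capture_output=True,
                text=True,
                timeout=timeout,
            )
        except subprocess.TimeoutExpired:
            return RunResult(exit_code=-1, log=f"timeout after {timeout}s")
        except OSError as exc:
            raise RunnerInfrastructureError(str(exc)) from exc
        return RunResult(exit_code=proc.returncode, log=proc.stdout + proc.stderr)


class DockerRunner(Runner):
    """Shells out to the ``docker`` CLI; inputs mounted read-only at
    ``/input/<mount>``, outputs read-write at ``/output/<mount>``; GPU
    jobs request devices via ``--gpus`` (container-toolkit convention)."""

    def __init__(self, docker_bin: str = "docker", gpus: str = "all") -> None:
        self.docker_bin = docker_bin
        self.gpus = gpus

    def run(self, image, command, input_dirs, output_dirs, env, device, timeout):
        argv = [self.docker_bin, "run", "--rm"]
        for mount, path in input_dirs.items():
            argv += ["-v", f"{path}:/input/{mount}:ro"]
        for mount, path in output_dirs.items():
            argv += ["-v", f"{path}:/output/{mount}"]
        for key, value in {**_mount_env(
            {m: Path(f"/input/{m}") for m in input_dirs},
            {m: Path(f"/output/{m}") for m in output_dirs},
        ), **env}.items():
            argv += ["-e", f"{key}={value}"]
        if device == "gpu":
            argv += ["--gpus", self.gpus]
        argv.append(image)
        if command:
            argv += list(command)
        try:
            proc = subprocess.run(
                argv, capture_output=True, text=True, timeout=timeout
            )
        except subprocess.TimeoutExpired:
            return RunResult(exit_code=-1, log=f"timeout after {timeout}s")
        except OSError as exc:
            raise RunnerInfrastructureError(str(exc)) from exc
        if proc.returncode == 125:  # docker daemon / invocation error
            raise RunnerInfrastructureError(proc.stderr)
        return RunResult(exit_code=proc.returncode, log=proc.stdout + proc.stderr)


@dataclass(frozen=True)
class WorkerConfig:
    cpu_workers: int = 1
    gpu_workers: int = 1
    scratch_root: Optional[Path] = None


def _set_tree_writable(root: Path) -> None:
    for p in [root, *root.rglob("*")]:
        p.chmod(p.stat().st_mode | stat.S_IWUSR)


def execute_job(
    job: ModelJob,
    runner: Runner,
    store: BundleStore,
    scratch_root: Optional[Path] = None,
) -> ModelResult:
    """Stage, run, collect: one model execution.

    Raises on infrastructure failures (storage miss, runner error) so the
    work message is nack'd; model-level failures return a failed result.
    Scratch is always cleaned up.
    """
    scratch_base = Path(scratch_root) if scratch_root else Path(tempfile.gettempdir())
    scratch_base.mkdir(parents=True, exist_ok=True)
    safe_id = "".join(c if c.isalnum() else "_" for c in job.job_id)
    scratch = scratch_base / f"job-{safe_id}-{uuid.uuid4().hex[:8]}"
    input_dirs: dict[str, Path] = {}
    output_dirs: dict[str, Path] = {}
    try:
        for mount, uid in job.inputs.items():
            bundle = store.get(uid)  # BundleNotFoundError propagates -> nack
            mount_dir = scratch / "input" / mount
            mount_dir.mkdir(parents=True)
            for rel, data in unpack_bundle(bundle):
                dest = mount_dir / rel
                dest.parent.mkdir(parents=True, exist_ok=True)
                dest.write_bytes(data)
                dest.chmod(0o444)
            for sub in [mount_dir, *[p for p in mount_dir.rglob("*") if p.is_dir()]]:
                sub.chmod(0o555)  # staged read-only
            input_dirs[mount] = mount_dir
        for mount in job.model.output_mounts:
            mount_dir = scratch / "output" / mount
            mount_dir.mkdir(parents=True)
            output_dirs[mount] = mount_dir

        run = runner.run(
            image=job.model.image,
            command=job.model.command,
            input_dirs=input_dirs,
            output_dirs=output_dirs,
            env=job.model.env,
            device=job.model.device,
            timeout=job.model.timeout,
        )
        tail = run.log[-2000:]
        if run.exit_code != 0:
            return ModelResult(
                job_id=job.job_id,
                flow_instance_id=job.flow_instance_id,
                model_name=job.model.name,
                status="failed",
                exit_code=run.exit_code,
                log_tail=tail,
            )

        outputs: dict[str, str] = {}
        for mount, out_dir in output_dirs.items():
            files = sorted(p for p in out_dir.rglob("*") if p.is_file())
            if not files:
                return ModelResult(
                    job_id=job.job_id,
                    flow_instance_id=job.flow_instance_id,
                    model_name=job.model.name,
                    status="failed",
                    exit_code=run.exit_code,
                    log_tail=f"declared output mount {mount!r} is empty; {tail}",
                )
            bundle = pack_bundle(
                (str(p.relative_to(out_dir)), p.read_bytes()) for p in files
            )
            outputs[mount] = store.put(bundle)
        return ModelResult(
            job_id=job.job_id,
            flow_instance_id=job.flow_instance_id,
            model_name=job.model.name,
            status="succeeded",
            outputs=outputs,
            exit_code=0,
            log_tail=tail,
        )
    finally:
        if scratch.exists():
            for mount_dir in input_dirs.values():
                if mount_dir.exists():
                    _set_tree_writable(mount_dir)
            shutil.rmtree(scratch, ignore_errors=True)


@dataclass
class Worker:
    """One subscriber on one device queue; publishes results."""

    broker: MemoryBroker
    store: BundleStore
    runner: Runner
    queue: str
    scratch_root: Optional[Path] = None
    jobs_handled: list[str] = field(default_factory=list)

    def attach(self) -> None:
        self.broker.subscribe(self.queue, self.handle)

    def handle(self, message: Message) -> None:
        job = ModelJob.from_body(message.body)
        try:
            result = execute_job(job, self.runner, self.store, self.scratch_root)
        except (BundleNotFoundError, RunnerInfrastructureError):
            raise  # nack -> redelivery / dead-letter
        self.jobs_handled.append(job.job_id)
        self.broker.publish("result", result.to_body())


def run_worker_loop(
    config: WorkerConfig,
    runner: Runner,
    broker: MemoryBroker,
    store: BundleStore,
) -> list[Worker]:
    """Attach the configured number of CPU and GPU workers to their
    queues.  GPU workers subscribe only to ``work.gpu``, CPU workers only
    to ``work.cpu``; with the in-memory broker, message pumping drives
    them round-robin (work-sharing)."""
    workers: list[Worker] = []
    for _ in range(config.cpu_workers):
        w = Worker(broker, store, runner, "work.cpu", config.scratch_root)
        w.attach()
        workers.append(w)
    for _ in range(config.gpu_workers):
        w = Worker(broker, store, runner, "work.gpu", config.scratch_root)
        w.attach()
        workers.append(w)
    return workers
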