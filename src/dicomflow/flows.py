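"""Declarative flow definitions: triggers, a DAG of containerized models,
and DICOM destinations.

A *flow* couples three parts:

* **triggers** — DICOM attribute constraints (``Modality: CT``,
  ``SeriesDescription: /.*T1.*/``) that decide when the flow fires;
* **models** — container images with named input/output *mounts*; mounts
  are the edges of the execution DAG, models the nodes.  A mount with no
  producing model must carry the name of a trigger, which makes it a
  trigger-input mount fed by the matched series;
* **destinations** — DICOM nodes (host, port, AE title) that receive the
  flow's final output.

Flow documents are YAML, one flow per file::

    flow_id: ct_seg
    triggers:
      - name: ct
        constraints: {Modality: CT}
    models:
      - name: seg
        image: org/ct-seg:1
        input_mounts: [ct]
        output_mounts: [rtss]
        device: gpu
    destinations:
      - {host: tps.example.org, port: 104, ae_title: TPS}

Parsing (:func:`parse_flow_definition`) checks structure and field types
only; graph-level invariants (acyclicity, dangling mounts, reachability)
are checked by :func:`validate_flow`, which reports findings as data
rather than raising.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)
from pydicom.datadict import tag_for_keyword

__all__ = [
    "TriggerSpec",
    "ModelSpec",
    "DestinationSpec",
    "FlowDefinition",
    "MountSpec",
    "ValidationIssue",
    "ValidationReport",
    "FlowParseError",
    "FlowValidationError",
    "parse_flow_definition",
    "serialize_flow",
    "load_flow_file",
    "load_flow_dir",
    "validate_flow",
    "execution_layers",
    "compile_constraint",
]


class FlowParseError(Exception):
    """Malformed flow document (bad YAML, missing/unknown fields)."""


class FlowValidationError(Exception):
    """Operation requires a valid flow but the flow fails validation."""


_HEX_TAG_RE = re.compile(r"^\(?([0-9a-fA-F]{4}),\s*([0-9a-fA-F]{4})\)?$")


def _is_dicom_attribute_key(key: str) -> bool:
    if _HEX_TAG_RE.match(key):
        return True
    return tag_for_keyword(key) is not None


def compile_constraint(pattern: str) -> Callable[[str], bool]:
    """Build a matcher for one trigger constraint value.

    A bare string means exact match after DICOM trailing-space
    normalization; ``/…/`` delimits an anchored regular expression.
    """
    if len(pattern) >= 2 and pattern.startswith("/") and pattern.endswith("/"):
        rx = re.compile(pattern[1:-1])
        return lambda value: rx.fullmatch(value.rstrip(" ")) is not None
    expected = pattern.rstrip(" ")
    return lambda value: value.rstrip(" ") == expected


class TriggerSpec(BaseModel):
    """One named set of DICOM attribute constraints; all must hold on a
    single series for the trigger to fire."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = Field(min_length=1)
    constraints: dict[str, str] = Field(min_length=1)

    @field_validator("constraints")
    @classmethod
    def _check_constraints(cls, v: dict[str, str]) -> dict[str, str]:
        for key, pattern in v.items():
            if not _is_dicom_attribute_key(key):
                raise ValueError(
                    f"{key!r} is not a DICOM keyword or group,element hex tag"
                )
            try:
                compile_constraint(str(pattern))
            except re.error as exc:
                raise ValueError(f"invalid regex for {key!r}: {exc}") from exc
        return {k: str(p) for k, p in v.items()}

    def matchers(self) -> dict[str, Callable[[str], bool]]:
        return {k: compile_constraint(p) for k, p in self.constraints.items()}


class ModelSpec(BaseModel):
    """One containerized processing step (node of the flow DAG)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = Field(min_length=1)
    image: str = Field(min_length=1)
    command: Optional[list[str]] = None
    input_mounts: list[str] = Field(min_length=1)
    output_mounts: list[str] = Field(min_length=1)
    device: Literal["cpu", "gpu"] = "cpu"
    timeout: float = Field(default=3600.0, gt=0)
    env: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_mounts(self) -> "ModelSpec":
        overlap = set(self.input_mounts) & set(self.output_mounts)
        if overlap:
            raise ValueError(
                f"mounts used as both input and output of model "
                f"{self.name!r}: {sorted(overlap)}"
            )
        for side, mounts in (("input", self.input_mounts),
                             ("output", self.output_mounts)):
            if len(set(mounts)) != len(mounts):
                raise ValueError(f"duplicate {side} mounts on model {self.name!r}")
        return self


class DestinationSpec(BaseModel):
    """A DICOM node to which the flow's output is C-STOREd."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    host: str = Field(min_length=1)
    port: int = Field(ge=1, le=65535)
    ae_title: str = Field(min_length=1, max_length=16)

    @field_validator("ae_title")
    @classmethod
    def _ascii_ae(cls, v: str) -> str:
        if not v.isascii():
            raise ValueError("AE title must be ASCII")
        return v


@dataclass(frozen=True)
class MountSpec:
    """Derived description of one mount (edge) of the flow graph."""

    name: str
    kind: Literal["trigger-input", "intermediate", "sink"]


class FlowDefinition(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    flow_id: str = Field(min_length=1)
    triggers: list[TriggerSpec] = Field(min_length=1)
    models: list[ModelSpec] = Field(min_length=1)
    destinations: list[DestinationSpec] = Field(min_length=1)
    sink_mounts: Optional[list[str]] = None

    # -- graph views ---------------------------------------------------
    @property
    def trigger_names(self) -> list[str]:
        return [t.name for t in self.triggers]

    def mount_producers(self) -> dict[str, list[str]]:
        """Mount name -> names of models that output it."""
        producers: dict[str, list[str]] = {}
        for m in self.models:
            for mount in m.output_mounts:
                producers.setdefault(mount, []).append(m.name)
        return producers

    def mount_consumers(self) -> dict[str, list[str]]:
        consumers: dict[str, list[str]] = {}
        for m in self.models:
            for mount in m.input_mounts:
                consumers.setdefault(mount, []).append(m.name)
        return consumers

    def effective_sink_mounts(self) -> list[str]:
        """Explicit ``sink_mounts`` if given; otherwise every output mount
        with no downstream consumer."""
        if self.sink_mounts is not None:
            return list(self.sink_mounts)
        consumed = set(self.mount_consumers())
        sinks = [
            mount
            for m in self.models
            for mount in m.output_mounts
            if mount not in consumed
        ]
        return sorted(set(sinks))

    def mounts(self) -> list[MountSpec]:
        trigger_names = set(self.trigger_names)
        produced = set(self.mount_producers())
        sinks = set(self.effective_sink_mounts())
        names = sorted(
            {mnt for m in self.models for mnt in m.input_mounts + m.output_mounts}
            | trigger_names
        )
        out = []
        for name in names:
            if name in trigger_names and name not in produced:
                kind: Literal["trigger-input", "intermediate", "sink"] = "trigger-input"
            elif name in sinks:
                kind = "sink"
            else:
                kind = "intermediate"
            out.append(MountSpec(name, kind))
        return out


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str
    element: str


@dataclass(frozen=True)
class ValidationReport:
    errors: tuple[ValidationIssue, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.errors

    def codes(self) -> set[str]:
        return {e.code for e in self.errors}


# ---------------------------------------------------------------------------
# parsing / serialization


_REQUIRED_SECTIONS = ("flow_id", "triggers", "models", "destinations")


def parse_flow_definition(text: str) -> FlowDefinition:
    """Parse a YAML flow document into a :class:`FlowDefinition`.

    Structural/type errors raise :class:`FlowParseError` with field
    context; graph invariants are *not* checked here (see
    :func:`validate_flow`).
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FlowParseError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise FlowParseError("flow document must be a YAML mapping")
    for section in _REQUIRED_SECTIONS:
        if section not in doc:
            raise FlowParseError(f"missing required section: {section!r}")
    try:
        return FlowDefinition.model_validate(doc)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise FlowParseError(f"invalid flow document: {details}") from exc


def serialize_flow(flow: FlowDefinition) -> str:
    """YAML serialization; ``parse_flow_definition`` round-trips it."""
    doc = flow.model_dump(exclude_none=True)
    return yaml.safe_dump(doc, sort_keys=False)


def load_flow_file(path: str | Path) -> FlowDefinition:
    path = Path(path)
    try:
        return parse_flow_definition(path.read_text())
    except FlowParseError as exc:
        raise FlowParseError(f"{path}: {exc}") from exc


def load_flow_dir(path: str | Path) -> list[FlowDefinition]:
    """Load every ``*.yml``/``*.yaml`` flow file in a directory, sorted by
    file name."""
    root = Path(path)
    flows = []
    for p in sorted(root.glob("*.y*ml")):
        flows.append(load_flow_file(p))
    return flows


# ---------------------------------------------------------------------------
# graph validation


def _model_edges(flow: FlowDefinition) -> dict[str, set[str]]:
    """model -> set of downstream models (via shared mounts)."""
    producers = flow.mount_producers()
    edges: dict[str, set[str]] = {m.name: set() for m in flow.models}
    for m in flow.models:
        for mount in m.input_mounts:
            for producer in producers.get(mount, []):
                if producer != m.name:
                    edges[producer].add(m.name)
    return edges


def _find_cycle_mounts(flow: FlowDefinition) -> list[str] | None:
    """Return a cyclic mount sequence (m1 -> m2 -> ... -> m1) if any."""
    by_name = {m.name: m for m in flow.models}
    consumers = flow.mount_consumers()
    # DFS over models; edge labels are the mount names carrying the data.
    color: dict[str, int] = {}
    stack: list[tuple[str, str]] = []  # (model, mount that led into it)

    def dfs(model: str) -> list[str] | None:
        color[model] = 1
        for mount in by_name[model].output_mounts:
            for consumer in consumers.get(mount, []):
                if consumer == model:
                    continue
                state = color.get(consumer, 0)
                if state == 1:
                    # found back edge: collect mounts from consumer onwards
                    mounts = [mount]
                    for mdl, mnt in reversed(stack):
                        if mdl == consumer:
                            break
                        mounts.append(mnt)
                    mounts.reverse()
                    return mounts
                if state == 0:
                    stack.append((consumer, mount))
                    found = dfs(consumer)
                    stack.pop()
                    if found:
                        return found
        color[model] = 2
        return None

    for m in flow.models:
        if color.get(m.name, 0) == 0:
            stack.clear()
            found = dfs(m.name)
            if found:
                return found
    return None


def validate_flow(flow: FlowDefinition) -> ValidationReport:
    """Check all graph-level flow invariants; findings are data, not
    exceptions.

    Error codes: ``DUPLICATE_MODEL``, ``DUPLICATE_TRIGGER``,
    ``DUPLICATE_MOUNT_PRODUCER`` (a mount produced by >1 model),
    ``DANGLING_MOUNT`` (input mount with no producer and no matching
    trigger), ``TRIGGER_MOUNT_PRODUCED`` (a trigger name also produced by
    a model), ``CYCLE``, ``UNREACHABLE`` (model not reachable from any
    trigger-input mount), ``UNKNOWN_SINK`` (explicit sink mount nobody
    produces).  A trigger feeding no model is legal: the flow still
    requires it to match, it just contributes no input data.
    """
    errors: list[ValidationIssue] = []

    model_names = [m.name for m in flow.models]
    for name in sorted({n for n in model_names if model_names.count(n) > 1}):
        errors.append(
            ValidationIssue("DUPLICATE_MODEL", f"model name {name!r} reused", name)
        )
    trig_names = flow.trigger_names
    for name in sorted({n for n in trig_names if trig_names.count(n) > 1}):
        errors.append(
            ValidationIssue("DUPLICATE_TRIGGER", f"trigger name {name!r} reused", name)
        )

    producers = flow.mount_producers()
    trigger_set = set(trig_names)
    for mount, prods in sorted(producers.items()):
        if len(prods) > 1:
            errors.append(
                ValidationIssue(
                    "DUPLICATE_MOUNT_PRODUCER",
                    f"mount {mount!r} produced by models {sorted(prods)}",
                    mount,
                )
            )
        if mount in trigger_set:
            errors.append(
                ValidationIssue(
                    "TRIGGER_MOUNT_PRODUCED",
                    f"mount {mount!r} is a trigger name but is produced by "
                    f"model(s) {sorted(prods)}",
                    mount,
                )
            )

    for m in flow.models:
        for mount in m.input_mounts:
            if mount not in producers and mount not in trigger_set:
                errors.append(
                    ValidationIssue(
                        "DANGLING_MOUNT",
                        f"input mount {mount!r} of model {m.name!r} has no "
                        f"producing model and matches no trigger",
                        mount,
                    )
                )

    cycle = _find_cycle_mounts(flow)
    if cycle:
        seq = " -> ".join(cycle + [cycle[0]])
        errors.append(
            ValidationIssue("CYCLE", f"mount cycle: {seq}", cycle[0])
        )

    # reachability from trigger-input mounts
    edges = _model_edges(flow)
    consumers = flow.mount_consumers()
    reached: set[str] = set()
    frontier = [
        mdl for t in trigger_set for mdl in consumers.get(t, [])
    ]
    while frontier:
        mdl = frontier.pop()
        if mdl in reached:
            continue
        reached.add(mdl)
        frontier.extend(edges.get(mdl, ()))
    for m in flow.models:
        if m.name not in reached:
            errors.append(
                ValidationIssue(
                    "UNREACHABLE",
                    f"model {m.name!r} is not reachable from any trigger-input "
                    f"mount",
                    m.name,
                )
            )

    if flow.sink_mounts is not None:
        for mount in flow.sink_mounts:
            if mount not in producers:
                errors.append(
                    ValidationIssue(
                        "UNKNOWN_SINK",
                        f"sink mount {mount!r} is produced by no model",
                        mount,
                    )
                )

    return ValidationReport(errors=tuple(errors))


def execution_layers(flow: FlowDefinition) -> list[list[str]]:
    """Stratify the model DAG: layer ``k`` holds exactly the models whose
    inputs are all satisfied by trigger mounts plus outputs of layers
    ``< k``.  Models within a layer are sorted by name (execution itself
    is order-free).  Raises :class:`FlowValidationError` on invalid flows.
    """
    report = validate_flow(flow)
    if not report.ok:
        raise FlowValidationError(
            "; ".join(f"{e.code}: {e.message}" for e in report.errors)
        )
    available = set(flow.trigger_names)
    remaining = {m.name: m for m in flow.models}
    layers: list[list[str]] = []
    while remaining:
        ready = sorted(
            name
            for name, m in remaining.items()
            if all(mnt in available for mnt in m.input_mounts)
        )
        if not ready:  # unreachable for validated flows
            raise FlowValidationError("no progress stratifying flow (cycle?)")
        layers.append(ready)
        for name in ready:
            available.update(remaining[name].output_mounts)
            del remaining[name]
    return layers
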