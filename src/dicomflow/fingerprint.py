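"""Trigger matching: decide which received series satisfy which flows.

A trigger matches a series when every constrained attribute exists on the
series and all its observed values satisfy the pattern (exact string
after DICOM trailing-space normalization, or ``/…/`` anchored regex).  A
flow matches a bundle when an *injective* assignment of its triggers to
distinct series exists — e.g. a planning-CT trigger and a CBCT trigger
must claim two different CT series.  When several assignments exist the
lexicographically smallest by (trigger name, SeriesInstanceUID) is chosen
and the ambiguity is logged, so matching is deterministic and auditable.

For each matched flow a pruned bundle holding exactly the matched files
is stored and a dispatch record (pruned-bundle UID + flow snapshot +
assignment) is emitted.  Flows are independent: one bundle may fan out to
several flows, and a failure evaluating one flow never suppresses the
others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .broker import SCHEMAS, MemoryBroker, Message
from .dicom_index import SeriesIndex, SeriesRecord, build_series_index
from .flows import FlowDefinition, TriggerSpec, validate_flow
from .storage import BundleStore, pack_bundle, unpack_bundle

log = logging.getLogger(__name__)

__all__ = [
    "AssignedSeries",
    "FlowMatch",
    "DispatchRecord",
    "trigger_matches_series",
    "match_flow",
    "fingerprint_bundle",
    "FingerprinterService",
]


def trigger_matches_series(trigger: TriggerSpec, series: SeriesRecord) -> bool:
    """True iff every constraint keyword exists on the series and all its
    observed values satisfy the pattern.  A keyword missing from the
    series never matches."""
    for keyword, matcher in trigger.matchers().items():
        values = series.attribute_values(keyword)
        if not values:
            return False
        if not all(matcher(v) for v in values):
            return False
    return True


@dataclass(frozen=True)
class FlowMatch:
    """An injective trigger -> series assignment for one flow."""

    flow_id: str
    assignment: Mapping[str, SeriesRecord]
    matched_file_paths: tuple[str, ...]


@dataclass(frozen=True)
class AssignedSeries:
    series_instance_uid: str
    file_paths: tuple[str, ...]


@dataclass(frozen=True)
class DispatchRecord:
    """What the fingerprinter publishes per matched flow: the pruned
    bundle, the flow snapshot as matched, and the trigger assignment."""

    flow: FlowDefinition
    bundle_uid: str
    source_bundle_uid: str
    assignment: Mapping[str, AssignedSeries]

    @property
    def flow_id(self) -> str:
        return self.flow.flow_id

    @property
    def matched_file_paths(self) -> tuple[str, ...]:
        paths = {p for a in self.assignment.values() for p in a.file_paths}
        return tuple(sorted(paths))

    def to_body(self) -> dict:
        return {
            "schema": SCHEMAS["dispatch"],
            "flow_id": self.flow_id,
            "bundle_uid": self.bundle_uid,
            "source_bundle_uid": self.source_bundle_uid,
            "flow": self.flow.model_dump(exclude_none=True),
            "assignment": {
                name: {
                    "series_instance_uid": a.series_instance_uid,
                    "file_paths": list(a.file_paths),
                }
                for name, a in self.assignment.items()
            },
        }

    @classmethod
    def from_body(cls, body: Mapping) -> "DispatchRecord":
        return cls(
            flow=FlowDefinition.model_validate(body["flow"]),
            bundle_uid=body["bundle_uid"],
            source_bundle_uid=body["source_bundle_uid"],
            assignment={
                name: AssignedSeries(
                    series_instance_uid=a["series_instance_uid"],
                    file_paths=tuple(a["file_paths"]),
                )
                for name, a in body["assignment"].items()
            },
        )


def match_flow(index: SeriesIndex, flow: FlowDefinition) -> Optional[FlowMatch]:
    """Find an injective trigger -> series assignment, or None.

    Triggers are processed in name order and candidate series in UID
    order; depth-first backtracking therefore returns the
    lexicographically smallest assignment when several exist (a warning
    notes the ambiguity).
    """
    triggers = sorted(flow.triggers, key=lambda t: t.name)
    candidates: dict[str, list[SeriesRecord]] = {
        t.name: sorted(
            (s for s in index.series if trigger_matches_series(t, s)),
            key=lambda s: s.series_instance_uid,
        )
        for t in triggers
    }

    solutions: list[dict[str, SeriesRecord]] = []

    def extend(i: int, used: set[str], partial: dict[str, SeriesRecord]) -> None:
        if len(solutions) >= 2:  # first solution + ambiguity probe
            return
        if i == len(triggers):
            solutions.append(dict(partial))
            return
        t = triggers[i]
        for series in candidates[t.name]:
            if series.series_instance_uid in used:
                continue
            partial[t.name] = series
            used.add(series.series_instance_uid)
            extend(i + 1, used, partial)
            used.discard(series.series_instance_uid)
            del partial[t.name]

    extend(0, set(), {})
    if not solutions:
        return None
    if len(solutions) > 1:
        log.warning(
            "ambiguous trigger assignment flow_id=%s chosen=%s alternative=%s",
            flow.flow_id,
            {t: s.series_instance_uid for t, s in solutions[0].items()},
            {t: s.series_instance_uid for t, s in solutions[1].items()},
        )
    assignment = solutions[0]
    paths = sorted({p for s in assignment.values() for p in s.file_paths})
    return FlowMatch(
        flow_id=flow.flow_id,
        assignment=assignment,
        matched_file_paths=tuple(paths),
    )


def fingerprint_bundle(
    bundle_uid: str,
    flows: Sequence[FlowDefinition],
    store: BundleStore,
) -> list[DispatchRecord]:
    """Evaluate every flow against a stored bundle; one dispatch record
    per matched flow, each with its own pruned bundle.

    A storage miss propagates (retriable); an exception while evaluating
    one flow is logged and isolated so the remaining flows are still
    evaluated.
    """
    bundle = store.get(bundle_uid)  # miss propagates -> message redelivery
    files = unpack_bundle(bundle)
    by_path = dict(files)
    index = build_series_index(files)

    records: list[DispatchRecord] = []
    for flow in flows:
        try:
            report = validate_flow(flow)
            if not report.ok:
                log.error(
                    "skipping invalid flow flow_id=%s errors=%s",
                    flow.flow_id, sorted(report.codes()),
                )
                continue
            match = match_flow(index, flow)
            if match is None:
                continue
            pruned = pack_bundle(
                (p, by_path[p]) for p in match.matched_file_paths
            )
            pruned_uid = store.put(pruned)
            records.append(
                DispatchRecord(
                    flow=flow,
                    bundle_uid=pruned_uid,
                    source_bundle_uid=bundle_uid,
                    assignment={
                        name: AssignedSeries(
                            series_instance_uid=s.series_instance_uid,
                            file_paths=s.file_paths,
                        )
                        for name, s in match.assignment.items()
                    },
                )
            )
            log.info(
                "matched flow_id=%s source_bundle=%s pruned_bundle=%s files=%d",
                flow.flow_id, bundle_uid, pruned_uid, len(match.matched_file_paths),
            )
        except Exception:  # noqa: BLE001 - flows are evaluated independently
            log.exception(
                "error evaluating flow_id=%s source_bundle=%s",
                flow.flow_id, bundle_uid,
            )
    return records


class FingerprinterService:
    """Stateless service: consumes ingest messages, publishes one
    dispatch message per matched flow."""

    def __init__(
        self,
        broker: MemoryBroker,
        store: BundleStore,
        flows: Sequence[FlowDefinition],
    ) -> None:
        self.broker = broker
        self.store = store
        self.flows = list(flows)

    def attach(self) -> None:
        self.broker.subscribe("ingest", self.handle)

    def handle(self, message: Message) -> None:
        bundle_uid = message.body["bundle_uid"]
        for record in fingerprint_bundle(bundle_uid, self.flows, self.store):
            self.broker.publish("dispatch", record.to_body())
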