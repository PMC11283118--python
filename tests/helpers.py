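"""Shared generators and independent oracles for the test suite.

The oracles here are deliberately implemented apart from the library code
they check: acyclicity via networkx, stratification via a longest-path
recursion, injective trigger assignment via exhaustive permutation
enumeration.
"""

from __future__ import annotations

import itertools
import random
from typing import Optional

import networkx as nx

from dicomflow.dicom_index import SeriesIndex, SeriesRecord
from dicomflow.fingerprint import AssignedSeries, DispatchRecord
from dicomflow.flows import (
    DestinationSpec,
    FlowDefinition,
    ModelSpec,
    TriggerSpec,
)
from dicomflow.storage import BundleStore, pack_bundle

DEST = DestinationSpec(host="127.0.0.1", port=11113, ae_title="TPS")


# ---------------------------------------------------------------------------
# random flow graphs


def random_dag_flow(
    rng: random.Random,
    max_models: int = 10,
    n_triggers: int = 1,
    flow_id: str = "random_dag",
    image: str = "stub/identity",
) -> FlowDefinition:
    """A random *valid* flow: every model's inputs come from triggers or
    strictly earlier models, so the mount graph is acyclic by
    construction."""
    n = rng.randint(1, max_models)
    triggers = [
        TriggerSpec(name=f"trig{t}", constraints={"Modality": "CT"})
        for t in range(n_triggers)
    ]
    available = [t.name for t in triggers]
    models: list[ModelSpec] = []
    for i in range(n):
        k = rng.randint(1, min(2, len(available)))
        inputs = rng.sample(available, k)
        if i == 0 and not set(inputs) & {t.name for t in triggers}:
            inputs[0] = triggers[0].name
        outputs = [f"m{i}_out{j}" for j in range(rng.randint(1, 2))]
        models.append(
            ModelSpec(
                name=f"model{i:02d}",
                image=image,
                input_mounts=sorted(set(inputs)),
                output_mounts=outputs,
                device=rng.choice(["cpu", "gpu"]),
            )
        )
        available.extend(outputs)
    return FlowDefinition(
        flow_id=flow_id, triggers=triggers, models=models, destinations=[DEST]
    )


def random_mount_graph_flow(
    rng: random.Random,
    max_models: int = 8,
    flow_id: str = "random_graph",
) -> FlowDefinition:
    """A random flow whose mount graph may contain cycles or dangling
    mounts — raw material for validator-oracle comparison."""
    n = rng.randint(2, max_models)
    trigger = TriggerSpec(name="trig", constraints={"Modality": "CT"})
    outputs = {i: [f"o{i}_{j}" for j in range(rng.randint(1, 2))] for i in range(n)}
    models = []
    for i in range(n):
        pool = ["trig"] + [
            m for j in range(n) if j != i for m in outputs[j]
        ]
        if rng.random() < 0.15:
            pool.append(f"dangling{i}")
        inputs = sorted(set(rng.sample(pool, rng.randint(1, min(3, len(pool))))))
        models.append(
            ModelSpec(
                name=f"model{i:02d}",
                image="stub/identity",
                input_mounts=inputs,
                output_mounts=outputs[i],
            )
        )
    return FlowDefinition(
        flow_id=flow_id, triggers=[trigger], models=models, destinations=[DEST]
    )


def model_digraph(flow: FlowDefinition) -> nx.DiGraph:
    """networkx model-dependency graph (edge producer -> consumer)."""
    g = nx.DiGraph()
    g.add_nodes_from(m.name for m in flow.models)
    producer_of = {}
    for m in flow.models:
        for mount in m.output_mounts:
            producer_of.setdefault(mount, []).append(m.name)
    for m in flow.models:
        for mount in m.input_mounts:
            for producer in producer_of.get(mount, []):
                if producer != m.name:
                    g.add_edge(producer, m.name)
    return g


def oracle_is_acyclic(flow: FlowDefinition) -> bool:
    return nx.is_directed_acyclic_graph(model_digraph(flow))


def oracle_layer_index(flow: FlowDefinition) -> dict[str, int]:
    """Layer index as longest path from any source, computed by memoized
    recursion over the model graph (independent of Kahn stratification)."""
    g = model_digraph(flow)
    memo: dict[str, int] = {}

    def depth(node: str) -> int:
        if node not in memo:
            preds = list(g.predecessors(node))
            memo[node] = 0 if not preds else 1 + max(depth(p) for p in preds)
        return memo[node]

    return {m.name: depth(m.name) for m in flow.models}


def descendants_of(flow: FlowDefinition, model: str) -> set[str]:
    return set(nx.descendants(model_digraph(flow), model))


# ---------------------------------------------------------------------------
# random series indexes and the assignment oracle

MODALITIES = ("CT", "MR", "PT", "REG")
DESCRIPTIONS = ("T1 ax", "T2 cor", "planning", "CBCT daily", "wb pet")


def synthetic_series_record(
    rng: random.Random, uid_tail: int, attributes: Optional[dict] = None
) -> SeriesRecord:
    attrs = attributes or {
        "Modality": rng.choice(MODALITIES),
        "SeriesDescription": rng.choice(DESCRIPTIONS),
    }
    uid = f"1.2.826.0.1.3680043.8.498.{uid_tail}"
    return SeriesRecord(
        series_instance_uid=uid,
        study_instance_uid="1.2.826.0.1.3680043.8.498.9",
        attributes=dict(attrs),
        value_sets={k: frozenset([v]) for k, v in attrs.items()},
        file_paths=(f"s{uid_tail}/000.dcm",),
    )


def random_series_index(rng: random.Random, max_series: int = 8) -> SeriesIndex:
    n = rng.randint(0, max_series)
    return SeriesIndex(
        series=tuple(synthetic_series_record(rng, i) for i in range(n))
    )


def random_trigger_flow(
    rng: random.Random, max_triggers: int = 6, flow_id: str = "random_triggers"
) -> FlowDefinition:
    n = rng.randint(1, max_triggers)
    triggers = []
    for t in range(n):
        constraints = {"Modality": rng.choice(MODALITIES)}
        if rng.random() < 0.4:
            desc = rng.choice(DESCRIPTIONS)
            constraints["SeriesDescription"] = (
                f"/.*{desc.split()[0]}.*/" if rng.random() < 0.5 else desc
            )
        triggers.append(TriggerSpec(name=f"t{t}", constraints=constraints))
    model = ModelSpec(
        name="model",
        image="stub/identity",
        input_mounts=[t.name for t in triggers],
        output_mounts=["out"],
    )
    return FlowDefinition(
        flow_id=flow_id, triggers=triggers, models=[model], destinations=[DEST]
    )


def oracle_injective_match_exists(
    index: SeriesIndex, flow: FlowDefinition, matches_fn
) -> bool:
    """Exhaustively enumerate injective trigger -> series assignments.

    ``matches_fn(trigger, series) -> bool`` is the per-pair predicate; the
    oracle only adds the combinatorial search, so it checks the
    *assignment* logic independently of the matcher's backtracking."""
    triggers = flow.triggers
    series = list(index.series)
    if len(series) < len(triggers):
        return False
    for combo in itertools.permutations(series, len(triggers)):
        if all(matches_fn(t, s) for t, s in zip(triggers, combo)):
            return True
    return False


# ---------------------------------------------------------------------------
# scheduler-side helpers


def make_dispatch(
    flow: FlowDefinition,
    store: BundleStore,
    files_per_trigger: int = 2,
    source_tag: str = "src",
) -> DispatchRecord:
    """Build a dispatch record with synthetic (non-DICOM) trigger files;
    the scheduler never parses file contents."""
    files: list[tuple[str, bytes]] = []
    assignment: dict[str, AssignedSeries] = {}
    for i, trigger in enumerate(flow.triggers):
        paths = []
        for j in range(files_per_trigger):
            path = f"{trigger.name}/f{j}.bin"
            files.append((path, f"{flow.flow_id}:{trigger.name}:{j}".encode()))
            paths.append(path)
        assignment[trigger.name] = AssignedSeries(
            series_instance_uid=f"1.2.826.0.1.3680043.8.498.{i}",
            file_paths=tuple(paths),
        )
    bundle_uid = store.put(pack_bundle(files))
    return DispatchRecord(
        flow=flow,
        bundle_uid=bundle_uid,
        source_bundle_uid=f"{source_tag}-{flow.flow_id}",
        assignment=assignment,
    )


def instant_success_result(job, store):
    """Simulated consumer: every declared output mount gets a one-file
    bundle derived from the job id."""
    from dicomflow.scheduler import ModelResult

    outputs = {
        mount: store.put(pack_bundle([(f"{mount}.bin", job.job_id.encode())]))
        for mount in job.model.output_mounts
    }
    return ModelResult(
        job_id=job.job_id,
        flow_instance_id=job.flow_instance_id,
        model_name=job.model.name,
        status="succeeded",
        outputs=outputs,
        exit_code=0,
    )


def run_flow_to_completion(scheduler, record, rng: random.Random):
    """Drive a dispatch through the scheduler with an instant-success
    consumer, completing ready jobs in random order.  Returns
    (execution order, final state)."""
    outcome = scheduler.register_dispatch(record)
    ready = list(outcome.jobs)
    order: list[str] = []
    final_uid = None
    while ready:
        job = ready.pop(rng.randrange(len(ready)))
        order.append(job.model.name)
        res = instant_success_result(job, scheduler.store)
        out = scheduler.on_model_result(res)
        ready.extend(out.jobs)
        if out.finished_bundle_uid:
            final_uid = out.finished_bundle_uid
    state = scheduler.state_store.load(record_instance_id(record))
    return order, state, final_uid


def record_instance_id(record: DispatchRecord) -> str:
    from dicomflow.scheduler import flow_instance_id_for

    return flow_instance_id_for(record.flow_id, record.source_bundle_uid)


# ---------------------------------------------------------------------------
# end-to-end recording helpers


def recording_flow(flow):
    """Rewrite a flow so every model runs the recording stub and announces
    its name through the job environment."""
    models = [
        m.model_copy(update={"image": "stub/record",
                             "env": {**m.env, "MODEL_NAME": m.name}})
        for m in flow.models
    ]
    return flow.model_copy(update={"models": models})


def recording_stub(order_list):
    """Stub model: records its MODEL_NAME, then acts as the identity."""
    from dicomflow.consumer import _identity_stub

    def fn(input_dirs, output_dirs, env):
        order_list.append(env["MODEL_NAME"])
        return _identity_stub(input_dirs, output_dirs, env)

    return fn
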