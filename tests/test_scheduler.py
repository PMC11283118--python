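"""DAG scheduling: ready-set emission, completion, retries, persistence."""

import random

import pytest

from dicomflow.flows import (
    FlowDefinition,
    ModelSpec,
    TriggerSpec,
)
from dicomflow.scheduler import (
    FileStateStore,
    ModelResult,
    Scheduler,
    flow_instance_id_for,
)
from dicomflow.storage import MemoryBundleStore, pack_bundle, unpack_bundle

from helpers import (
    DEST,
    instant_success_result,
    make_dispatch,
    oracle_layer_index,
    random_dag_flow,
    run_flow_to_completion,
)


def single_model_flow(device="cpu"):
    return FlowDefinition(
        flow_id="single",
        triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
        models=[ModelSpec(name="seg", image="stub/identity", device=device,
                          input_mounts=["ct"], output_mounts=["rtss"])],
        destinations=[DEST],
    )


def decomposed_flow():
    """One CPU registration container feeding five GPU predictors."""
    reg = ModelSpec(name="registration", image="i", device="cpu",
                    input_mounts=["ct"], output_mounts=["aligned"])
    preds = [
        ModelSpec(name=f"pred{k}", image="i", device="gpu",
                  input_mounts=["aligned"], output_mounts=[f"gtv{k}"])
        for k in range(1, 6)
    ]
    return FlowDefinition(
        flow_id="decomposed",
        triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
        models=[reg, *preds],
        destinations=[DEST],
    )


def diamond_flow():
    return FlowDefinition(
        flow_id="diamond",
        triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
        models=[
            ModelSpec(name="A", image="i", input_mounts=["ct"],
                      output_mounts=["a"]),
            ModelSpec(name="B", image="i", input_mounts=["a"],
                      output_mounts=["b"]),
            ModelSpec(name="C", image="i", input_mounts=["a"],
                      output_mounts=["c"]),
            ModelSpec(name="D", image="i", input_mounts=["b", "c"],
                      output_mounts=["d"]),
        ],
        destinations=[DEST],
    )


@pytest.fixture
def scheduler(store):
    return Scheduler(store)


class TestRegisterDispatch:
    def test_single_cpu_model_emits_one_job_on_cpu_queue(self, scheduler, store):
        record = make_dispatch(single_model_flow(), store)
        outcome = scheduler.register_dispatch(record)
        (job,) = outcome.jobs
        assert job.model.name == "seg"
        assert job.queue == "work.cpu"
        assert set(job.inputs) == {"ct"}

    def test_trigger_mounts_bound_per_trigger(self, scheduler, store):
        """Each trigger's series is packed as its own bundle so a
        multi-modality model addresses each input by mount name."""
        flow = FlowDefinition(
            flow_id="mm",
            triggers=[
                TriggerSpec(name="ct", constraints={"Modality": "CT"}),
                TriggerSpec(name="pet", constraints={"Modality": "PT"}),
            ],
            models=[ModelSpec(name="m", image="i",
                              input_mounts=["ct", "pet"], output_mounts=["o"])],
            destinations=[DEST],
        )
        record = make_dispatch(flow, store, files_per_trigger=2)
        (job,) = scheduler.register_dispatch(record).jobs
        for trigger in ("ct", "pet"):
            members = unpack_bundle(store.get(job.inputs[trigger]))
            assert [p for p, _ in members] == sorted(
                record.assignment[trigger].file_paths
            )

    def test_decomposed_shape_emits_only_registration(self, scheduler, store):
        record = make_dispatch(decomposed_flow(), store)
        outcome = scheduler.register_dispatch(record)
        assert [j.model.name for j in outcome.jobs] == ["registration"]
        assert outcome.state.model_status["pred3"] == "pending"
        assert {j.queue for j in outcome.jobs} == {"work.cpu"}

    def test_duplicate_dispatch_is_ignored(self, scheduler, store):
        record = make_dispatch(single_model_flow(), store)
        first = scheduler.register_dispatch(record)
        second = scheduler.register_dispatch(record)
        assert first.jobs and not second.jobs
        assert len(scheduler.state_store.all_states()) == 1


class TestOnModelResult:
    def test_chain_result_unlocks_next_model(self, scheduler, store):
        flow = FlowDefinition(
            flow_id="chain",
            triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
            models=[
                ModelSpec(name="A", image="i", input_mounts=["ct"],
                          output_mounts=["m1"]),
                ModelSpec(name="B", image="i", input_mounts=["m1"],
                          output_mounts=["m2"]),
            ],
            destinations=[DEST],
        )
        record = make_dispatch(flow, store)
        (job_a,) = scheduler.register_dispatch(record).jobs
        outcome = scheduler.on_model_result(instant_success_result(job_a, store))
        assert [j.model.name for j in outcome.jobs] == ["B"]
        assert outcome.finished_bundle_uid is None

    def test_diamond_join_emits_exactly_once_in_both_orders(self, store):
        """D must run only after both B and C, and exactly once, whatever
        the completion order of the independent branch."""
        for b_first in (True, False):
            scheduler = Scheduler(MemoryBundleStore())
            record = make_dispatch(diamond_flow(), scheduler.store)
            (job_a,) = scheduler.register_dispatch(record).jobs
            out_a = scheduler.on_model_result(
                instant_success_result(job_a, scheduler.store))
            jobs = {j.model.name: j for j in out_a.jobs}
            assert set(jobs) == {"B", "C"}
            first, second = ("B", "C") if b_first else ("C", "B")
            emitted = []
            out1 = scheduler.on_model_result(
                instant_success_result(jobs[first], scheduler.store))
            emitted += [j.model.name for j in out1.jobs]
            assert "D" not in emitted  # join not complete yet
            out2 = scheduler.on_model_result(
                instant_success_result(jobs[second], scheduler.store))
            emitted += [j.model.name for j in out2.jobs]
            assert emitted.count("D") == 1

    def test_unknown_job_and_duplicate_results_dropped(self, scheduler, store):
        record = make_dispatch(single_model_flow(), store)
        (job,) = scheduler.register_dispatch(record).jobs
        ghost = ModelResult(job_id="nope", flow_instance_id=job.flow_instance_id,
                            model_name="seg", status="succeeded")
        assert scheduler.on_model_result(ghost).jobs == ()
        done = instant_success_result(job, store)
        first = scheduler.on_model_result(done)
        assert first.finished_bundle_uid is not None
        replay = scheduler.on_model_result(done)
        assert replay.jobs == () and replay.finished_bundle_uid is None

    def test_failed_model_fails_flow_and_blocks_downstream(self, store):
        scheduler = Scheduler(store, retry_limit=0)
        record = make_dispatch(decomposed_flow(), store)
        (job,) = scheduler.register_dispatch(record).jobs
        failure = ModelResult(
            job_id=job.job_id, flow_instance_id=job.flow_instance_id,
            model_name="registration", status="failed", exit_code=9,
        )
        outcome = scheduler.on_model_result(failure)
        assert outcome.flow_failed and outcome.jobs == ()
        state = outcome.state
        assert state.status == "failed"
        assert all(state.model_status[f"pred{k}"] == "pending"
                   for k in range(1, 6))

    def test_retry_budget_consumed_before_failing(self, store):
        scheduler = Scheduler(store, retry_limit=1)
        record = make_dispatch(single_model_flow(), store)
        (job1,) = scheduler.register_dispatch(record).jobs

        def fail(job):
            return ModelResult(job_id=job.job_id,
                               flow_instance_id=job.flow_instance_id,
                               model_name=job.model.name, status="failed",
                               exit_code=1)

        retry = scheduler.on_model_result(fail(job1))
        (job2,) = retry.jobs
        assert job2.attempt == 2 and not retry.flow_failed
        final = scheduler.on_model_result(fail(job2))
        assert final.flow_failed

    def test_random_dags_execute_every_model_once_in_topological_order(self):
        """Instant-success consumer over 60 random DAGs: execution count
        equals model count and every order respects the precedence
        relation (independent longest-path verifier)."""
        rng = random.Random(5)
        for i in range(60):
            store = MemoryBundleStore()
            scheduler = Scheduler(store)
            flow = random_dag_flow(rng, flow_id=f"r{i}")
            record = make_dispatch(flow, store)
            order, state, final_uid = run_flow_to_completion(
                scheduler, record, rng)
            assert sorted(order) == sorted(m.name for m in flow.models)
            layer = oracle_layer_index(flow)
            positions = {name: k for k, name in enumerate(order)}
            for m in flow.models:
                for pred_mount in m.input_mounts:
                    producers = [p.name for p in flow.models
                                 if pred_mount in p.output_mounts]
                    for p in producers:
                        assert positions[p] < positions[m.name]
            assert layer  # oracle engaged
            assert state.finished and final_uid


class TestQueueSelection:
    @pytest.mark.parametrize("device, queue", [("gpu", "work.gpu"),
                                               ("cpu", "work.cpu")])
    def test_device_routing(self, device, queue):
        model = ModelSpec(name="m", image="i", device=device,
                          input_mounts=["a"], output_mounts=["b"])
        assert Scheduler.select_queue(model) == queue

    def test_device_default_is_cpu(self):
        model = ModelSpec(name="m", image="i",
                          input_mounts=["a"], output_mounts=["b"])
        assert Scheduler.select_queue(model) == "work.cpu"


class TestFinalBundle:
    def test_single_sink_passthrough(self, scheduler, store):
        record = make_dispatch(single_model_flow(), store)
        (job,) = scheduler.register_dispatch(record).jobs
        payload = pack_bundle([("structs.dcm", b"RTSS-BYTES")])
        uid = store.put(payload)
        result = ModelResult(
            job_id=job.job_id, flow_instance_id=job.flow_instance_id,
            model_name="seg", status="succeeded", outputs={"rtss": uid},
        )
        outcome = scheduler.on_model_result(result)
        final = unpack_bundle(store.get(outcome.finished_bundle_uid))
        assert final == [("structs.dcm", b"RTSS-BYTES")]

    def test_clashing_sink_paths_kept_under_mount_prefixes(self, store):
        flow = FlowDefinition(
            flow_id="clash",
            triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
            models=[
                ModelSpec(name="A", image="i", input_mounts=["ct"],
                          output_mounts=["s1"]),
                ModelSpec(name="B", image="i", input_mounts=["ct"],
                          output_mounts=["s2"]),
            ],
            destinations=[DEST],
        )
        scheduler = Scheduler(store)
        record = make_dispatch(flow, store)
        jobs = scheduler.register_dispatch(record).jobs
        final_uid = None
        for job, mount, body in zip(jobs, ("s1", "s2"), (b"one", b"two")):
            uid = store.put(pack_bundle([("out.dcm", body)]))
            outcome = scheduler.on_model_result(ModelResult(
                job_id=job.job_id, flow_instance_id=job.flow_instance_id,
                model_name=job.model.name, status="succeeded",
                outputs={mount: uid},
            ))
            final_uid = outcome.finished_bundle_uid or final_uid
        final = dict(unpack_bundle(store.get(final_uid)))
        assert final == {"s1/out.dcm": b"one", "s2/out.dcm": b"two"}

    def test_missing_output_mount_fails_result(self, scheduler, store):
        record = make_dispatch(single_model_flow(), store)
        (job,) = scheduler.register_dispatch(record).jobs
        empty = ModelResult(job_id=job.job_id,
                            flow_instance_id=job.flow_instance_id,
                            model_name="seg", status="succeeded", outputs={})
        outcome = scheduler.on_model_result(empty)
        # missing outputs consume the retry, then fail the flow
        (retry_job,) = outcome.jobs
        final = scheduler.on_model_result(ModelResult(
            job_id=retry_job.job_id, flow_instance_id=job.flow_instance_id,
            model_name="seg", status="succeeded", outputs={}))
        assert final.flow_failed


class TestSweepStale:
    def make(self, store, timeout=10.0):
        clock = {"now": 0.0}
        flow = single_model_flow().model_copy(update={
            "models": [single_model_flow().models[0].model_copy(
                update={"timeout": timeout})]
        })
        scheduler = Scheduler(store, retry_limit=1, clock=lambda: clock["now"])
        record = make_dispatch(flow, store)
        (job,) = scheduler.register_dispatch(record).jobs
        return scheduler, clock, job

    def test_job_within_timeout_untouched(self, store):
        scheduler, clock, _ = self.make(store)
        clock["now"] = 5.0
        assert scheduler.sweep_stale() == []

    def test_stale_job_requeued_with_incremented_attempt(self, store):
        scheduler, clock, job = self.make(store)
        clock["now"] = 11.0
        (requeued,) = scheduler.sweep_stale()
        assert requeued.model.name == job.model.name
        assert requeued.attempt == 2

    def test_stale_job_past_budget_fails_flow(self, store):
        scheduler, clock, _ = self.make(store)
        clock["now"] = 11.0
        scheduler.sweep_stale()
        clock["now"] = 22.0
        assert scheduler.sweep_stale() == []
        (state,) = scheduler.state_store.all_states()
        assert state.status == "failed"

    def test_sweep_is_idempotent(self, store):
        scheduler, clock, _ = self.make(store)
        clock["now"] = 11.0
        first = scheduler.sweep_stale()
        second = scheduler.sweep_stale()
        assert len(first) == 1 and second == []


class TestPersistence:
    def test_state_survives_scheduler_restart(self, store, tmp_path):
        """Kill the scheduler after the first result, restart from the
        file-backed store, and the flow still completes."""
        state_root = tmp_path / "state"
        sched1 = Scheduler(store, FileStateStore(state_root))
        record = make_dispatch(decomposed_flow(), store)
        (reg_job,) = sched1.register_dispatch(record).jobs
        out = sched1.on_model_result(instant_success_result(reg_job, store))
        assert len(out.jobs) == 5
        del sched1  # "crash"

        sched2 = Scheduler(store, FileStateStore(state_root))
        final_uid = None
        for job in out.jobs:
            res = sched2.on_model_result(instant_success_result(job, store))
            final_uid = res.finished_bundle_uid or final_uid
        assert final_uid is not None
        state = sched2.state_store.load(
            flow_instance_id_for(record.flow_id, record.source_bundle_uid))
        assert state.finished

    def test_flow_state_json_round_trip(self, store):
        from dicomflow.scheduler import FlowState

        scheduler = Scheduler(store)
        record = make_dispatch(diamond_flow(), store)
        state = scheduler.register_dispatch(record).state
        assert FlowState.from_json(state.to_json()) == state
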