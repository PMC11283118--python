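"""Trigger matching, injective assignment, and bundle pruning."""

import hashlib
import random

from dicomflow.dicom_index import SeriesIndex, build_series_index
from dicomflow.fingerprint import (
    fingerprint_bundle,
    match_flow,
    trigger_matches_series,
)
from dicomflow.fixtures import make_series
from dicomflow.flows import (
    FlowDefinition,
    ModelSpec,
    TriggerSpec,
)
from dicomflow.storage import MemoryBundleStore, pack_bundle, unpack_bundle

from helpers import (
    DEST,
    oracle_injective_match_exists,
    random_series_index,
    random_trigger_flow,
    synthetic_series_record,
)


def ct_flow(flow_id="ct_flow"):
    return FlowDefinition(
        flow_id=flow_id,
        triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
        models=[ModelSpec(name="m", image="stub/identity",
                          input_mounts=["ct"], output_mounts=["out"])],
        destinations=[DEST],
    )


class TestTriggerMatch:
    def trigger(self, **constraints):
        return TriggerSpec(name="t", constraints=constraints)

    def series(self, rng=None, **attrs):
        return synthetic_series_record(random.Random(0), 1, attributes=attrs)

    def test_exact_modality_match(self):
        assert trigger_matches_series(
            self.trigger(Modality="CT"), self.series(Modality="CT")
        )

    def test_modality_mismatch(self):
        assert not trigger_matches_series(
            self.trigger(Modality="CT"), self.series(Modality="MR")
        )

    def test_missing_keyword_never_matches(self):
        assert not trigger_matches_series(
            self.trigger(Modality="CT", SeriesDescription="x"),
            self.series(Modality="CT"),
        )

    def test_regex_on_t1_weighted_mr(self):
        t1 = self.trigger(Modality="MR", SeriesDescription="/.*T1.*/")
        assert trigger_matches_series(
            t1, self.series(Modality="MR", SeriesDescription="ax T1 post")
        )
        assert not trigger_matches_series(
            t1, self.series(Modality="MR", SeriesDescription="ax T2")
        )

    def test_exact_match_ignores_trailing_spaces(self):
        assert trigger_matches_series(
            self.trigger(Modality="CT "), self.series(Modality="CT")
        )


class TestMatchFlow:
    def test_empty_index_gives_none(self):
        assert match_flow(SeriesIndex(), ct_flow()) is None

    def test_sct_three_trigger_assignment(self, scenarios):
        """Planning CT, CBCT-flagged CT and registration object are each
        claimed by their own trigger, injectively."""
        scenario = scenarios["sct"]
        index = build_series_index(scenario.files)
        match = match_flow(index, scenario.flows[0])
        assert match is not None
        got = {t: s.series_instance_uid for t, s in match.assignment.items()}
        assert got == scenario.expected_matches["sct_generation"]

    def test_two_of_three_series_do_not_match(self, scenarios):
        scenario = scenarios["sct"]
        flow = scenario.flows[0]
        index_full = build_series_index(scenario.files)
        for leave_out in scenario.series_uids.values():
            subset = SeriesIndex(series=tuple(
                s for s in index_full.series
                if s.series_instance_uid != leave_out
            ))
            assert match_flow(subset, flow) is None

    def test_injectivity_two_ct_triggers_one_series(self):
        flow = FlowDefinition(
            flow_id="two_ct",
            triggers=[
                TriggerSpec(name="a", constraints={"Modality": "CT"}),
                TriggerSpec(name="b", constraints={"Modality": "CT"}),
            ],
            models=[ModelSpec(name="m", image="i",
                              input_mounts=["a", "b"], output_mounts=["o"])],
            destinations=[DEST],
        )
        one_ct = SeriesIndex(series=(
            synthetic_series_record(random.Random(0), 1,
                                    attributes={"Modality": "CT"}),
        ))
        assert match_flow(one_ct, flow) is None
        two_ct = SeriesIndex(series=tuple(
            synthetic_series_record(random.Random(0), i,
                                    attributes={"Modality": "CT"})
            for i in (1, 2)
        ))
        match = match_flow(two_ct, flow)
        assert match is not None
        uids = {s.series_instance_uid for s in match.assignment.values()}
        assert len(uids) == 2

    def test_deterministic_lexicographic_choice(self):
        """With several valid assignments the (trigger name, series UID)
        lexicographically smallest one is chosen."""
        flow = FlowDefinition(
            flow_id="amb",
            triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
            models=[ModelSpec(name="m", image="i",
                              input_mounts=["ct"], output_mounts=["o"])],
            destinations=[DEST],
        )
        series = tuple(
            synthetic_series_record(random.Random(0), i,
                                    attributes={"Modality": "CT"})
            for i in (5, 2, 9)
        )
        match = match_flow(SeriesIndex(series=series), flow)
        assert match.assignment["ct"].series_instance_uid.endswith(".2")

    def test_existence_equals_exhaustive_oracle(self):
        """Matcher verdict equals brute-force injective-assignment
        enumeration on 200 random (index, flow) instances."""
        rng = random.Random(31)
        checked_positive = 0
        for _ in range(200):
            index = random_series_index(rng)
            flow = random_trigger_flow(rng)
            got = match_flow(index, flow)
            expected = oracle_injective_match_exists(
                index, flow, trigger_matches_series
            )
            assert (got is not None) == expected
            if got is not None:
                checked_positive += 1
                # assignment must be injective and satisfy every trigger
                uids = [s.series_instance_uid for s in got.assignment.values()]
                assert len(set(uids)) == len(uids)
                by_name = {t.name: t for t in flow.triggers}
                assert set(got.assignment) == set(by_name)
                for name, series in got.assignment.items():
                    assert trigger_matches_series(by_name[name], series)
        assert checked_positive > 10  # the sample exercises both verdicts

    def test_monotonicity_adding_series_never_unmatches(self):
        rng = random.Random(17)
        for _ in range(50):
            index = random_series_index(rng, max_series=5)
            flow = random_trigger_flow(rng, max_triggers=3)
            if match_flow(index, flow) is None:
                continue
            grown = SeriesIndex(series=index.series + (
                synthetic_series_record(rng, 1000 + rng.randrange(100)),
            ))
            assert match_flow(grown, flow) is not None


class TestFingerprintBundle:
    def make_store_with(self, files):
        store = MemoryBundleStore()
        uid = store.put(pack_bundle(files))
        return store, uid

    def test_single_flow_matches(self):
        store, uid = self.make_store_with(make_series("CT", 3, seed=1))
        mr_flow = ct_flow("mr_flow").model_copy(update={
            "triggers": [TriggerSpec(name="ct", constraints={"Modality": "MR"})]
        })
        records = fingerprint_bundle(uid, [ct_flow(), mr_flow], store)
        assert [r.flow_id for r in records] == ["ct_flow"]

    def test_multi_flow_fan_out(self):
        store, uid = self.make_store_with(make_series("CT", 3, seed=1))
        records = fingerprint_bundle(uid, [ct_flow("a"), ct_flow("b")], store)
        assert sorted(r.flow_id for r in records) == ["a", "b"]
        assert len({r.bundle_uid for r in records}) == 2  # own pruned bundle each

    def test_pruned_bundle_holds_exactly_matched_files_bit_identical(self):
        ct = make_series("CT", 3, seed=1)
        mr = make_series("MR", 2, seed=2)
        store, uid = self.make_store_with(ct + mr)
        (record,) = fingerprint_bundle(uid, [ct_flow()], store)
        pruned = dict(unpack_bundle(store.get(record.bundle_uid)))
        assert pruned == dict(ct)  # set equality and byte identity
        checks = {p: hashlib.sha256(d).hexdigest() for p, d in ct}
        assert {p: hashlib.sha256(d).hexdigest()
                for p, d in pruned.items()} == checks

    def test_per_flow_errors_are_isolated(self):
        store, uid = self.make_store_with(make_series("CT", 2, seed=1))
        cyclic = FlowDefinition(
            flow_id="cyclic",
            triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
            models=[
                ModelSpec(name="A", image="i", input_mounts=["m2"],
                          output_mounts=["m1"]),
                ModelSpec(name="B", image="i", input_mounts=["m1"],
                          output_mounts=["m2"]),
            ],
            destinations=[DEST],
        )
        records = fingerprint_bundle(uid, [cyclic, ct_flow()], store)
        assert [r.flow_id for r in records] == ["ct_flow"]

    def test_determinism_modulo_bundle_uids(self):
        files = make_series("CT", 3, seed=1) + make_series("MR", 2, seed=2)
        store, uid = self.make_store_with(files)
        r1 = fingerprint_bundle(uid, [ct_flow()], store)
        r2 = fingerprint_bundle(uid, [ct_flow()], store)
        strip = lambda recs: [
            (r.flow_id, r.source_bundle_uid, dict(r.assignment)) for r in recs
        ]
        assert strip(r1) == strip(r2)

    def test_dispatch_record_body_round_trip(self):
        from dicomflow.fingerprint import DispatchRecord

        store, uid = self.make_store_with(make_series("CT", 2, seed=1))
        (record,) = fingerprint_bundle(uid, [ct_flow()], store)
        assert DispatchRecord.from_body(record.to_body()) == record
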