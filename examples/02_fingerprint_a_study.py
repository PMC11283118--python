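"""Fingerprint a synthetic study: which flows do the received series
trigger, and which series is assigned to which trigger?

Uses the synthetic-CT scenario: a planning CT, a CBCT-flagged CT and a
rigid spatial registration object.  Two series share Modality=CT, so the
matcher must assign them *injectively* — the CBCT trigger's ImageType
constraint claims one, the plain CT trigger gets the other.
"""

from dicomflow import build_series_index, make_scenario, match_flow

scenario = make_scenario("sct", seed=11)
index = build_series_index(scenario.files)
print(f"received {index.n_files} files in {len(index.series)} series:")
for series in index.series:
    print(f"  {series.attributes.get('Modality'):8s} "
          f"{series.attributes.get('SeriesDescription', '')!r:28s} "
          f"{len(series.file_paths)} file(s)")

(flow,) = scenario.flows
match = match_flow(index, flow)
print(f"\nflow {flow.flow_id!r} matched: {match is not None}")
for trigger, series in sorted(match.assignment.items()):
    print(f"  trigger {trigger!r:7s} <- series {series.series_instance_uid}")

# Dropping any one of the three series makes the match impossible: every
# trigger of a flow must be satisfied by its own series before the flow
# fires.
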