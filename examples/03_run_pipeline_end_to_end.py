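"""Run the full stack end to end in one process.

A study is pushed into the ingress SCP, the fingerprinter matches it, the
scheduler queues the model DAG, stub workers execute it, and the egress
SCU delivers the result to a fixture destination SCP (a PACS/TPS
stand-in).  ``pump_until_idle`` drains the message queues
deterministically, so the whole asynchronous pipeline runs as a
sequential program.
"""

from dicomflow import StackConfig, build_stack, make_scenario

scenario = make_scenario("multi_modality", seed=11)
stack = build_stack(StackConfig(), flows=list(scenario.flows))

stack.send_study(scenario.files)          # one DICOM association
deliveries = stack.pump_until_idle()      # drain every queue

print(f"pumped {deliveries} messages to quiescence")
for state in stack.dump_state():
    print(f"flow {state['flow']['flow_id']!r}: {state['status']}, "
          f"models: {state['model_status']}")
for (host, port), files in stack.destination_files().items():
    print(f"destination {host}:{port} received {len(files)} files")

# The 10 input files (CT+PET+T1+T2) pass through the CPU registration
# model, then each of the five GPU predictors sinks a copy: the
# destination receives 5 x 10 = 50 files, checksum-identical to the model
# outputs.
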