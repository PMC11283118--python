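# dicomflow

Message-driven orchestration of containerized models on DICOM studies:
tag-based flow triggering, DAG job scheduling across CPU/GPU work queues,
and DICOM delivery of the results.

## The problem

Radiotherapy and radiology departments increasingly run in-house models —
auto-segmentation networks, synthetic-CT generators, dose predictors —
that must slot into clinical DICOM traffic: images are pushed from a
scanner or treatment planning system (TPS), the right model(s) must run on
the right series, and the resulting DICOM objects (e.g. RT structure
sets) must land back in the TPS or PACS. `dicomflow` is a deployment
framework for exactly that: any piece of software that can be wrapped in
a container and consumes/produces DICOM files can be deployed by writing
one declarative *flow* file, with no coupling to a particular TPS.

## The model

A **flow** has three parts:

* **triggers** — DICOM attribute constraints (exact values or anchored
  regular expressions, e.g. `Modality: CT`,
  `SeriesDescription: /.*T1.*/`). A flow fires when every trigger can be
  assigned its *own* series from one received study (an injective
  trigger→series assignment);
* **models** — container images with named input/output **mounts**.
  Mounts are the edges of a directed acyclic graph whose nodes are the
  models: a model becomes runnable the moment all of its input mounts are
  bound, so independent models execute concurrently on CPU and GPU work
  queues;
* **destinations** — DICOM nodes (host, port, AE title) that receive the
  flow's terminal ("sink") outputs via C-STORE.

The runtime is a set of microservices joined by message queues, with all
files exchanged as checksummed tar bundles in a content store: a storage
SCP ingests associations, a fingerprinter matches studies against flows,
a scheduler (the only stateful service) tracks each flow instance's mount
table and queues ready models, a worker pool executes containers, and a
storage SCU delivers the final bundle. Messaging is at-least-once; every
service is idempotent under redelivery, and repeatedly failing messages
are dead-lettered rather than silently lost.

## Worked example

```python
from dicomflow import StackConfig, build_stack, make_scenario

scenario = make_scenario("multi_modality", seed=11)   # CT+PET+T1+T2 study
stack = build_stack(StackConfig(), flows=list(scenario.flows))
stack.send_study(scenario.files)      # one DICOM association into the SCP
stack.pump_until_idle()               # drain every queue deterministically
print(stack.dump_state()[0]["status"])
print({k: len(v) for k, v in stack.destination_files().items()})
```

prints

```
finished
{('127.0.0.1', 11113): 50}
```

The four-modality study (10 files) triggers a flow whose DAG is one CPU
registration model feeding five GPU prediction models; each predictor
sinks a copy of its input, so the fixture destination SCP receives
5 × 10 = 50 files, checksum-identical to the model outputs. The scripts
in `examples/` walk through each capability (flow validation and
layering, fingerprinting, the end-to-end run, replay/restart resilience),
and the same runs are available from the shell:

```bash
dicomflow demo multi_modality --seed 11
dicomflow flow validate myflows/     # exit 0 iff all valid
dicomflow fixtures generate sct --out /tmp/sct
dicomflow fingerprint /tmp/sct/dicom --flows /tmp/sct/flows
```

## Scope notes

The models themselves are out of scope: the framework executes whatever
container (or, in tests, registered stub executable) a flow names. DICOM
networking runs over an in-process association transport implementing
the SCP/SCU contract; see `docs/methods.md` for the design and its
limitations.
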