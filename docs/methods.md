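# Methods

This note records the design of `dicomflow`: the orchestration model, the
choices made where the design was genuinely open, the numerical/protocol
conventions, what the synthetic fixtures do and do not emulate, and known
limitations.

## Orchestration model

The unit of deployment is the **flow**: triggers (DICOM attribute
constraints), a DAG of containerized **models** connected by named
**mounts**, and DICOM **destinations**. Services communicate only
through named queues (`ingest`, `dispatch`, `work.cpu`, `work.gpu`,
`result`, `egress`) and a content store of tar bundles; a bundle UID in a
message is the only reference to data. The SCP, fingerprinter, workers
and SCU are stateless; the scheduler is the single stateful service, and
its state store is a pluggable key-value contract (in-memory and
one-JSON-file-per-flow-instance implementations ship).

### Trigger matching

A trigger matches a series when every constrained keyword exists on the
series and **all** observed values satisfy the pattern. Values are
compared after stripping trailing spaces (DICOM padding); multi-valued
elements such as ImageType are compared as the `\`-joined string. A bare
pattern is an exact match; `/…/` is an anchored regular expression
(compiled at flow load, so a bad regex is a configuration error, not a
match-time one). Matching is at *series* granularity — the clinical
inputs (CT/PET/MR series, registration objects) are series-shaped — and a
flow fires only if an **injective** trigger→series assignment exists
within one received bundle. When several assignments exist, the
lexicographically smallest by (trigger name, SeriesInstanceUID) is chosen
and the ambiguity is logged; determinism here is what makes matching
auditable and testable. Cross-association accumulation is deliberately
not performed: all series of a flow must arrive in one association.

### Scheduling

Each flow instance keeps a mount table (mount name → bundle UID).
Trigger mounts are pre-filled at registration, each trigger's series
packed as its *own* bundle so a multi-modality model addresses every
input by mount name. A model is queued exactly when all its input mounts
are bound; `device: gpu` routes to `work.gpu`, otherwise `work.cpu`.
Completion requires every model to succeed (including models whose
outputs feed nothing). Sink mounts default to output mounts with no
downstream consumer; the final bundle is their union, with paths that
occur in more than one sink bundle kept under a `<mount>/` prefix.

Idempotency under at-least-once messaging: `flow_instance_id` is a
SHA-256 hash of (flow_id, source bundle UID), so redelivered dispatches
register nothing; results for unknown jobs or already-done models are
dropped; state is persisted after every transition so a restarted
scheduler resumes mid-flow. Failure policy: a failed (or timed-out,
via `sweep_stale`) model is retried once by default, then the flow is
failed and downstream models are never queued. Both the retry budget
and per-model timeouts (default 1 h) are configurable per flow file.

### Execution contract for models

Workers stage inputs read-only at per-mount directories (`/input/<mount>`
in the container runner), create empty output directories, and export
`INPUT_<MOUNT>`/`OUTPUT_<MOUNT>` environment variables. Exit 0 with
every declared output mount non-empty is success; nonzero exit, timeout,
or an empty declared output is a *model* failure (acknowledged, counted
against the retry budget), while storage misses and engine failures are
*infrastructure* failures (message nack'd for redelivery, dead-lettered
after 3 attempts). Three runners implement the contract: a container
runner shelling out to the `docker` CLI (GPU requests passed via
`--gpus`, the container-toolkit convention), a local-process runner, and
a stub runner mapping image names to registered Python callables — the
test and demo vehicle, so the whole stack is exercisable without a
container engine.

## Protocol and format conventions

* **Bundles** are POSIX (ustar) tar archives with a `_manifest.json`
  member recording per-file SHA-256 checksums; packing sorts members and
  zeroes timestamps, so identical logical content is byte-identical.
  Unpacking verifies every checksum. No deduplication or garbage
  collection in v1.
* **Association = bundle boundary**: everything C-STOREd within one
  association becomes one bundle on release; an aborted association
  discards its files (the sender retries). Empty associations publish
  nothing.
* **Message bodies** are JSON with a `schema` field (`ingest.v1`,
  `dispatch.v1`, `work.v1`, `result.v1`, `egress.v1`). Work messages
  carry the full model spec, keeping workers stateless.
* **DICOM transport**: the SCP/SCU services run over an in-process
  association transport (`DicomNetwork`) that models the lifecycle the
  stack depends on — association open (refused when no listener),
  repeated C-STOREs, release/abort. This keeps the edge services, their
  error contracts, and end-to-end byte-fidelity checks fully testable in
  one process; a wire-protocol (DICOM Upper Layer/DIMSE) backend would
  implement the same four-method surface. Until then the package does
  not speak TCP to real modalities — the primary known limitation.
* **Broker**: the deterministic in-memory backend is the reference
  implementation of the publish/subscribe contract (FIFO per queue,
  round-robin work-sharing, redelivery with incremented delivery count,
  per-queue dead-letter queues, `max_deliveries` 3). It is
  single-process; a networked backend (e.g. AMQP) would slot behind the
  same contract and is what multi-host scaling requires.

## All-in-one harness

Because messages flow asynchronously in a real deployment, the state
space is untestable by observation alone. The all-in-one stack wires
every service to the in-memory broker and pumps messages explicitly:
`pump_until_idle()` drains all queues to quiescence (bounded by a step
budget, turning livelock into an error). Every end-to-end property —
byte fidelity, replay invariance, restart recovery, worker-count
invariance — is asserted on this deterministic harness; multi-process
deployment is exactly the same services on a networked broker.

## Synthetic fixtures

`make_series` emits valid Part-10 files: 8×8 16-bit images for CT/MR/PT,
pixel-less spatial registration and RT structure set objects, fixed dates
and deterministic UIDs per seed (byte-identical regeneration). CBCT is
encoded as Modality=CT with `CBCT` in ImageType — DICOM has no CBCT
modality code and this mirrors common vendor practice — which makes the
synthetic-CT scenario exercise multi-constraint triggers and injective
assignment. Three presets mirror deployments of increasing complexity:
`single_modality` (one CT series → one segmentation model),
`multi_modality` (CT+PET+T1+T2 → CPU registration → five GPU predictors,
the decomposed five-fold ensemble), and `sct` (planning CT + CBCT +
rigid registration → synthetic-CT generator). Expected trigger
assignments are computed by construction, never by running the matcher,
so the presets double as ground truth.

What the fixtures do **not** emulate: anatomically meaningful pixel data,
vendor-private tags, non-trivial transfer syntaxes, malformed-but-
salvageable datasets, association-level timing. Passing tests therefore
demonstrate the orchestration semantics — matching, scheduling, delivery
fidelity, resilience — not robustness to the long tail of real-world
DICOM encoding variation.

## Test oracles and problem sizes

Every nontrivial verdict is cross-checked against an independently
implemented oracle: trigger-assignment existence against exhaustive
permutation enumeration (200 random instances, ≤6 triggers × ≤8 series);
DAG stratification and execution order against a networkx/longest-path
verifier (100 random flows of ≤10 models, run end to end with an
instant-success stub consumer); validator acyclicity against
`networkx.is_directed_acyclic_graph`. These sizes keep the default suite
and the acceptance script in the seconds range while covering the
combinatorial space densely; all randomness is seeded.

## Known limitations

* No real network I/O (DICOM or broker) — see transport/broker notes.
* No stateful multi-association study accumulation, no C-FIND/C-MOVE,
  no worklists, no TLS, no DICOMweb.
* One match per flow per bundle: multiple disjoint assignments in one
  study trigger one flow execution, not several.
* No cross-flow priorities or fair-share scheduling; no flow versioning.
* Egress redelivery may re-send files; receivers are assumed to tolerate
  duplicate SOP instances (standard PACS behavior) — documented, not
  enforced.
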