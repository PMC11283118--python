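"""Synthetic DICOM studies and flow scenarios.

Everything the stack needs for testing and demos is generated here: small
valid Part-10 files (8x8 pixel images for CT/MR/PT, pixel-less spatial
registration and RT structure set objects) and three named scenario
presets mirroring common radiotherapy deployments:

* ``single_modality`` — one CT series triggering one auto-segmentation
  model;
* ``multi_modality`` — CT + PET + T1- and T2-weighted MR triggering a
  CPU registration model that feeds five GPU prediction models (a
  five-fold ensemble decomposed into a DAG);
* ``sct`` — planning CT + CBCT-flagged CT + rigid registration object
  triggering a synthetic-CT generator.

Generation is deterministic given a seed (byte-identical files), and the
expected trigger assignment of every scenario is computed *by
construction* — never by running the fingerprinter — so scenarios double
as ground truth for matching tests.

CBCT series are encoded as Modality=CT with ``CBCT`` in ImageType (a
common vendor convention; DICOM has no CBCT modality code), which makes
the ``sct`` preset exercise multi-constraint triggers and injective
assignment of two CT series to two different triggers.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .flows import (
    DestinationSpec,
    FlowDefinition,
    ModelSpec,
    TriggerSpec,
    serialize_flow,
)

__all__ = [
    "SOP_CLASSES",
    "PRESETS",
    "SeriesSpec",
    "ScenarioSpec",
    "Scenario",
    "make_series",
    "make_scenario",
    "build_scenario",
    "write_scenario",
]

UID_ROOT = "1.2.826.0.1.3680043.8.498."  # pydicom's public test root
_IMPLEMENTATION_UID = UID_ROOT + "77770001"
_FIXED_DATE = "20240101"
_FIXED_TIME = "120000"

SOP_CLASSES: dict[str, str] = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "MR": "1.2.840.10008.5.1.4.1.1.4",
    "PT": "1.2.840.10008.5.1.4.1.1.128",
    "REG": "1.2.840.10008.5.1.4.1.1.66.1",
    "RTSTRUCT": "1.2.840.10008.5.1.4.1.1.481.3",
}

_IMAGE_MODALITIES = ("CT", "MR", "PT")

PRESETS = ("single_modality", "multi_modality", "sct")


def _uid(rng: random.Random) -> str:
    digits = str(rng.randrange(1, 10)) + "".join(
        str(rng.randrange(10)) for _ in range(15)
    )
    return UID_ROOT + digits


def _base_dataset(
    modality: str,
    sop_class: str,
    rng: random.Random,
    study_uid: str,
    series_uid: str,
) -> FileDataset:
    sop_uid = _uid(rng)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _IMPLEMENTATION_UID
    meta.ImplementationVersionName = "DICOMFLOW_FIX"

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = modality
    ds.PatientName = "Fixture^Phantom"
    ds.PatientID = "FIX0001"
    ds.StudyDate = _FIXED_DATE
    ds.StudyTime = _FIXED_TIME
    ds.ContentDate = _FIXED_DATE
    ds.ContentTime = _FIXED_TIME
    ds.Manufacturer = "dicomflow-fixtures"
    ds.StationName = "FIXSTATION"
    return ds


def _add_pixels(ds: FileDataset, rng: random.Random) -> None:
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = 8
    ds.Columns = 8
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = bytes(rng.randrange(256) for _ in range(8 * 8 * 2))


def _registration_payload(ds: FileDataset, rng: random.Random) -> None:
    ds.ImageType = ["DERIVED", "SECONDARY"]
    reg_item = Dataset()
    reg_item.FrameOfReferenceUID = _uid(rng)
    matrix_item = Dataset()
    matrix_item.FrameOfReferenceTransformationMatrixType = "RIGID"
    matrix_item.FrameOfReferenceTransformationMatrix = [
        1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1
    ]
    matrix_seq_item = Dataset()
    matrix_seq_item.MatrixSequence = [matrix_item]
    reg_item.MatrixRegistrationSequence = [matrix_seq_item]
    ds.RegistrationSequence = [reg_item]


def _rtstruct_payload(ds: FileDataset, rng: random.Random) -> None:
    ds.StructureSetLabel = "FixtureStructs"
    ds.StructureSetDate = _FIXED_DATE
    ds.StructureSetTime = _FIXED_TIME
    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = "Body"
    roi.ReferencedFrameOfReferenceUID = _uid(rng)
    ds.StructureSetROISequence = [roi]


def make_series(
    modality: str,
    n_slices: int = 1,
    tag_overrides: Optional[Mapping[str, object]] = None,
    seed: int = 0,
    study_instance_uid: Optional[str] = None,
) -> list[tuple[str, bytes]]:
    """Generate one synthetic series as ``(relative_path, bytes)`` pairs.

    All files share one SeriesInstanceUID; REG/RTSTRUCT are single-object
    series without pixel data.  Deterministic given the seed.
    """
    if modality not in SOP_CLASSES:
        raise ValueError(f"unknown modality {modality!r}; "
                         f"choose from {sorted(SOP_CLASSES)}")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if modality in ("REG", "RTSTRUCT"):
        n_slices = 1

    rng = random.Random(f"series:{modality}:{seed}")
    study_uid = study_instance_uid or _uid(rng)
    series_uid = _uid(rng)

    files: list[tuple[str, bytes]] = []
    for i in range(n_slices):
        ds = _base_dataset(modality, SOP_CLASSES[modality], rng, study_uid, series_uid)
        ds.SeriesDescription = f"{modality} fixture series"
        ds.InstanceNumber = i + 1
        if modality in _IMAGE_MODALITIES:
            ds.ImageType = ["ORIGINAL", "PRIMARY", "AXIAL"]
            _add_pixels(ds, rng)
        elif modality == "REG":
            _registration_payload(ds, rng)
        else:
            _rtstruct_payload(ds, rng)
        for keyword, value in (tag_overrides or {}).items():
            setattr(ds, keyword, value)
        buf = io.BytesIO()
        pydicom.dcmwrite(buf, ds)
        files.append(
            (f"{modality.lower()}_{series_uid[-6:]}/{i + 1:03d}.dcm", buf.getvalue())
        )
    return files


@dataclass(frozen=True)
class SeriesSpec:
    """One series to generate within a scenario."""

    label: str
    modality: str
    n_slices: int = 1
    tag_overrides: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    series: tuple[SeriesSpec, ...]
    flows: tuple[FlowDefinition, ...]
    #: flow_id -> trigger name -> series *label*; resolved to UIDs during
    #: generation.  Computed by construction, never by running the matcher.
    expected_assignment_labels: Mapping[str, Mapping[str, str]]
    seed: int = 0


@dataclass(frozen=True)
class Scenario:
    """Materialized scenario: files, flow documents, and expected matches."""

    name: str
    seed: int
    files: tuple[tuple[str, bytes], ...]
    flows: tuple[FlowDefinition, ...]
    flow_texts: Mapping[str, str]  # file name -> YAML document
    series_uids: Mapping[str, str]  # series label -> SeriesInstanceUID
    expected_matches: Mapping[str, Mapping[str, str]]  # flow -> trigger -> uid


def build_scenario(spec: ScenarioSpec) -> Scenario:
    rng = random.Random(f"scenario:{spec.name}:{spec.seed}")
    study_uid = _uid(rng)
    files: list[tuple[str, bytes]] = []
    series_uids: dict[str, str] = {}
    for i, sspec in enumerate(spec.series):
        series_files = make_series(
            sspec.modality,
            n_slices=sspec.n_slices,
            tag_overrides=sspec.tag_overrides,
            seed=rng.randrange(2**31) + i,
            study_instance_uid=study_uid,
        )
        files.extend(series_files)
        meta = pydicom.dcmread(io.BytesIO(series_files[0][1]), stop_before_pixels=True)
        series_uids[sspec.label] = str(meta.SeriesInstanceUID)

    expected = {
        flow_id: {
            trigger: series_uids[label] for trigger, label in assignment.items()
        }
        for flow_id, assignment in spec.expected_assignment_labels.items()
    }
    flow_texts = {
        f"{flow.flow_id}.yaml": serialize_flow(flow) for flow in spec.flows
    }
    return Scenario(
        name=spec.name,
        seed=spec.seed,
        files=tuple(files),
        flows=spec.flows,
        flow_texts=flow_texts,
        series_uids=series_uids,
        expected_matches=expected,
    )


def _destination(port: int = 11113) -> DestinationSpec:
    return DestinationSpec(host="127.0.0.1", port=port, ae_title="TPS")


def _single_modality_spec(seed: int) -> ScenarioSpec:
    flow = FlowDefinition(
        flow_id="single_modality_seg",
        triggers=[TriggerSpec(name="ct", constraints={"Modality": "CT"})],
        models=[
            ModelSpec(
                name="segmentation",
                image="stub/identity",
                input_mounts=["ct"],
                output_mounts=["rtss"],
                device="gpu",
            )
        ],
        destinations=[_destination()],
    )
    return ScenarioSpec(
        name="single_modality",
        series=(SeriesSpec(label="ct", modality="CT", n_slices=3),),
        flows=(flow,),
        expected_assignment_labels={"single_modality_seg": {"ct": "ct"}},
        seed=seed,
    )


def _multi_modality_spec(seed: int) -> ScenarioSpec:
    triggers = [
        TriggerSpec(name="ct", constraints={"Modality": "CT"}),
        TriggerSpec(name="pet", constraints={"Modality": "PT"}),
        TriggerSpec(
            name="t1",
            constraints={"Modality": "MR", "SeriesDescription": "/.*T1.*/"},
        ),
        TriggerSpec(
            name="t2",
            constraints={"Modality": "MR", "SeriesDescription": "/.*T2.*/"},
        ),
    ]
    registration = ModelSpec(
        name="registration",
        image="stub/identity",
        input_mounts=["ct", "pet", "t1", "t2"],
        output_mounts=["aligned"],
        device="cpu",
    )
    predictors = [
        ModelSpec(
            name=f"predict_fold{k}",
            image="stub/identity",
            input_mounts=["aligned"],
            output_mounts=[f"gtv_fold{k}"],
            device="gpu",
        )
        for k in range(1, 6)
    ]
    flow = FlowDefinition(
        flow_id="multi_modality_gtv",
        triggers=triggers,
        models=[registration, *predictors],
        destinations=[_destination()],
    )
    return ScenarioSpec(
        name="multi_modality",
        series=(
            SeriesSpec(label="ct", modality="CT", n_slices=3),
            SeriesSpec(label="pet", modality="PT", n_slices=3),
            SeriesSpec(
                label="t1", modality="MR", n_slices=2,
                tag_overrides={"SeriesDescription": "T1w post-contrast"},
            ),
            SeriesSpec(
                label="t2", modality="MR", n_slices=2,
                tag_overrides={"SeriesDescription": "T2w TSE"},
            ),
        ),
        flows=(flow,),
        expected_assignment_labels={
            "multi_modality_gtv": {"ct": "ct", "pet": "pet", "t1": "t1", "t2": "t2"}
        },
        seed=seed,
    )


def _sct_spec(seed: int) -> ScenarioSpec:
    flow = FlowDefinition(
        flow_id="sct_generation",
        triggers=[
            TriggerSpec(name="ct", constraints={"Modality": "CT"}),
            TriggerSpec(
                name="cbct",
                constraints={"Modality": "CT", "ImageType": "/.*CBCT.*/"},
            ),
            TriggerSpec(name="reg", constraints={"Modality": "REG"}),
        ],
        models=[
            ModelSpec(
                name="sct_generator",
                image="stub/identity",
                input_mounts=["ct", "cbct", "reg"],
                output_mounts=["sct"],
                device="gpu",
            )
        ],
        destinations=[_destination()],
    )
    return ScenarioSpec(
        name="sct",
        series=(
            SeriesSpec(label="ct", modality="CT", n_slices=3),
            SeriesSpec(
                label="cbct", modality="CT", n_slices=3,
                tag_overrides={
                    "ImageType": ["DERIVED", "SECONDARY", "CBCT"],
                    "SeriesDescription": "kV CBCT positioning",
                },
            ),
            SeriesSpec(label="reg", modality="REG"),
        ),
        flows=(flow,),
        expected_assignment_labels={
            "sct_generation": {"ct": "ct", "cbct": "cbct", "reg": "reg"}
        },
        seed=seed,
    )


_PRESET_BUILDERS = {
    "single_modality": _single_modality_spec,
    "multi_modality": _multi_modality_spec,
    "sct": _sct_spec,
}


def make_scenario(preset: str | ScenarioSpec, seed: int = 0) -> Scenario:
    """Materialize a named preset (or an explicit :class:`ScenarioSpec`)."""
    if isinstance(preset, ScenarioSpec):
        return build_scenario(preset)
    try:
        builder = _PRESET_BUILDERS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {PRESETS}"
        ) from None
    return build_scenario(builder(seed))


def write_scenario(scenario: Scenario, out_dir: str | Path) -> Path:
    """Write a scenario to disk: ``dicom/`` file tree + ``flows/`` YAMLs."""
    out = Path(out_dir)
    dicom_dir = out / "dicom"
    flow_dir = out / "flows"
    for path, data in scenario.files:
        dest = dicom_dir / path
        dest.parent.mkdir(parents=True, exist_ok=True)
        dest.write_bytes(data)
    flow_dir.mkdir(parents=True, exist_ok=True)
    for name, text in scenario.flow_texts.items():
        (flow_dir / name).write_text(text)
    return out
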