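"""Per-file and per-series metadata extraction from a received bundle.

Trigger evaluation needs DICOM header attributes only, never pixel data,
so indexing reads each file's meta-information and main dataset header
(``stop_before_pixels``) and groups files by SeriesInstanceUID.  Files
that fail to parse are kept as *orphans* — failures are data, not
exceptions — and every parsed file lands in exactly one series record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pydicom
from pydicom.errors import InvalidDicomError
from pydicom.multival import MultiValue

__all__ = [
    "DEFAULT_ATTRIBUTE_ALLOWLIST",
    "DicomParseError",
    "FileMeta",
    "OrphanFile",
    "SeriesRecord",
    "SeriesIndex",
    "read_file_meta",
    "build_series_index",
]

#: Attributes extracted per file by default; covers modality-based and
#: scanner-origin routing.  Extendable via the ``allowlist`` argument.
DEFAULT_ATTRIBUTE_ALLOWLIST: tuple[str, ...] = (
    "Modality",
    "SOPClassUID",
    "SeriesDescription",
    "StudyDescription",
    "ImageType",
    "PatientID",
    "StationName",
    "BodyPartExamined",
    "Manufacturer",
)


class DicomParseError(Exception):
    """The bytes are not a readable DICOM dataset."""


@dataclass(frozen=True)
class FileMeta:
    relative_path: str
    sop_instance_uid: str
    series_instance_uid: str
    study_instance_uid: str
    attributes: dict[str, str]


@dataclass(frozen=True)
class OrphanFile:
    relative_path: str
    error: str


@dataclass(frozen=True)
class SeriesRecord:
    """One DICOM series: representative (first-file) attribute values,
    the full per-keyword value sets, and the member file paths."""

    series_instance_uid: str
    study_instance_uid: str
    attributes: dict[str, str]
    value_sets: dict[str, frozenset[str]]
    file_paths: tuple[str, ...]

    def attribute_values(self, keyword: str) -> frozenset[str]:
        return self.value_sets.get(keyword, frozenset())


@dataclass(frozen=True)
class SeriesIndex:
    series: tuple[SeriesRecord, ...] = field(default_factory=tuple)
    orphan_files: tuple[OrphanFile, ...] = field(default_factory=tuple)

    @property
    def n_files(self) -> int:
        return sum(len(s.file_paths) for s in self.series)

    def by_uid(self, series_instance_uid: str) -> SeriesRecord:
        for s in self.series:
            if s.series_instance_uid == series_instance_uid:
                return s
        raise KeyError(series_instance_uid)


def _stringify(value) -> str:
    """Render a DICOM element value the way trigger patterns see it.

    Multi-valued elements (e.g. ImageType) join with the DICOM ``\\``
    value separator.
    """
    if isinstance(value, (list, MultiValue)):
        return "\\".join(str(v) for v in value)
    return str(value)


def read_file_meta(
    data: bytes,
    relative_path: str = "",
    allowlist: Sequence[str] = DEFAULT_ATTRIBUTE_ALLOWLIST,
) -> FileMeta:
    """Extract UIDs and allow-listed attributes from one file's bytes.

    Attributes absent from the dataset are omitted (never empty strings).
    Raises :class:`DicomParseError` on non-DICOM bytes; the caller records
    such files as orphans.
    """
    if not data:
        raise DicomParseError("empty file")
    try:
        ds = pydicom.dcmread(io.BytesIO(data), stop_before_pixels=True)
    except InvalidDicomError:
        # headerless (no preamble/magic) datasets are accepted if they
        # still yield identifiable DICOM content
        try:
            ds = pydicom.dcmread(io.BytesIO(data), stop_before_pixels=True, force=True)
        except Exception as exc:  # noqa: BLE001 - any read failure is a parse error
            raise DicomParseError(f"unreadable DICOM stream: {exc}") from exc
    except Exception as exc:  # noqa: BLE001
        raise DicomParseError(f"unreadable DICOM stream: {exc}") from exc

    sop_uid = str(getattr(ds, "SOPInstanceUID", "") or "")
    if not sop_uid:
        raise DicomParseError("dataset has no SOPInstanceUID")
    study_uid = str(getattr(ds, "StudyInstanceUID", "") or "")
    if not study_uid:
        raise DicomParseError("dataset has no StudyInstanceUID")
    # files without SeriesInstanceUID become synthetic singleton series so
    # standalone objects (e.g. registrations) stay matchable
    series_uid = str(getattr(ds, "SeriesInstanceUID", "") or "") or sop_uid

    attributes: dict[str, str] = {}
    for keyword in allowlist:
        if keyword in ds and ds[keyword].value not in (None, ""):
            attributes[keyword] = _stringify(ds[keyword].value)
    return FileMeta(
        relative_path=relative_path,
        sop_instance_uid=sop_uid,
        series_instance_uid=series_uid,
        study_instance_uid=study_uid,
        attributes=attributes,
    )


def build_series_index(
    files: Iterable[tuple[str, bytes]],
    allowlist: Sequence[str] = DEFAULT_ATTRIBUTE_ALLOWLIST,
) -> SeriesIndex:
    """Group files by SeriesInstanceUID into a deterministic index.

    Series are sorted by UID and files by path; unparseable files are
    recorded in ``orphan_files``.  Indexing is idempotent and conserves
    files: every input appears either in exactly one series record or as
    an orphan.
    """
    metas: dict[str, list[FileMeta]] = {}
    orphans: list[OrphanFile] = []
    for path, data in sorted(files, key=lambda item: item[0]):
        try:
            meta = read_file_meta(data, relative_path=path, allowlist=allowlist)
        except DicomParseError as exc:
            orphans.append(OrphanFile(relative_path=path, error=str(exc)))
            continue
        metas.setdefault(meta.series_instance_uid, []).append(meta)

    series: list[SeriesRecord] = []
    for series_uid in sorted(metas):
        group = metas[series_uid]
        value_sets: dict[str, set[str]] = {}
        for meta in group:
            for keyword, value in meta.attributes.items():
                value_sets.setdefault(keyword, set()).add(value)
        series.append(
            SeriesRecord(
                series_instance_uid=series_uid,
                study_instance_uid=group[0].study_instance_uid,
                attributes=dict(group[0].attributes),
                value_sets={k: frozenset(v) for k, v in value_sets.items()},
                file_paths=tuple(m.relative_path for m in group),
            )
        )
    return SeriesIndex(series=tuple(series), orphan_files=tuple(orphans))
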