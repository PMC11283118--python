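"""Content storage for the tar bundles exchanged between services.

Every object that moves through the stack — a received study, a pruned
per-flow subset, a per-mount model input, a model output, the final
result — is a POSIX tar archive ("bundle") held in a content store and
referenced by an opaque bundle UID.  Archives are built deterministically
(sorted members, zeroed metadata) so that identical logical content yields
byte-identical archives; a JSON manifest member records per-file SHA-256
checksums so consumers can verify bit-exact delivery.
"""

from __future__ import annotations

import hashlib
import io
import json
import posixpath
import tarfile
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

MANIFEST_NAME = "_manifest.json"


class StorageError(Exception):
    """Base class for storage failures."""


class BundleFormatError(StorageError):
    """Malformed archive or bad member paths."""


class BundleIntegrityError(StorageError):
    """Archive contents disagree with the manifest checksums."""


class BundleNotFoundError(StorageError):
    """UID not present in the store (lost message or expired object)."""


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    size: int
    sha256: str


@dataclass(frozen=True)
class TarBundle:
    """A tar archive plus its parsed manifest."""

    payload: bytes
    manifest: tuple[ManifestEntry, ...]

    @classmethod
    def from_bytes(cls, payload: bytes) -> "TarBundle":
        try:
            with tarfile.open(fileobj=io.BytesIO(payload), mode="r:") as tf:
                member = tf.getmember(MANIFEST_NAME)
                fh = tf.extractfile(member)
                assert fh is not None
                raw = json.loads(fh.read().decode("utf-8"))
        except (tarfile.TarError, KeyError, ValueError) as exc:
            raise BundleFormatError(f"not a valid bundle archive: {exc}") from exc
        manifest = tuple(
            ManifestEntry(e["path"], int(e["size"]), e["sha256"]) for e in raw
        )
        return cls(payload=payload, manifest=manifest)

    @property
    def paths(self) -> tuple[str, ...]:
        return tuple(e.path for e in self.manifest)


def _normalize_path(path: str) -> str:
    norm = posixpath.normpath(str(path).replace("\\", "/")).lstrip("/")
    if not norm or norm in (".", ".."):
        raise BundleFormatError(f"empty or invalid member path: {path!r}")
    if norm.startswith("../") or "/../" in f"/{norm}/":
        raise BundleFormatError(f"path traversal component in {path!r}")
    if norm == MANIFEST_NAME:
        raise BundleFormatError(f"{MANIFEST_NAME} is a reserved member name")
    return norm


def _add_member(tf: tarfile.TarFile, name: str, data: bytes) -> None:
    info = tarfile.TarInfo(name=name)
    info.size = len(data)
    info.mtime = 0
    info.uid = info.gid = 0
    info.uname = info.gname = ""
    info.mode = 0o644
    tf.addfile(info, io.BytesIO(data))


def pack_bundle(files: Iterable[tuple[str, bytes]]) -> TarBundle:
    """Pack ``(relative_path, bytes)`` pairs into a deterministic archive.

    Members are sorted by path and carry zeroed timestamps/ownership, so
    the same logical input always produces byte-identical archive bytes.
    Duplicate or traversal paths are rejected.
    """
    staged: dict[str, bytes] = {}
    for path, data in files:
        norm = _normalize_path(path)
        if norm in staged:
            raise BundleFormatError(f"duplicate member path: {norm}")
        staged[norm] = bytes(data)

    ordered = sorted(staged.items())
    manifest = tuple(
        ManifestEntry(p, len(d), hashlib.sha256(d).hexdigest()) for p, d in ordered
    )
    manifest_json = json.dumps(
        [{"path": e.path, "size": e.size, "sha256": e.sha256} for e in manifest],
        sort_keys=True,
        separators=(",", ":"),
    ).encode("utf-8")

    buf = io.BytesIO()
    with tarfile.open(fileobj=buf, mode="w", format=tarfile.USTAR_FORMAT) as tf:
        _add_member(tf, MANIFEST_NAME, manifest_json)
        for path, data in ordered:
            _add_member(tf, path, data)
    return TarBundle(payload=buf.getvalue(), manifest=manifest)


def unpack_bundle(bundle: TarBundle | bytes) -> list[tuple[str, bytes]]:
    """Inverse of :func:`pack_bundle`; verifies every member checksum."""
    if isinstance(bundle, (bytes, bytearray)):
        bundle = TarBundle.from_bytes(bytes(bundle))
    expected = {e.path: e for e in bundle.manifest}
    out: list[tuple[str, bytes]] = []
    try:
        with tarfile.open(fileobj=io.BytesIO(bundle.payload), mode="r:") as tf:
            for member in tf.getmembers():
                if member.name == MANIFEST_NAME:
                    continue
                fh = tf.extractfile(member)
                data = fh.read() if fh is not None else b""
                entry = expected.pop(member.name, None)
                if entry is None:
                    raise BundleIntegrityError(
                        f"member {member.name!r} absent from manifest"
                    )
                digest = hashlib.sha256(data).hexdigest()
                if digest != entry.sha256 or len(data) != entry.size:
                    raise BundleIntegrityError(
                        f"checksum mismatch for member {member.name!r}"
                    )
                out.append((member.name, data))
    except tarfile.TarError as exc:
        raise BundleFormatError(f"malformed archive: {exc}") from exc
    if expected:
        missing = ", ".join(sorted(expected))
        raise BundleIntegrityError(f"manifest entries missing from archive: {missing}")
    return out


class BundleStore:
    """put/get contract shared by the in-memory and filesystem backends.

    ``get(put(b))`` is byte-for-byte identical to ``b``.  UIDs are UUID4
    strings; identical content stored twice yields two distinct UIDs (no
    deduplication).
    """

    def put(self, bundle: TarBundle) -> str:
        raise NotImplementedError

    def get(self, uid: str) -> TarBundle:
        raise NotImplementedError

    def exists(self, uid: str) -> bool:
        raise NotImplementedError

    def _new_uid(self) -> str:
        return str(uuid.uuid4())


class MemoryBundleStore(BundleStore):
    def __init__(self) -> None:
        self._objects: dict[str, bytes] = {}

    def put(self, bundle: TarBundle) -> str:
        uid = self._new_uid()
        self._objects[uid] = bundle.payload
        return uid

    def get(self, uid: str) -> TarBundle:
        try:
            return TarBundle.from_bytes(self._objects[uid])
        except KeyError:
            raise BundleNotFoundError(uid) from None

    def exists(self, uid: str) -> bool:
        return uid in self._objects


class FileBundleStore(BundleStore):
    """Directory-backed store; one ``<uid>.tar`` file per object."""

    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, uid: str) -> Path:
        if not uid or "/" in uid or uid.startswith("."):
            raise BundleNotFoundError(uid)
        return self.root / f"{uid}.tar"

    def put(self, bundle: TarBundle) -> str:
        uid = self._new_uid()
        tmp = self.root / f".{uid}.tmp"
        tmp.write_bytes(bundle.payload)
        tmp.rename(self._path(uid))
        return uid

    def get(self, uid: str) -> TarBundle:
        path = self._path(uid)
        if not path.is_file():
            raise BundleNotFoundError(uid)
        return TarBundle.from_bytes(path.read_bytes())

    def exists(self, uid: str) -> bool:
        return self._path(uid).is_file()
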