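"""Shared pool of named, sealed, immutable columnar objects.

Pipeline stages never hand data to each other directly: a producer
``put``s a chunk or a delta-column set under a namespaced key, and any
number of consumers — including concurrently running worker processes —
``get`` it back bit-identically.  Objects are write-once: creation and
sealing are separate steps (``put`` does both), and a sealed object's
payload never changes.

The backing implementation is a store directory of Arrow IPC files, one
per object, plus a JSON manifest.  Sealing is an atomic rename, and a
``get`` memory-maps the file, so retrieval does no SAM re-parsing and no
per-consumer copy of column contents; repeated gets leave the store's
accounting untouched.  This reproduces the create/seal/get/delete
semantics of a shared-memory object store while remaining testable on
any filesystem.
"""

from __future__ import annotations

import fcntl
import json
import os
import urllib.parse
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import pyarrow as pa
import pyarrow.ipc as ipc

from .model import SamHeader, StoreError

__all__ = ["ObjectKey", "StoredObject", "ObjectStore"]


@dataclass(frozen=True)
class ObjectKey:
    """(namespace, chromosome, ordinal) identifying one stored object."""

    namespace: str
    chrom: str
    ordinal: int

    @property
    def name(self) -> str:
        return f"{self.namespace}/{self.chrom}/{self.ordinal}"

    @classmethod
    def parse(cls, name: str) -> "ObjectKey":
        namespace, chrom, ordinal = name.split("/")
        return cls(namespace, chrom, int(ordinal))

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class StoredObject:
    key: ObjectKey
    byte_size: int
    sealed: bool


def _decode_payload(rb: pa.RecordBatch):
    meta = rb.schema.metadata or {}
    kind = meta.get(b"colsam_kind", b"").decode()
    if kind == "chunk":
        from .model import Chunk
        return Chunk.from_record_batch(rb)
    if kind == "flagdelta":
        from .markdup import FlagDelta
        return FlagDelta.from_record_batch(rb)
    if kind == "qualindex":
        from .views import QualIndexDelta
        return QualIndexDelta.from_record_batch(rb)
    raise StoreError(f"unknown payload kind {kind!r}")


class ObjectStore:
    """Directory-backed pool of sealed immutable objects.

    Parameters
    ----------
    root:
        Store directory; created if absent.
    capacity_bytes:
        Optional hard bound on the summed serialized size of all
        objects.  There is no eviction: exceeding the bound is an error,
        matching the assumption that working data fits in memory.
    """

    def __init__(self, root, capacity_bytes: int | None = None):
        self.root = Path(root)
        self.capacity_bytes = capacity_bytes
        (self.root / "objects").mkdir(parents=True, exist_ok=True)
        (self.root / "tmp").mkdir(exist_ok=True)
        self._manifest_path = self.root / "manifest.json"
        self._lock_path = self.root / ".lock"

    # -- locking / manifest ------------------------------------------------
    @contextmanager
    def _locked(self):
        with open(self._lock_path, "w") as fh:
            fcntl.flock(fh, fcntl.LOCK_EX)
            try:
                yield
            finally:
                fcntl.flock(fh, fcntl.LOCK_UN)

    def _load_manifest(self) -> dict:
        if not self._manifest_path.exists():
            return {}
        with open(self._manifest_path) as fh:
            return json.load(fh)

    def _write_manifest(self, manifest: dict) -> None:
        tmp = self.root / "tmp" / f"manifest.{os.getpid()}.json"
        with open(tmp, "w") as fh:
            json.dump(manifest, fh)
        os.replace(tmp, self._manifest_path)

    # -- paths -------------------------------------------------------------
    def _fname(self, key: ObjectKey, sealed: bool) -> Path:
        safe = "__".join(
            urllib.parse.quote(part, safe="") for part in
            (key.namespace, key.chrom, str(key.ordinal)))
        suffix = ".arrow" if sealed else ".unsealed"
        return self.root / "objects" / (safe + suffix)

    # -- chromosome ordering / header -------------------------------------
    def set_header(self, header: SamHeader) -> None:
        """Persist the SAM header; it defines chromosome ordering for
        :meth:`list_keys` and is reused at export."""
        with open(self.root / "header.sam", "w", encoding="utf-8") as fh:
            fh.write(header.serialize())

    def get_header(self) -> SamHeader:
        path = self.root / "header.sam"
        if not path.exists():
            raise StoreError(f"store {self.root} has no header")
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        return SamHeader.parse(lines)

    def _chrom_rank(self) -> dict[str, int]:
        try:
            return self.get_header().chrom_rank()
        except StoreError:
            return {}

    # -- core operations ---------------------------------------------------
    def create(self, key: ObjectKey, payload) -> StoredObject:
        """Write an object without sealing it; invisible to ``get`` until
        :meth:`seal` is called."""
        with self._locked():
            manifest = self._load_manifest()
            if key.name in manifest:
                raise StoreError(f"duplicate object key {key.name!r}")
            path = self._fname(key, sealed=False)
            rb = payload.to_record_batch()
            tmp = self.root / "tmp" / f"{os.getpid()}.{path.name}"
            with pa.OSFile(str(tmp), "wb") as sink:
                with ipc.new_file(sink, rb.schema) as writer:
                    writer.write_batch(rb)
            byte_size = tmp.stat().st_size
            if self.capacity_bytes is not None:
                used = sum(v["byte_size"] for v in manifest.values())
                if used + byte_size > self.capacity_bytes:
                    tmp.unlink()
                    raise StoreError(
                        f"store capacity {self.capacity_bytes} exceeded by "
                        f"{key.name} ({byte_size} bytes on top of {used})")
            os.replace(tmp, path)
            manifest[key.name] = {
                "file": path.name, "byte_size": byte_size, "sealed": False}
            self._write_manifest(manifest)
        return StoredObject(key, byte_size, sealed=False)

    def seal(self, key: ObjectKey) -> StoredObject:
        with self._locked():
            manifest = self._load_manifest()
            entry = manifest.get(key.name)
            if entry is None:
                raise StoreError(f"cannot seal missing key {key.name!r}")
            if not entry["sealed"]:
                os.replace(self._fname(key, sealed=False),
                           self._fname(key, sealed=True))
                entry["file"] = self._fname(key, sealed=True).name
                entry["sealed"] = True
                self._write_manifest(manifest)
        return StoredObject(key, entry["byte_size"], sealed=True)

    def put(self, key: ObjectKey, payload) -> StoredObject:
        """Create and seal in one step (the common producer call)."""
        rb = payload.to_record_batch()
        tmp = self.root / "tmp" / f"{os.getpid()}.{key.name.replace('/', '_')}"
        with pa.OSFile(str(tmp), "wb") as sink:
            with ipc.new_file(sink, rb.schema) as writer:
                writer.write_batch(rb)
        byte_size = tmp.stat().st_size
        with self._locked():
            manifest = self._load_manifest()
            if key.name in manifest:
                tmp.unlink()
                raise StoreError(f"duplicate object key {key.name!r}")
            if self.capacity_bytes is not None:
                used = sum(v["byte_size"] for v in manifest.values())
                if used + byte_size > self.capacity_bytes:
                    tmp.unlink()
                    raise StoreError(
                        f"store capacity {self.capacity_bytes} exceeded by "
                        f"{key.name} ({byte_size} bytes on top of {used})")
            path = self._fname(key, sealed=True)
            os.replace(tmp, path)
            manifest[key.name] = {
                "file": path.name, "byte_size": byte_size, "sealed": True}
            self._write_manifest(manifest)
        return StoredObject(key, byte_size, sealed=True)

    def get(self, key: ObjectKey):
        """Retrieve a sealed object's payload, memory-mapped (zero-copy)."""
        path = self._fname(key, sealed=True)
        if not path.exists():
            if self._fname(key, sealed=False).exists():
                raise StoreError(f"object {key.name!r} exists but is not sealed")
            raise StoreError(f"missing object key {key.name!r}")
        with pa.memory_map(str(path), "r") as source:
            reader = ipc.open_file(source)
            rb = reader.get_batch(0)
            return _decode_payload(rb)

    def describe(self, key: ObjectKey) -> StoredObject:
        manifest = self._load_manifest()
        entry = manifest.get(key.name)
        if entry is None:
            raise StoreError(f"missing object key {key.name!r}")
        return StoredObject(key, entry["byte_size"], entry["sealed"])

    def contains(self, key: ObjectKey) -> bool:
        return key.name in self._load_manifest()

    def delete(self, key: ObjectKey) -> None:
        with self._locked():
            manifest = self._load_manifest()
            entry = manifest.pop(key.name, None)
            if entry is None:
                raise StoreError(f"cannot delete missing key {key.name!r}")
            path = self._fname(key, sealed=entry["sealed"])
            if path.exists():
                path.unlink()
            self._write_manifest(manifest)

    def list_keys(self, namespace: str | None = None) -> list[ObjectKey]:
        """Keys (optionally one namespace), ordered by (chromosome order
        in the stored header, ordinal); unknown chromosomes sort after
        known ones, lexicographically."""
        rank = self._chrom_rank()
        keys = [ObjectKey.parse(name) for name in self._load_manifest()]
        if namespace is not None:
            keys = [k for k in keys if k.namespace == namespace]
        keys.sort(key=lambda k: (
            k.namespace,
            rank.get(k.chrom, len(rank)), k.chrom, k.ordinal))
        return keys

    def namespaces(self) -> list[str]:
        return sorted({k.namespace for k in self.list_keys()})

    def drop_namespace(self, namespace: str) -> int:
        """Delete every object in a namespace (one manifest transaction);
        returns the number removed."""
        with self._locked():
            manifest = self._load_manifest()
            doomed = [n for n in manifest
                      if ObjectKey.parse(n).namespace == namespace]
            for name in doomed:
                entry = manifest.pop(name)
                path = self._fname(ObjectKey.parse(name), entry["sealed"])
                if path.exists():
                    path.unlink()
            self._write_manifest(manifest)
        return len(doomed)

    def total_bytes(self) -> int:
        return sum(v["byte_size"] for v in self._load_manifest().values())

    def inventory(self) -> list[dict]:
        """Manifest as a list of {key, byte_size, sealed} dicts, ordered
        like :meth:`list_keys`."""
        manifest = self._load_manifest()
        return [
            {"key": k.name,
             "byte_size": manifest[k.name]["byte_size"],
             "sealed": manifest[k.name]["sealed"]}
            for k in self.list_keys()
        ]
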