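"""Bundle synchronization with an experiment/sample database store.

A bundle is pushed to a server as one *experiment*; every collection in
it becomes a *sample* of that experiment, and raw data plus annotations
are stored as *datasets* under their sample — the provenance chain
(dataset -> sample -> experiment) the database needs for tracking.  Cache
files are derived and are never uploaded.  Uploads are differential: a
file whose MD5 already matches its server copy is skipped, so re-syncing
an unchanged bundle transfers nothing.  The server side is a pluggable
contract (put / get / list / stat-with-md5); the bundled implementation
mirrors the hierarchy into a local directory.

Sequence of one sync: verify local integrity -> ensure experiment ->
ensure samples (assigning database ids back into the local metadata) ->
diff by MD5 -> upload.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .metadata import read_metadata, write_metadata
from .repository import (
    Bundle,
    Collection,
    IntegrityReport,
    RepositoryError,
    md5_file,
    rebuild_cache,
    verify_integrity,
)

__all__ = [
    "SyncError",
    "SyncReport",
    "RemoteReport",
    "DirectoryStore",
    "sync_bundle",
    "verify_remote",
    "download",
]

#: Pseudo-dataset holding a collection's own annotation files server-side.
COLLECTION_DATASET = "_collection"


class SyncError(Exception):
    pass


@dataclass
class SyncReport:
    uploaded: int = 0
    skipped_unchanged: int = 0
    excluded_cache_files: int = 0
    assigned_ids: list[tuple[str, str]] = field(default_factory=list)
    complete: bool = True


@dataclass
class RemoteReport:
    checked: int = 0
    passed: int = 0
    failures: list[tuple[str, str, str]] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)  # server files with no local twin

    @property
    def ok(self) -> bool:
        return not self.failures


class DirectoryStore:
    """Mock server: the experiment/sample/dataset hierarchy on disk.

    Layout: ``store/experiments/<eid>/samples/<sid>/datasets/<did>/
    {RawData,Annotations}`` with a ``record.xml`` at every level.
    """

    def __init__(self, root: Path):
        self.root = Path(root)
        (self.root / "experiments").mkdir(parents=True, exist_ok=True)

    # -- hierarchy ----------------------------------------------------------

    def _exp_dir(self, eid: str) -> Path:
        return self.root / "experiments" / eid

    def _sample_dir(self, eid: str, sid: str) -> Path:
        return self._exp_dir(eid) / "samples" / sid

    def _dataset_dir(self, eid: str, sid: str, did: str) -> Path:
        return self._sample_dir(eid, sid) / "datasets" / did

    @staticmethod
    def _write_record(path: Path, kind: str, **attrs: str) -> None:
        root = etree.Element("record")
        root.set("kind", kind)
        for k, v in sorted(attrs.items()):
            root.set(k, v)
        (path / "record.xml").write_bytes(
            etree.tostring(root, pretty_print=True, encoding="utf-8")
        )

    def ensure_experiment(self, eid: str, **attrs: str) -> str:
        d = self._exp_dir(eid)
        if not d.exists():
            (d / "samples").mkdir(parents=True)
            self._write_record(d, "experiment", id=eid, **attrs)
        return eid

    def ensure_sample(self, eid: str, sid: str, **attrs: str) -> str:
        d = self._sample_dir(eid, sid)
        if not d.exists():
            (d / "datasets").mkdir(parents=True)
            self._write_record(d, "sample", id=sid, experiment=eid, **attrs)
        return sid

    def ensure_dataset(self, eid: str, sid: str, did: str, **attrs: str) -> str:
        d = self._dataset_dir(eid, sid, did)
        if not d.exists():
            (d / "RawData").mkdir(parents=True)
            (d / "Annotations").mkdir()
            self._write_record(d, "dataset", id=did, sample=sid, experiment=eid, **attrs)
        return did

    # -- file contract ------------------------------------------------------

    def put(self, eid: str, sid: str, did: str, kind: str, filename: str, data: bytes) -> None:
        target = self._dataset_dir(eid, sid, did) / kind
        target.mkdir(parents=True, exist_ok=True)
        (target / filename).write_bytes(data)

    def get(self, eid: str, sid: str, did: str, kind: str, filename: str) -> bytes:
        return (self._dataset_dir(eid, sid, did) / kind / filename).read_bytes()

    def stat_md5(self, eid: str, sid: str, did: str, kind: str, filename: str) -> Optional[str]:
        p = self._dataset_dir(eid, sid, did) / kind / filename
        return md5_file(p) if p.is_file() else None

    def experiments(self) -> list[str]:
        return sorted(p.name for p in (self.root / "experiments").iterdir() if p.is_dir())

    def samples(self, eid: str) -> list[str]:
        d = self._exp_dir(eid) / "samples"
        return sorted(p.name for p in d.iterdir() if p.is_dir()) if d.exists() else []

    def datasets(self, eid: str, sid: str) -> list[str]:
        d = self._sample_dir(eid, sid) / "datasets"
        return sorted(p.name for p in d.iterdir() if p.is_dir()) if d.exists() else []

    def files(self, eid: str, sid: str, did: str) -> list[tuple[str, str]]:
        """(kind, filename) pairs stored for one dataset."""
        out = []
        for kind in ("RawData", "Annotations"):
            d = self._dataset_dir(eid, sid, did) / kind
            if d.exists():
                out.extend((kind, p.name) for p in sorted(d.iterdir()) if p.is_file())
        return out

    def sample_record(self, eid: str, sid: str) -> dict[str, str]:
        path = self._sample_dir(eid, sid) / "record.xml"
        root = etree.parse(str(path)).getroot()
        return dict(root.attrib)

    def find_sample(self, sid: str) -> Optional[str]:
        """Return the experiment owning ``sid``, if any."""
        for eid in self.experiments():
            if sid in self.samples(eid):
                return eid
        return None


# --- helpers ---------------------------------------------------------------

def _slug(bundle: Bundle, coll: Collection) -> str:
    rel = coll.path.relative_to(bundle.fs_path)
    parts = [bundle.name] + [p for p in rel.parts if p != "Collections"]
    return "-".join(parts)


def _collection_files(coll: Collection) -> dict[str, list[tuple[str, Path]]]:
    """Map dataset id (or the collection pseudo-dataset) to its files."""
    out: dict[str, list[tuple[str, Path]]] = {COLLECTION_DATASET: []}
    dataset_ids = coll.dataset_ids()
    for did in dataset_ids:
        out[did] = []
        ddir = coll.raw_dir / did
        for p in sorted(ddir.iterdir()):
            if p.is_file():
                out[did].append(("RawData", p))
    if coll.annotations_dir.exists():
        for p in sorted(coll.annotations_dir.iterdir()):
            if not p.is_file():
                continue
            owner = next(
                (did for did in dataset_ids if p.name == f"{did}.xml" or p.name.startswith(did + "_")),
                COLLECTION_DATASET,
            )
            out[owner].append(("Annotations", p))
    return out


def _count_cache_files(root: Collection) -> int:
    n = 0
    for coll in root.walk():
        if coll.cache_dir.exists():
            n += sum(1 for p in coll.cache_dir.rglob("*") if p.is_file())
    return n


# --- operations ------------------------------------------------------------

def sync_bundle(bundle: Bundle, store: DirectoryStore) -> SyncReport:
    """Push a bundle's raw data and annotations to the store.

    Local integrity is verified first; any failure aborts before a single
    upload.  Database ids are written back into each collection's
    metadata before its annotation files are diffed, so an immediately
    repeated sync uploads nothing.
    """
    integrity = verify_integrity(bundle)
    if not integrity.ok:
        raise SyncError(
            f"local integrity check failed for {len(integrity.failures)} file(s); not syncing"
        )
    report = SyncReport()
    report.excluded_cache_files = _count_cache_files(bundle.root)
    eid = f"{bundle.name}"
    store.ensure_experiment(eid, name=bundle.name)

    # ensure samples + write back ids before diffing annotation files
    collections = list(bundle.walk())
    for coll in collections:
        sid = _slug(bundle, coll)
        parent = coll.parent
        attrs = {"name": str(coll.path.name)}
        if parent is not None:
            attrs["parent"] = _slug(bundle, parent)
        store.ensure_sample(eid, sid, **attrs)
        doc = coll.read_metadata()
        if doc.database_id != sid:
            doc.database_id = sid
            coll.write_metadata(doc)
        report.assigned_ids.append((str(coll.path), sid))

    try:
        for coll in collections:
            sid = _slug(bundle, coll)
            for did, files in _collection_files(coll).items():
                store.ensure_dataset(eid, sid, did)
                for kind, path in files:
                    remote = store.stat_md5(eid, sid, did, kind, path.name)
                    if remote == md5_file(path):
                        report.skipped_unchanged += 1
                        continue
                    store.put(eid, sid, did, kind, path.name, path.read_bytes())
                    report.uploaded += 1
    except OSError:
        report.complete = False
        raise
    return report


def verify_remote(bundle: Bundle, store: DirectoryStore) -> RemoteReport:
    """Compare every local raw/annotation file's MD5 with its server copy."""
    eid = bundle.name
    if eid not in store.experiments():
        raise SyncError(f"bundle {bundle.name!r} unknown on server")
    report = RemoteReport()
    seen: dict[tuple, set[tuple[str, str]]] = {}
    for coll in bundle.walk():
        sid = _slug(bundle, coll)
        for did, files in _collection_files(coll).items():
            seen.setdefault((sid, did), set())
            for kind, path in files:
                report.checked += 1
                seen[(sid, did)].add((kind, path.name))
                remote = store.stat_md5(eid, sid, did, kind, path.name)
                local = md5_file(path)
                if remote is None:
                    report.failures.append((str(path), local, "missing"))
                elif remote != local:
                    report.failures.append((str(path), local, remote))
                else:
                    report.passed += 1
    for sid in store.samples(eid):
        for did in store.datasets(eid, sid):
            for kind, filename in store.files(eid, sid, did):
                if (kind, filename) not in seen.get((sid, did), set()):
                    report.orphans.append(f"{sid}/{did}/{kind}/{filename}")
    return report


def _materialize(eid: str, sid: str, store: DirectoryStore, parent: Collection) -> Collection:
    name = store.sample_record(eid, sid).get("name", sid)
    target = parent.collections_dir / name
    if target.exists():
        raise SyncError(f"collection {name!r} already exists under {parent.path}")
    parent.collections_dir.mkdir(exist_ok=True)
    target.mkdir()
    for sub in ("RawData", "Annotations", "Cache", "Collections"):
        (target / sub).mkdir()
    coll = Collection(target)
    for did in store.datasets(eid, sid):
        for kind, filename in store.files(eid, sid, did):
            data = store.get(eid, sid, did, kind, filename)
            if kind == "RawData":
                ddir = coll.raw_dir / did
                ddir.mkdir(exist_ok=True)
                (ddir / filename).write_bytes(data)
            else:
                (coll.annotations_dir / filename).write_bytes(data)
    rebuild_cache(coll)
    # recurse into child samples (recorded by their parent link)
    for child_sid in store.samples(eid):
        if store.sample_record(eid, child_sid).get("parent") == sid:
            _materialize(eid, child_sid, store, coll)
    return coll


def download(collection_id: str, store: DirectoryStore, target_bundle: Bundle) -> Collection:
    """Materialize a server-side sample (and its sub-collections) locally.

    The four-folder layout is recreated, raw data and annotations are
    fetched, the cache is regenerated locally (never downloaded), and the
    result is integrity-verified against the restored metadata.
    """
    eid = store.find_sample(collection_id)
    if eid is None:
        raise SyncError(f"unknown collection id {collection_id!r} on server")
    coll = _materialize(eid, collection_id, store, target_bundle.root)
    post = verify_integrity(coll)
    if not post.ok:
        raise SyncError(f"integrity check failed after download of {collection_id!r}")
    return coll
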