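"""The on-disk container format: bundles, collections, datasets.

An experiment lives in a *bundle*, a directory named ``<name>.bundle``
that is itself the root *collection*.  Every collection holds exactly
four subfolders::

    RawData/      imported raw files, never modified after import
    Annotations/  XML metadata, thumbnails, previews, annotated views
    Cache/        derived files, recomputable from RawData + Annotations
    Collections/  sub-collections, nested arbitrarily deep

Raw data integrity rests on MD5 checksums computed at import time over
the *uncompressed* content; files may be stored ZIP-compressed (deflate,
one file per archive) without affecting the recorded checksum.  The whole
tree is plain files, browsable and readable by any third-party tool.
"""

from __future__ import annotations

import hashlib
import re
import shutil
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from . import datatypes as _dt
from .metadata import (
    DatasetProperties,
    MetadataDoc,
    MetadataError,
    RawFileRecord,
    ingest_attribute_file,
    read_metadata,
    write_metadata,
)

__all__ = [
    "SUBFOLDERS",
    "Bundle",
    "Collection",
    "DatasetRecord",
    "IntegrityReport",
    "RepositoryError",
    "LockError",
    "DatatypeHandler",
    "DATATYPES",
    "register_datatype",
    "create_bundle",
    "open_bundle",
    "create_collection",
    "import_dataset",
    "verify_integrity",
    "lock_collection",
    "release_lock",
    "rebuild_cache",
    "md5_file",
]

SUBFOLDERS = ("RawData", "Annotations", "Cache", "Collections")

#: Portable-name policy for bundles/collections (cross-platform paths).
_NAME_RE = re.compile(r"^[A-Za-z0-9._ -]+$")

LOCK_FILENAME = ".lock"
COLLECTION_META = "collection.xml"


class RepositoryError(Exception):
    pass


class LockError(RepositoryError):
    pass


def md5_file(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --- datatype handler registry ---------------------------------------------

@dataclass(frozen=True)
class DatatypeHandler:
    """Import-time hooks a viewportType contributes for its data type."""

    datatype_id: str
    describe: Callable[[Path], tuple[Optional[DatasetProperties], list[tuple[str, str]]]]
    previews: Callable[[Path], dict[str, bytes]]  # suffix -> PNG bytes


def _image_describe(path: Path):
    try:
        img, props = _dt.import_image(path)
    except ValueError:
        return None, []
    return props, list(img.header)


def _image_previews(path: Path) -> dict[str, bytes]:
    try:
        img, _ = _dt.import_image(path)
    except ValueError:
        return {}
    return {"thumb": _dt.make_thumbnail(img), "preview": _dt.make_preview(img)}


def _wave_describe(path: Path):
    try:
        series = _dt.import_wave(path)
    except ValueError:
        return None, []
    props = DatasetProperties([series.dimension], series.element)
    return props, [("samples", str(series.dimension.length))]


def _wave_previews(path: Path) -> dict[str, bytes]:
    try:
        series = _dt.import_wave(path)
    except ValueError:
        return {}
    png = _dt.wave_preview(series)
    return {"thumb": png, "preview": png}


#: Registered datatype handlers, keyed by datatype id.
DATATYPES: dict[str, DatatypeHandler] = {}


def register_datatype(handler: DatatypeHandler) -> None:
    if handler.datatype_id in DATATYPES:
        raise RepositoryError(f"datatype {handler.datatype_id!r} already registered")
    DATATYPES[handler.datatype_id] = handler


register_datatype(DatatypeHandler("image.grey", _image_describe, _image_previews))
register_datatype(DatatypeHandler("wave.equally-spaced", _wave_describe, _wave_previews))
register_datatype(DatatypeHandler("generic", lambda p: (None, []), lambda p: {}))


# --- collection / bundle objects -------------------------------------------

class Collection:
    """Handle on one collection directory; disk state is authoritative."""

    def __init__(self, path: Path):
        self.path = Path(path)

    @property
    def name(self) -> str:
        n = self.path.name
        return n[: -len(".bundle")] if n.endswith(".bundle") else n

    @property
    def raw_dir(self) -> Path:
        return self.path / "RawData"

    @property
    def annotations_dir(self) -> Path:
        return self.path / "Annotations"

    @property
    def cache_dir(self) -> Path:
        return self.path / "Cache"

    @property
    def collections_dir(self) -> Path:
        return self.path / "Collections"

    @property
    def metadata_path(self) -> Path:
        return self.annotations_dir / COLLECTION_META

    def read_metadata(self) -> MetadataDoc:
        return read_metadata(self.metadata_path)

    def write_metadata(self, doc: MetadataDoc) -> Path:
        return write_metadata(self.metadata_path, doc)

    def children(self) -> list["Collection"]:
        if not self.collections_dir.exists():
            return []
        return [Collection(p) for p in sorted(self.collections_dir.iterdir()) if p.is_dir()]

    def child(self, name: str) -> "Collection":
        p = self.collections_dir / name
        if not p.is_dir():
            raise RepositoryError(f"no sub-collection {name!r} in {self.path}")
        return Collection(p)

    def walk(self) -> Iterable["Collection"]:
        yield self
        for c in self.children():
            yield from c.walk()

    def dataset_ids(self) -> list[str]:
        if not self.raw_dir.exists():
            return []
        return sorted(p.name for p in self.raw_dir.iterdir() if p.is_dir())

    def dataset(self, dataset_id: str) -> "DatasetRecord":
        doc = read_metadata(self.annotations_dir / f"{dataset_id}.xml")
        return DatasetRecord(dataset_id, self, doc)

    def datasets(self) -> list["DatasetRecord"]:
        return [self.dataset(i) for i in self.dataset_ids()]

    @property
    def parent(self) -> Optional["Collection"]:
        p = self.path.parent
        if p.name == "Collections":
            return Collection(p.parent)
        return None

    # -- advisory locking ---------------------------------------------------

    @property
    def lock_path(self) -> Path:
        return self.path / LOCK_FILENAME

    def lock_owner(self) -> Optional[str]:
        if self.lock_path.exists():
            return self.lock_path.read_text(encoding="utf-8").splitlines()[0]
        return None

    def check_writable(self, owner: str) -> None:
        held = self.lock_owner()
        if held is not None and held != owner:
            raise LockError(f"collection {self.path} is locked by {held!r}")

    def __repr__(self) -> str:
        return f"Collection({str(self.path)!r})"


@dataclass
class Bundle:
    """The root collection, bound to a file-system path."""

    name: str
    fs_path: Path

    @property
    def root(self) -> Collection:
        return Collection(self.fs_path)

    def walk(self) -> Iterable[Collection]:
        return self.root.walk()


@dataclass
class DatasetRecord:
    """One imported unit of raw files plus its metadata document."""

    id: str
    collection: Collection
    doc: MetadataDoc

    @property
    def raw_dir(self) -> Path:
        return self.collection.raw_dir / self.id

    @property
    def metadata_path(self) -> Path:
        return self.collection.annotations_dir / f"{self.id}.xml"

    @property
    def datatype_id(self) -> str:
        return self.doc.datatype_id or "generic"

    @property
    def raw_files(self) -> list[RawFileRecord]:
        return self.doc.raw_files

    def stored_path(self, record: RawFileRecord) -> Path:
        if record.compressed:
            return self.raw_dir / (record.filename + ".zip")
        return self.raw_dir / record.filename

    def read_raw(self, record: RawFileRecord) -> bytes:
        """Raw file content with transparent decompression."""
        p = self.stored_path(record)
        if record.compressed:
            with zipfile.ZipFile(p) as zf:
                return zf.read(record.filename)
        return p.read_bytes()

    def save(self) -> Path:
        return write_metadata(self.metadata_path, self.doc)


@dataclass
class IntegrityReport:
    checked: int = 0
    passed: int = 0
    failures: list[tuple[str, str, str]] = field(default_factory=list)  # path, expected, actual

    @property
    def ok(self) -> bool:
        return not self.failures


# --- operations ------------------------------------------------------------

def _check_name(name: str) -> None:
    if not name or not _NAME_RE.match(name):
        raise RepositoryError(
            f"invalid name {name!r}: use only letters, digits, '.', '_', '-', ' '"
        )


def _make_collection_dir(path: Path) -> None:
    path.mkdir(parents=False, exist_ok=False)
    for sub in SUBFOLDERS:
        (path / sub).mkdir()


def create_bundle(parent_dir: Path, name: str) -> Bundle:
    """Create ``<parent>/<name>.bundle`` with the four subfolders.

    Refuses to touch an existing path (no silent overwrite).
    """
    _check_name(name)
    parent_dir = Path(parent_dir)
    path = parent_dir / f"{name}.bundle"
    if path.exists():
        raise RepositoryError(f"{path} already exists")
    _make_collection_dir(path)
    bundle = Bundle(name, path)
    bundle.root.write_metadata(MetadataDoc())
    return bundle


def open_bundle(path: Path) -> Bundle:
    path = Path(path)
    if not path.is_dir() or not path.name.endswith(".bundle"):
        raise RepositoryError(f"{path} is not a bundle directory")
    return Bundle(path.name[: -len(".bundle")], path)


def create_collection(
    parent: Collection,
    name: str,
    protocol_id: Optional[str] = None,
    importer_id: Optional[str] = None,
    protocols=None,
    owner: str = "local",
) -> Collection:
    """Create a sub-collection under ``parent``'s Collections/ folder.

    When a protocol id is given it must resolve in the protocol store and
    its collection part is instantiated with defaults into the new
    collection's metadata.
    """
    from .metadata import apply_protocol  # local import keeps module load light

    _check_name(name)
    parent.check_writable(owner)
    template = None
    if protocol_id is not None:
        if protocols is None or protocol_id not in getattr(protocols, "templates", {}):
            raise RepositoryError(f"unknown collection protocol {protocol_id!r}")
        template = protocols.templates[protocol_id]
    target = parent.collections_dir / name
    if target.exists():
        raise RepositoryError(f"sibling collection {name!r} already exists")
    parent.collections_dir.mkdir(exist_ok=True)
    _make_collection_dir(target)
    coll = Collection(target)
    doc = MetadataDoc()
    if template is not None:
        apply_protocol(doc, template, part="collection")
        for k, v in template.init:
            doc.embedded_set(k, v)
    if importer_id is not None:
        doc.embedded_set("importer", importer_id)
    coll.write_metadata(doc)
    return coll


def _next_dataset_id(collection: Collection, first_filename: str) -> str:
    ordinal = len(collection.dataset_ids()) + 1
    stem = re.sub(r"[^A-Za-z0-9._-]", "_", Path(first_filename).name)
    return f"{ordinal:04d}_{stem}"


def import_dataset(
    collection: Collection,
    source_files: Sequence[Path],
    datatype_id: str = "generic",
    compress: bool = False,
    owner: str = "local",
) -> DatasetRecord:
    """Copy raw files into the collection and record their checksums.

    Sources are left untouched.  MD5 is computed over the uncompressed
    content; with ``compress`` each file is stored as a single-entry
    deflate ZIP named ``<original>.zip``.  The datatype handler extracts
    embedded header keys and dataset properties and renders thumbnail and
    preview PNGs into Annotations/.  A ``<source>.attr`` sidecar next to
    a source file is ingested into the embedded metadata.  On any error
    no partial dataset remains.
    """
    collection.check_writable(owner)
    if datatype_id not in DATATYPES:
        raise RepositoryError(f"unregistered datatype {datatype_id!r}")
    if not source_files:
        raise RepositoryError("no source files given")
    sources = [Path(p) for p in source_files]
    for p in sources:
        if not p.is_file():
            raise RepositoryError(f"source file not readable: {p}")
    handler = DATATYPES[datatype_id]
    dataset_id = _next_dataset_id(collection, sources[0].name)
    target_dir = collection.raw_dir / dataset_id
    written: list[Path] = []
    try:
        target_dir.mkdir(parents=True, exist_ok=False)
        doc = MetadataDoc(datatype_id=datatype_id)
        for src in sources:
            md5 = md5_file(src)
            size = src.stat().st_size
            if compress:
                dst = target_dir / (src.name + ".zip")
                with zipfile.ZipFile(dst, "w", compression=zipfile.ZIP_DEFLATED) as zf:
                    zf.write(src, arcname=src.name)
            else:
                dst = target_dir / src.name
                shutil.copy2(src, dst)
            written.append(dst)
            doc.raw_files.append(RawFileRecord(src.name, size, md5, compress))
            attr = src.with_name(src.name + ".attr")
            if attr.is_file():
                ingest_attribute_file(doc, attr)
        # first decodable source defines properties/header
        for src in sources:
            props, header = handler.describe(src)
            if props is not None or header:
                doc.properties = props
                for k, v in header:
                    doc.embedded_set(k, v)
                break
        collection.annotations_dir.mkdir(exist_ok=True)
        for src in sources:
            for suffix, png in handler.previews(src).items():
                out = collection.annotations_dir / f"{dataset_id}_{src.name}_{suffix}.png"
                out.write_bytes(png)
                written.append(out)
        record = DatasetRecord(dataset_id, collection, doc)
        record.save()
        written.append(record.metadata_path)
        _populate_cache(collection, record)
        return record
    except BaseException:
        shutil.rmtree(target_dir, ignore_errors=True)
        for p in written:
            if p.exists() and p.parent != target_dir:
                p.unlink()
        raise


def verify_integrity(scope: Bundle | Collection) -> IntegrityReport:
    """Hash every recorded raw file (after transparent decompression) and
    compare with the stored MD5.  Missing files are failures, not errors.
    """
    root = scope.root if isinstance(scope, Bundle) else scope
    report = IntegrityReport()
    for coll in root.walk():
        for ds in coll.datasets():
            for rec in ds.raw_files:
                report.checked += 1
                stored = ds.stored_path(rec)
                rel = str(stored)
                if not stored.exists():
                    report.failures.append((rel, rec.md5_hex, "missing"))
                    continue
                try:
                    actual = hashlib.md5(ds.read_raw(rec)).hexdigest()
                except (OSError, zipfile.BadZipFile, KeyError):
                    report.failures.append((rel, rec.md5_hex, "unreadable"))
                    continue
                if actual == rec.md5_hex:
                    report.passed += 1
                else:
                    report.failures.append((rel, rec.md5_hex, actual))
    return report


def lock_collection(collection: Collection, owner: str) -> Path:
    """Take (or re-take) the advisory lock; stealing is refused."""
    held = collection.lock_owner()
    if held is not None and held != owner:
        raise LockError(f"already locked by {held!r}")
    from .hcoords import now

    ts = now()
    collection.lock_path.write_text(f"{owner}\n{ts.seconds}.{ts.fraction}\n", encoding="utf-8")
    return collection.lock_path


def release_lock(collection: Collection, owner: str) -> None:
    held = collection.lock_owner()
    if held is None:
        return
    if held != owner:
        raise LockError(f"lock held by {held!r}, not {owner!r}")
    collection.lock_path.unlink()


def _populate_cache(collection: Collection, record: DatasetRecord) -> int:
    """Write the derived cache entries for one dataset (preview copies)."""
    handler = DATATYPES.get(record.datatype_id)
    count = 0
    collection.cache_dir.mkdir(exist_ok=True)
    for rec in record.raw_files:
        if handler is None:
            continue
        if rec.compressed:
            # derive from the uncompressed content via a scratch copy
            import tempfile

            with tempfile.TemporaryDirectory() as td:
                tmp = Path(td) / rec.filename
                tmp.write_bytes(record.read_raw(rec))
                previews = handler.previews(tmp)
        else:
            previews = handler.previews(record.stored_path(rec))
        for suffix, png in previews.items():
            if suffix != "preview":
                continue
            out = collection.cache_dir / f"{record.id}_{rec.filename}_{suffix}.png"
            out.write_bytes(png)
            count += 1
    return count


def coordinate_path(entity: Collection | DatasetRecord) -> list:
    """Coordinate chain from the nearest frame root down to ``entity``.

    Walks up the collection tree collecting every stored coordinate
    record, stopping at the first (nearest) rootflag — the path
    :func:`bebkit.hcoords.resolve_absolute` expects.  Entities without a
    stored coordinate contribute nothing (zero offset).
    """
    chain = []
    if isinstance(entity, DatasetRecord):
        if entity.doc.coords is not None:
            chain.append(entity.doc.coords)
        node: Optional[Collection] = entity.collection
    else:
        node = entity
    while node is not None:
        try:
            doc = node.read_metadata()
        except (MetadataError, FileNotFoundError):
            doc = None
        if doc is not None and doc.coords is not None:
            chain.append(doc.coords)
            if doc.coords.rootflag:
                break
        node = node.parent
    chain.reverse()
    return chain


def rebuild_cache(collection: Collection) -> int:
    """Drop and regenerate Cache/ from RawData + Annotations.

    The result is a pure function of the raw data, so rebuilding twice
    yields identical file sets.  Returns the number of regenerated files.
    """
    if collection.cache_dir.exists():
        shutil.rmtree(collection.cache_dir)
    collection.cache_dir.mkdir()
    count = 0
    for ds in collection.datasets():
        count += _populate_cache(collection, ds)
    return count
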