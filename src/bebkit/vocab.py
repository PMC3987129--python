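"""Controlled vocabulary, protocol templates, and support-folder updates.

All annotation protocols in a workgroup are assembled from one shared
library of vocabulary entries, each carrying an immutable unique id (UID).
A protocol template has a collection part, a dataset part and an init
list; each part is an ordered list of references into the library, with
optional per-template title/default overrides.  Because templates store
*references*, editing a library entry propagates automatically to every
template that has not overridden it — the point of UID-based vocabularies.

The per-user application support folder (protocols, macros, plug-ins,
error definitions) is kept in sync with a workgroup repository through a
``manifest.xml`` listing file hashes and the range of core versions the
content is compatible with.
"""

from __future__ import annotations

import hashlib
import shutil
import tempfile
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

__all__ = [
    "CORE_VERSION",
    "VocabularyEntry",
    "EntryRef",
    "ResolvedEntry",
    "VocabularyLibrary",
    "ProtocolTemplate",
    "ProtocolStore",
    "SupportManifest",
    "UpdateReport",
    "VocabError",
    "new_uid",
    "write_manifest",
    "read_manifest",
    "sync_support_folder",
    "init_support_folder",
]

#: Version of this core, checked against support-folder manifests.
CORE_VERSION = "0.1.0"

SUPPORT_SUBDIRS = ("protocols", "macros", "plugins", "errors")

VALUE_KINDS = ("text", "number", "enum", "date")


class VocabError(ValueError):
    pass


def new_uid() -> str:
    """Opaque ASCII token, generated once per vocabulary entry."""
    return uuid.uuid4().hex[:12]


@dataclass
class VocabularyEntry:
    uid: str
    title: str
    value_kind: str = "text"
    default: object = None
    allowed: Optional[list] = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise VocabError(f"unknown value kind {self.value_kind!r}")
        if self.value_kind == "enum":
            if not self.allowed:
                raise VocabError(f"enum entry {self.uid} needs an allowed list")
            if self.default is not None and self.default not in self.allowed:
                raise VocabError(f"default {self.default!r} not in allowed list")


@dataclass(frozen=True)
class EntryRef:
    """Reference to a library entry, with optional local overrides."""

    uid: str
    title_override: Optional[str] = None
    default_override: object = None


@dataclass(frozen=True)
class ResolvedEntry:
    """Effective entry after merging library values with overrides."""

    uid: str
    title: str
    value_kind: str
    default: object
    allowed: Optional[tuple]


class VocabularyLibrary:
    """The shared entry library; UIDs are unique and immutable."""

    def __init__(self) -> None:
        self._entries: dict[str, VocabularyEntry] = {}

    def add(self, entry: VocabularyEntry) -> VocabularyEntry:
        if entry.uid in self._entries:
            raise VocabError(f"uid {entry.uid!r} already in library")
        self._entries[entry.uid] = entry
        return entry

    def get(self, uid: str) -> VocabularyEntry:
        try:
            return self._entries[uid]
        except KeyError:
            raise VocabError(f"unknown vocabulary uid {uid!r}") from None

    def __contains__(self, uid: str) -> bool:
        return uid in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)


@dataclass
class ProtocolTemplate:
    protocol_id: str
    library: VocabularyLibrary
    collection_part: list[EntryRef] = field(default_factory=list)
    dataset_part: list[EntryRef] = field(default_factory=list)
    init: list[tuple[str, str]] = field(default_factory=list)

    def resolve(self, ref: EntryRef) -> ResolvedEntry:
        ent = self.library.get(ref.uid)
        return ResolvedEntry(
            uid=ent.uid,
            title=ref.title_override if ref.title_override is not None else ent.title,
            value_kind=ent.value_kind,
            default=ref.default_override if ref.default_override is not None else ent.default,
            allowed=tuple(ent.allowed) if ent.allowed is not None else None,
        )

    def references(self, uid: str, overridden_ok: bool = False) -> bool:
        for ref in list(self.collection_part) + list(self.dataset_part):
            if ref.uid != uid:
                continue
            if overridden_ok:
                return True
            if ref.title_override is None and ref.default_override is None:
                return True
        return False


class ProtocolStore:
    """Library + templates persisted under ``support/protocols/``."""

    def __init__(self, library: Optional[VocabularyLibrary] = None) -> None:
        self.library = library or VocabularyLibrary()
        self.templates: dict[str, ProtocolTemplate] = {}

    # -- assembly / propagation --------------------------------------------

    def assemble_protocol(
        self,
        protocol_id: str,
        collection_refs: Iterable[EntryRef | str],
        dataset_refs: Iterable[EntryRef | str] = (),
        init: Iterable[tuple[str, str]] = (),
    ) -> ProtocolTemplate:
        """Build a template from library references (strings become refs).

        Duplicate UIDs within a part are allowed and kept in order —
        repeatable measurement blocks.  Dangling references are rejected
        with the full list of missing UIDs.
        """
        def norm(refs):
            return [EntryRef(r) if isinstance(r, str) else r for r in refs]

        c_refs, d_refs = norm(collection_refs), norm(dataset_refs)
        missing = sorted({r.uid for r in c_refs + d_refs if r.uid not in self.library})
        if missing:
            raise VocabError(f"unresolved vocabulary uids: {', '.join(missing)}")
        tmpl = ProtocolTemplate(protocol_id, self.library, c_refs, d_refs, list(init))
        self.templates[protocol_id] = tmpl
        return tmpl

    def update_vocab_entry(
        self,
        uid: str,
        new_title: Optional[str] = None,
        new_default: object = None,
    ) -> list[str]:
        """Edit a library entry; return the protocol ids the edit reaches.

        A template is affected iff it references the UID without a local
        override of the edited field(s); overridden references keep their
        local values (override precedence).
        """
        ent = self.library.get(uid)
        if new_title is not None:
            ent.title = new_title
        if new_default is not None:
            if ent.allowed is not None and new_default not in ent.allowed:
                raise VocabError(f"default {new_default!r} not in allowed list of {uid}")
            ent.default = new_default
        return sorted(
            pid for pid, t in self.templates.items() if t.references(uid)
        )

    # -- persistence --------------------------------------------------------

    def save(self, protocols_dir: Path) -> None:
        protocols_dir = Path(protocols_dir)
        protocols_dir.mkdir(parents=True, exist_ok=True)
        root = etree.Element("beb-vocabulary")
        for ent in sorted(self.library, key=lambda e: e.uid):
            e = etree.SubElement(root, "entry")
            e.set("uid", ent.uid)
            e.set("title", ent.title)
            e.set("kind", ent.value_kind)
            if ent.default is not None:
                e.set("default", str(ent.default))
            if ent.allowed is not None:
                e.set("allowed", "|".join(str(a) for a in ent.allowed))
        (protocols_dir / "vocabulary.xml").write_bytes(
            etree.tostring(root, pretty_print=True, encoding="utf-8")
        )
        for pid, tmpl in sorted(self.templates.items()):
            root = etree.Element("beb-protocol")
            root.set("id", pid)
            for part_name, refs in (
                ("collection", tmpl.collection_part),
                ("dataset", tmpl.dataset_part),
            ):
                pe = etree.SubElement(root, part_name)
                for ref in refs:
                    re_ = etree.SubElement(pe, "ref")
                    re_.set("uid", ref.uid)
                    if ref.title_override is not None:
                        re_.set("title", ref.title_override)
                    if ref.default_override is not None:
                        re_.set("default", str(ref.default_override))
            ie = etree.SubElement(root, "init")
            for k, v in tmpl.init:
                item = etree.SubElement(ie, "item")
                item.set("key", k)
                item.text = str(v)
            (protocols_dir / f"{pid}.protocol.xml").write_bytes(
                etree.tostring(root, pretty_print=True, encoding="utf-8")
            )

    @classmethod
    def load(cls, protocols_dir: Path) -> "ProtocolStore":
        protocols_dir = Path(protocols_dir)
        store = cls()
        vocab_path = protocols_dir / "vocabulary.xml"
        if vocab_path.exists():
            root = etree.parse(str(vocab_path)).getroot()
            for e in root.findall("entry"):
                allowed = e.get("allowed")
                store.library.add(
                    VocabularyEntry(
                        uid=e.get("uid"),
                        title=e.get("title"),
                        value_kind=e.get("kind"),
                        default=e.get("default"),
                        allowed=allowed.split("|") if allowed is not None else None,
                    )
                )
        for path in sorted(protocols_dir.glob("*.protocol.xml")):
            root = etree.parse(str(path)).getroot()
            pid = root.get("id")
            parts = {}
            for part_name in ("collection", "dataset"):
                refs = []
                pe = root.find(part_name)
                if pe is not None:
                    for re_ in pe.findall("ref"):
                        refs.append(
                            EntryRef(re_.get("uid"), re_.get("title"), re_.get("default"))
                        )
                parts[part_name] = refs
            init = []
            ie = root.find("init")
            if ie is not None:
                for item in ie.findall("item"):
                    init.append((item.get("key"), item.text or ""))
            store.templates[pid] = ProtocolTemplate(
                pid, store.library, parts["collection"], parts["dataset"], init
            )
        return store


# --- support-folder synchronization ----------------------------------------

@dataclass(frozen=True)
class SupportManifest:
    version: str
    core_min: str
    core_max: str
    files: tuple[tuple[str, str], ...]  # (relative path, md5 hex)


@dataclass(frozen=True)
class UpdateReport:
    added: int
    replaced: int
    removed: int
    incompatible: bool = False


def _version_key(v: str) -> tuple:
    return tuple(int(p) for p in v.split("."))


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(repo_dir: Path, version: str, core_min: str, core_max: str) -> SupportManifest:
    """Scan a repository directory and (re)write its manifest.xml."""
    repo_dir = Path(repo_dir)
    files = []
    for p in sorted(repo_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.xml":
            files.append((p.relative_to(repo_dir).as_posix(), _md5(p)))
    root = etree.Element("beb-manifest")
    root.set("version", version)
    root.set("core-min", core_min)
    root.set("core-max", core_max)
    for rel, md5 in files:
        fe = etree.SubElement(root, "file")
        fe.set("path", rel)
        fe.set("md5", md5)
    (repo_dir / "manifest.xml").write_bytes(
        etree.tostring(root, pretty_print=True, encoding="utf-8")
    )
    return SupportManifest(version, core_min, core_max, tuple(files))


def read_manifest(repo_dir: Path) -> SupportManifest:
    path = Path(repo_dir) / "manifest.xml"
    if not path.exists():
        raise FileNotFoundError(f"repository manifest not found: {path}")
    root = etree.parse(str(path)).getroot()
    files = tuple((fe.get("path"), fe.get("md5")) for fe in root.findall("file"))
    return SupportManifest(
        root.get("version"), root.get("core-min"), root.get("core-max"), files
    )


def sync_support_folder(
    local_dir: Path, repo: Path, core_version: str = CORE_VERSION
) -> UpdateReport:
    """Bring a local support folder in line with a repository manifest.

    The new state is staged in a temporary sibling directory and swapped
    in with atomic renames, so a failed sync leaves the previous state
    intact.  When the manifest's compatible core range excludes
    ``core_version`` nothing is written and ``incompatible`` is set.
    """
    local_dir, repo = Path(local_dir), Path(repo)
    manifest = read_manifest(repo)
    if not (
        _version_key(manifest.core_min)
        <= _version_key(core_version)
        <= _version_key(manifest.core_max)
    ):
        return UpdateReport(0, 0, 0, incompatible=True)

    local_files = {}
    if local_dir.exists():
        for p in local_dir.rglob("*"):
            if p.is_file() and p.name != "manifest.xml":
                local_files[p.relative_to(local_dir).as_posix()] = _md5(p)

    wanted = dict(manifest.files)
    added = sum(1 for rel in wanted if rel not in local_files)
    replaced = sum(1 for rel, md5 in wanted.items() if local_files.get(rel) not in (None, md5))
    removed = sum(1 for rel in local_files if rel not in wanted)
    if added == replaced == removed == 0 and local_dir.exists():
        return UpdateReport(0, 0, 0)

    stage = Path(tempfile.mkdtemp(prefix=".sync-stage-", dir=local_dir.parent))
    try:
        for rel in wanted:
            src = repo / rel
            dst = stage / rel
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.copy2(src, dst)
        shutil.copy2(repo / "manifest.xml", stage / "manifest.xml")
        backup = local_dir.with_name(local_dir.name + ".old")
        if backup.exists():
            shutil.rmtree(backup)
        if local_dir.exists():
            local_dir.rename(backup)
        stage.rename(local_dir)
        if backup.exists():
            shutil.rmtree(backup)
    except BaseException:
        shutil.rmtree(stage, ignore_errors=True)
        raise
    return UpdateReport(added, replaced, removed)


def init_support_folder(local_dir: Path) -> Path:
    """Create an empty support folder with the standard sub-directories."""
    local_dir = Path(local_dir)
    for sub in SUPPORT_SUBDIRS:
        (local_dir / sub).mkdir(parents=True, exist_ok=True)
    return local_dir
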