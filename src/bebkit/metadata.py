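"""XML metadata documents for collections and datasets.

Every collection and dataset owns one XML document gathering: protocol
instances (controlled-vocabulary annotations), a free-text user description
with a 0-5 rating, the database id assigned at synchronization time
(collections only), the hierarchical coordinate record, dataset properties
(dimensions + element descriptor), metadata embedded in the raw files, and
stored graphical "views".  Unknown elements found in a document are
preserved verbatim across rewrites, so newer documents survive older
software (forward compatibility).

The serialization is canonical: fixed section order, deterministic pretty
printing, UTF-8.  ``write(read(write(doc)))`` is byte-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

from lxml import etree
from PIL import Image, ImageDraw

from .hcoords import HCoord, Timestamp128

__all__ = [
    "PRECISIONS",
    "UserDescription",
    "Dimension",
    "ElementDescriptor",
    "DatasetProperties",
    "InstanceEntry",
    "ProtocolInstance",
    "RawFileRecord",
    "ViewRecord",
    "MetadataDoc",
    "MetadataError",
    "read_metadata",
    "write_metadata",
    "apply_protocol",
    "ingest_attribute_file",
    "add_view",
    "batch_annotate",
]

#: Memory structures an element descriptor may name.
PRECISIONS = ("uint8", "uint16", "int32", "int64", "float32", "float64")

KNOWN_SECTIONS = (
    "protocols",
    "user",
    "database",
    "coordinates",
    "properties",
    "embedded",
    "rawfiles",
    "views",
)


class MetadataError(ValueError):
    pass


@dataclass
class UserDescription:
    free_text: str = ""
    rating: int = 0

    def __post_init__(self) -> None:
        if not (0 <= int(self.rating) <= 5):
            raise MetadataError(f"rating {self.rating} outside 0-5")
        self.rating = int(self.rating)


@dataclass
class Dimension:
    """One axis of a dataset: name, kind, unit, sampling and length.

    ``start``/``spacing`` describe equally spaced numeric axes; index axes
    carry no spacing.
    """

    name: str
    kind: str = "numeric"  # numeric | index
    unit: str = ""
    start: float = 0.0
    spacing: Optional[float] = None
    length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "index"):
            raise MetadataError(f"dimension kind {self.kind!r}")
        if self.length < 1:
            raise MetadataError("dimension length must be >= 1")
        if self.kind == "index" and self.spacing is not None:
            raise MetadataError("index dimensions carry no spacing")

    @property
    def end(self) -> float:
        if self.spacing is None:
            return self.start
        return self.start + (self.length - 1) * self.spacing


@dataclass
class ElementDescriptor:
    name: str
    unit: str = ""
    kind: str = "numeric"  # numeric | category
    precision: str = "float64"

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "category"):
            raise MetadataError(f"element kind {self.kind!r}")
        if self.precision not in PRECISIONS:
            raise MetadataError(f"unknown precision {self.precision!r}")


@dataclass
class DatasetProperties:
    dimensions: list[Dimension]
    element: ElementDescriptor

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise MetadataError("at least one dimension required")


@dataclass
class InstanceEntry:
    """One filled-in protocol field, tied to its vocabulary UID."""

    uid: str
    title: str
    value_kind: str = "text"  # text | number | enum | date
    value: object = None
    allowed: Optional[list] = None

    def set_value(self, value) -> None:
        if self.allowed is not None and value not in self.allowed:
            raise MetadataError(
                f"value {value!r} not in controlled list {self.allowed} for {self.uid}"
            )
        self.value = value


@dataclass
class ProtocolInstance:
    protocol_id: str
    entries: list[InstanceEntry] = field(default_factory=list)

    def entry(self, uid: str) -> InstanceEntry:
        for e in self.entries:
            if e.uid == uid:
                return e
        raise KeyError(uid)


@dataclass
class RawFileRecord:
    """Integrity record of one imported raw file.

    ``md5_hex`` always hashes the *uncompressed* content, whether or not
    the file is stored ZIP-compressed on disk.
    """

    filename: str
    byte_size: int
    md5_hex: str
    compressed: bool = False

    def __post_init__(self) -> None:
        if len(self.md5_hex) != 32 or self.md5_hex != self.md5_hex.lower():
            raise MetadataError(f"md5 must be 32 lowercase hex chars, got {self.md5_hex!r}")


@dataclass
class ViewRecord:
    """A stored graphical representation plus optional burned-in shapes."""

    view_name: str
    generator_id: str
    image_path: str  # relative to the Annotations/ folder
    shapes: list[tuple] = field(default_factory=list)  # (kind, coords, label)

    SHAPE_KINDS = ("point", "line", "rect", "ellipse", "text")


@dataclass
class MetadataDoc:
    protocols: list[ProtocolInstance] = field(default_factory=list)
    user: UserDescription = field(default_factory=UserDescription)
    database_id: Optional[str] = None
    coords: Optional[HCoord] = None
    properties: Optional[DatasetProperties] = None
    embedded: list[tuple[str, str]] = field(default_factory=list)
    views: list[ViewRecord] = field(default_factory=list)
    # dataset documents only: the imported raw files and their datatype
    datatype_id: Optional[str] = None
    raw_files: list[RawFileRecord] = field(default_factory=list)
    # forward-compatible payload: unknown top-level elements, kept verbatim
    unknown: list = field(default_factory=list)

    def embedded_get(self, key: str) -> Optional[str]:
        for k, v in self.embedded:
            if k == key:
                return v
        return None

    def embedded_set(self, key: str, value: str) -> None:
        for i, (k, _) in enumerate(self.embedded):
            if k == key:
                self.embedded[i] = (key, value)
                return
        self.embedded.append((key, value))


# --- serialization ---------------------------------------------------------

def _coord_to_xml(parent: etree._Element, c: HCoord) -> None:
    e = etree.SubElement(parent, "coordinates")
    e.set("rootflag", "true" if c.rootflag else "false")
    for name in ("x", "y", "z", "dx", "dy", "dz"):
        etree.SubElement(e, name).text = str(getattr(c, name))
    etree.SubElement(e, "scale").text = repr(c.scale)
    t = etree.SubElement(e, "t")
    t.set("seconds", str(c.t.seconds))
    t.set("fraction", str(c.t.fraction))
    etree.SubElement(e, "dt").text = repr(c.dt)
    etree.SubElement(e, "description").text = c.description or None


def _coord_from_xml(e: etree._Element) -> HCoord:
    def text(tag):
        el = e.find(tag)
        return el.text if el is not None else None

    t_el = e.find("t")
    return HCoord(
        x=int(text("x")), y=int(text("y")), z=int(text("z")),
        rootflag=e.get("rootflag") == "true",
        scale=float(text("scale")),
        dx=int(text("dx")), dy=int(text("dy")), dz=int(text("dz")),
        t=Timestamp128(int(t_el.get("seconds")), int(t_el.get("fraction"))),
        dt=float(text("dt")),
        description=text("description") or "",
    )


def doc_to_xml(doc: MetadataDoc) -> etree._Element:
    root = etree.Element("beb-metadata")

    protos = etree.SubElement(root, "protocols")
    for inst in doc.protocols:
        p = etree.SubElement(protos, "protocol")
        p.set("id", inst.protocol_id)
        for ent in inst.entries:
            x = etree.SubElement(p, "entry")
            x.set("uid", ent.uid)
            x.set("title", ent.title)
            x.set("kind", ent.value_kind)
            if ent.allowed is not None:
                x.set("allowed", "|".join(str(a) for a in ent.allowed))
            x.text = None if ent.value is None else str(ent.value)

    user = etree.SubElement(root, "user")
    user.set("rating", str(doc.user.rating))
    user.text = doc.user.free_text or None

    if doc.database_id is not None:
        db = etree.SubElement(root, "database")
        db.set("id", doc.database_id)

    if doc.coords is not None:
        _coord_to_xml(root, doc.coords)

    if doc.properties is not None:
        props = etree.SubElement(root, "properties")
        for d in doc.properties.dimensions:
            de = etree.SubElement(props, "dimension")
            de.set("name", d.name)
            de.set("kind", d.kind)
            de.set("unit", d.unit)
            de.set("start", repr(d.start))
            if d.spacing is not None:
                de.set("spacing", repr(d.spacing))
            de.set("length", str(d.length))
        el = etree.SubElement(props, "element")
        el.set("name", doc.properties.element.name)
        el.set("unit", doc.properties.element.unit)
        el.set("kind", doc.properties.element.kind)
        el.set("precision", doc.properties.element.precision)

    emb = etree.SubElement(root, "embedded")
    for k, v in doc.embedded:
        it = etree.SubElement(emb, "item")
        it.set("key", k)
        it.text = str(v) if v != "" else None

    if doc.datatype_id is not None or doc.raw_files:
        rf = etree.SubElement(root, "rawfiles")
        if doc.datatype_id is not None:
            rf.set("datatype", doc.datatype_id)
        for r in doc.raw_files:
            fe = etree.SubElement(rf, "file")
            fe.set("name", r.filename)
            fe.set("size", str(r.byte_size))
            fe.set("md5", r.md5_hex)
            fe.set("compressed", "true" if r.compressed else "false")

    views = etree.SubElement(root, "views")
    for v in doc.views:
        ve = etree.SubElement(views, "view")
        ve.set("name", v.view_name)
        ve.set("generator", v.generator_id)
        ve.set("image", v.image_path)
        for kind, coords, label in v.shapes:
            se = etree.SubElement(ve, "shape")
            se.set("kind", kind)
            se.set("coords", ",".join(repr(float(c)) for c in coords))
            se.set("label", label)

    for extra in doc.unknown:
        root.append(copy.deepcopy(extra))
    return root


def doc_from_xml(root: etree._Element) -> MetadataDoc:
    doc = MetadataDoc()
    for child in root:
        if not isinstance(child.tag, str):
            continue  # comments etc.
        tag = child.tag
        if tag == "protocols":
            for p in child.findall("protocol"):
                inst = ProtocolInstance(p.get("id"))
                for x in p.findall("entry"):
                    allowed = x.get("allowed")
                    inst.entries.append(
                        InstanceEntry(
                            uid=x.get("uid"),
                            title=x.get("title"),
                            value_kind=x.get("kind"),
                            value=x.text,
                            allowed=allowed.split("|") if allowed is not None else None,
                        )
                    )
                doc.protocols.append(inst)
        elif tag == "user":
            doc.user = UserDescription(child.text or "", int(child.get("rating", "0")))
        elif tag == "database":
            doc.database_id = child.get("id")
        elif tag == "coordinates":
            doc.coords = _coord_from_xml(child)
        elif tag == "properties":
            dims = []
            for de in child.findall("dimension"):
                spacing = de.get("spacing")
                dims.append(
                    Dimension(
                        name=de.get("name"),
                        kind=de.get("kind"),
                        unit=de.get("unit", ""),
                        start=float(de.get("start", "0")),
                        spacing=float(spacing) if spacing is not None else None,
                        length=int(de.get("length")),
                    )
                )
            el = child.find("element")
            doc.properties = DatasetProperties(
                dims,
                ElementDescriptor(
                    el.get("name"), el.get("unit", ""), el.get("kind"), el.get("precision")
                ),
            )
        elif tag == "embedded":
            for it in child.findall("item"):
                doc.embedded.append((it.get("key"), it.text or ""))
        elif tag == "rawfiles":
            doc.datatype_id = child.get("datatype")
            for fe in child.findall("file"):
                doc.raw_files.append(
                    RawFileRecord(
                        fe.get("name"),
                        int(fe.get("size")),
                        fe.get("md5"),
                        fe.get("compressed") == "true",
                    )
                )
        elif tag == "views":
            for ve in child.findall("view"):
                shapes = []
                for se in ve.findall("shape"):
                    coords = tuple(float(c) for c in se.get("coords").split(",")) if se.get("coords") else ()
                    shapes.append((se.get("kind"), coords, se.get("label", "")))
                doc.views.append(
                    ViewRecord(ve.get("name"), ve.get("generator"), ve.get("image"), shapes)
                )
        else:
            doc.unknown.append(copy.deepcopy(child))
    return doc


def write_metadata(path: Path, doc: MetadataDoc) -> Path:
    """Serialize a document to canonical UTF-8 XML at ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = etree.tostring(
        doc_to_xml(doc), pretty_print=True, encoding="utf-8", xml_declaration=True
    )
    path.write_bytes(data)
    return path


def read_metadata(path: Path) -> MetadataDoc:
    """Parse a metadata document; parse errors carry the line number."""
    parser = etree.XMLParser(remove_blank_text=True)
    try:
        root = etree.parse(str(path), parser).getroot()
    except etree.XMLSyntaxError as exc:
        raise MetadataError(f"malformed metadata XML in {path}: {exc}") from exc
    if root.tag != "beb-metadata":
        raise MetadataError(f"{path}: unexpected root element {root.tag!r}")
    return doc_from_xml(root)


# --- operations ------------------------------------------------------------

def apply_protocol(doc: MetadataDoc, template, part: str = "collection") -> ProtocolInstance:
    """Instantiate a protocol template into a document.

    Every template entry is copied with its default value and vocabulary
    UID; repeated application appends a fresh instance (repeatable
    measurement blocks), never touching earlier ones.
    """
    refs = template.collection_part if part == "collection" else template.dataset_part
    inst = ProtocolInstance(template.protocol_id)
    for ref in refs:
        ent = template.resolve(ref)
        inst.entries.append(
            InstanceEntry(
                uid=ent.uid,
                title=ent.title,
                value_kind=ent.value_kind,
                value=ent.default,
                allowed=list(ent.allowed) if ent.allowed is not None else None,
            )
        )
    doc.protocols.append(inst)
    return inst


def ingest_attribute_file(doc: MetadataDoc, attr_path: Path, log=None) -> int:
    """Merge a ``key=value`` attribute file into the embedded section.

    UTF-8 text, one pair per line, ``#`` starts a comment.  Later keys
    overwrite earlier ones; unparseable lines are skipped (and logged when
    a log handler is given).  Returns the number of lines ingested.
    """
    count = 0
    for lineno, raw in enumerate(Path(attr_path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            if log is not None:
                log.log("metadata", "warning", f"{attr_path}:{lineno}: unparseable line skipped")
            continue
        key, _, value = line.partition("=")
        doc.embedded_set(key.strip(), value.strip())
        count += 1
    return count


def add_view(
    annotations_dir: Path,
    doc: MetadataDoc,
    view_name: str,
    source_image: Image.Image,
    shapes: Sequence[tuple] = (),
    generator_id: str = "manual",
) -> ViewRecord:
    """Store a view PNG (plus an annotated copy when shapes are given).

    Shapes are kept as editable records in the document *and* burned into
    ``<name>_annotated.png`` so third-party tools see the picture.
    """
    if any(v.view_name == view_name for v in doc.views):
        raise MetadataError(f"duplicate view name {view_name!r}")
    for kind, coords, _label in shapes:
        if kind not in ViewRecord.SHAPE_KINDS:
            raise MetadataError(f"unknown shape kind {kind!r}")
    annotations_dir = Path(annotations_dir)
    annotations_dir.mkdir(parents=True, exist_ok=True)
    plain = f"{view_name}.png"
    source_image.save(annotations_dir / plain, format="PNG")
    rec = ViewRecord(view_name, generator_id, plain, [tuple(s) for s in shapes])
    if shapes:
        annotated = source_image.convert("RGB")
        draw = ImageDraw.Draw(annotated)
        for kind, coords, label in shapes:
            _draw_shape(draw, kind, coords, label)
        annotated.save(annotations_dir / f"{view_name}_annotated.png", format="PNG")
    doc.views.append(rec)
    return rec


def _draw_shape(draw: ImageDraw.ImageDraw, kind: str, coords, label: str) -> None:
    color = (255, 64, 64)
    if kind == "point":
        x, y = coords[:2]
        draw.ellipse([x - 2, y - 2, x + 2, y + 2], fill=color)
    elif kind == "line":
        draw.line(list(coords), fill=color, width=2)
    elif kind == "rect":
        draw.rectangle(list(coords[:4]), outline=color, width=2)
    elif kind == "ellipse":
        draw.ellipse(list(coords[:4]), outline=color, width=2)
    elif kind == "text":
        draw.text(tuple(coords[:2]), label, fill=color)
    if label and kind != "text":
        draw.text((coords[0] + 3, coords[1] + 3), label, fill=color)


def _apply_field(doc: MetadataDoc, field_path: str, value) -> None:
    parts = field_path.split(".")
    if parts[0] == "user" and len(parts) == 2:
        if parts[1] == "rating":
            doc.user = UserDescription(doc.user.free_text, int(value))
            return
        if parts[1] == "free_text":
            doc.user = UserDescription(str(value), doc.user.rating)
            return
    elif parts[0] == "protocols" and len(parts) == 3:
        _, pid, uid = parts
        for inst in doc.protocols:
            if inst.protocol_id == pid:
                inst.entry(uid).set_value(value)
                return
        raise MetadataError(f"no protocol instance {pid!r}")
    raise MetadataError(f"invalid field path {field_path!r}")


def batch_annotate(paths: Sequence[Path], field_path: str, value) -> int:
    """Set one field across many documents; each file rewritten atomically.

    The path is validated against every document before the first write,
    so an invalid path touches nothing.  Returns the number of documents
    rewritten (every targeted document is rewritten, changed or not).
    """
    docs = []
    for p in paths:
        doc = read_metadata(p)
        _apply_field(doc, field_path, value)  # validate + apply in memory
        docs.append((Path(p), doc))
    for p, doc in docs:
        tmp = p.with_suffix(p.suffix + ".tmp")
        write_metadata(tmp, doc)
        tmp.replace(p)
    return len(docs)
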