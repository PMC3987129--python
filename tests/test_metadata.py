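"""Metadata document round trips, protocols, attribute files and views."""

import numpy as np
import pytest
from lxml import etree
from PIL import Image

from bebkit.hcoords import HCoord, Timestamp128
from bebkit.metadata import (
    DatasetProperties,
    Dimension,
    ElementDescriptor,
    MetadataDoc,
    MetadataError,
    RawFileRecord,
    UserDescription,
    add_view,
    apply_protocol,
    batch_annotate,
    ingest_attribute_file,
    read_metadata,
    write_metadata,
)
from bebkit.vocab import EntryRef, ProtocolStore, VocabularyEntry


def full_doc():
    doc = MetadataDoc()
    doc.user = UserDescription("ok", 3)
    doc.database_id = "S-17"
    doc.coords = HCoord(x=1500, y=-2, z=0, rootflag=True, scale=1000.0,
                        dx=3, t=Timestamp128(12, 2**63), dt=0.5, description="dish")
    doc.properties = DatasetProperties(
        [Dimension("t", "numeric", "s", 0.0, 0.1, 100),
         Dimension("x", "index", "px", length=64)],
        ElementDescriptor("intensity", "counts", "numeric", "uint16"),
    )
    doc.embedded = [("width", "64"), ("height", "48")]
    doc.datatype_id = "image.grey"
    doc.raw_files = [RawFileRecord("a.png", 123, "d41d8cd98f00b204e9800998ecf8427e", True)]
    return doc


class TestRoundTrip:
    def test_values_survive(self, tmp_path):
        p = tmp_path / "m.xml"
        write_metadata(p, full_doc())
        back = read_metadata(p)
        assert back.user.rating == 3 and back.user.free_text == "ok"
        assert back.database_id == "S-17"
        assert back.coords == full_doc().coords
        assert back.properties.dimensions[0].spacing == 0.1
        assert back.properties.dimensions[1].spacing is None
        assert back.properties.element.precision == "uint16"
        assert back.embedded == [("width", "64"), ("height", "48")]
        assert back.raw_files[0].compressed is True
        assert back.datatype_id == "image.grey"

    def test_canonical_serialization_is_stable(self, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_metadata(p1, full_doc())
        write_metadata(p2, read_metadata(p1))
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_elements_preserved(self, tmp_path):
        p = tmp_path / "m.xml"
        write_metadata(p, MetadataDoc())
        root = etree.parse(str(p)).getroot()
        extra = etree.SubElement(root, "future-section")
        extra.set("version", "9")
        etree.SubElement(extra, "payload").text = "keep me"
        p.write_bytes(etree.tostring(root, pretty_print=True, encoding="utf-8"))
        doc = read_metadata(p)
        write_metadata(p, doc)
        reread = read_metadata(p)
        assert len(reread.unknown) == 1
        a, b = (etree.tostring(e) for e in (doc.unknown[0], reread.unknown[0]))
        assert a == b and b"keep me" in a

    def test_truncated_file_is_an_error(self, tmp_path):
        p = tmp_path / "m.xml"
        write_metadata(p, full_doc())
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(MetadataError, match="line"):
            read_metadata(p)

    def test_rating_range_enforced(self):
        with pytest.raises(MetadataError):
            UserDescription("x", 6)


@pytest.fixture
def store():
    s = ProtocolStore()
    s.library.add(VocabularyEntry("u1", "Organism", default="yeast"))
    s.library.add(VocabularyEntry("u2", "Medium", default="YPD"))
    s.library.add(VocabularyEntry("u3", "Temp", "enum", default="30C", allowed=["4C", "30C", "37C"]))
    s.library.add(VocabularyEntry("u4", "Operator", default=""))
    s.assemble_protocol("culture", ["u1", "u2", "u3", "u4"])
    return s


class TestProtocols:
    def test_defaults_filled(self, store):
        doc = MetadataDoc()
        inst = apply_protocol(doc, store.templates["culture"])
        assert [e.uid for e in inst.entries] == ["u1", "u2", "u3", "u4"]
        assert inst.entry("u1").value == "yeast"
        assert inst.entry("u3").value == "30C"

    def test_reapplication_appends(self, store):
        doc = MetadataDoc()
        first = apply_protocol(doc, store.templates["culture"])
        first.entry("u1").set_value("mouse")
        apply_protocol(doc, store.templates["culture"])
        assert len(doc.protocols) == 2
        assert doc.protocols[0].entry("u1").value == "mouse"
        assert doc.protocols[1].entry("u1").value == "yeast"

    def test_off_list_value_rejected(self, store):
        doc = MetadataDoc()
        inst = apply_protocol(doc, store.templates["culture"])
        with pytest.raises(MetadataError):
            inst.entry("u3").set_value("99C")


class TestAttributeFiles:
    def test_keys_ingested(self, tmp_path):
        attr = tmp_path / "x.attr"
        attr.write_text("a=1\nb = 2\n# comment\nc=3\n", encoding="utf-8")
        doc = MetadataDoc()
        assert ingest_attribute_file(doc, attr) == 3
        assert doc.embedded == [("a", "1"), ("b", "2"), ("c", "3")]

    def test_last_value_wins_and_lines_counted(self, tmp_path):
        attr = tmp_path / "x.attr"
        attr.write_text("k=1\nk=2\nk=3\n", encoding="utf-8")
        doc = MetadataDoc()
        # oracle: sequential replay — 3 lines ingested, final value 3
        assert ingest_attribute_file(doc, attr) == 3
        assert doc.embedded == [("k", "3")]

    def test_empty_and_bad_lines(self, tmp_path):
        attr = tmp_path / "x.attr"
        attr.write_text("", encoding="utf-8")
        assert ingest_attribute_file(MetadataDoc(), attr) == 0
        attr.write_text("no equals sign\nok=1\n", encoding="utf-8")
        doc = MetadataDoc()
        assert ingest_attribute_file(doc, attr) == 1


class TestViews:
    def test_view_stored(self, tmp_path):
        doc = MetadataDoc()
        img = Image.fromarray(np.zeros((40, 60), dtype=np.uint8))
        rec = add_view(tmp_path, doc, "powerspec", img, [])
        assert (tmp_path / rec.image_path).exists()
        assert len(doc.views) == 1

    def test_burned_in_shape_changes_pixels(self, tmp_path):
        doc = MetadataDoc()
        img = Image.fromarray(np.zeros((40, 60), dtype=np.uint8))
        add_view(tmp_path, doc, "v", img, [("rect", (10, 10, 30, 25), "cell")])
        plain = np.array(Image.open(tmp_path / "v.png").convert("RGB"))
        annotated = np.array(Image.open(tmp_path / "v_annotated.png").convert("RGB"))
        region = slice(10, 26), slice(10, 31)
        assert (plain[region] != annotated[region]).any()

    def test_duplicate_name_rejected(self, tmp_path):
        doc = MetadataDoc()
        img = Image.fromarray(np.zeros((8, 8), dtype=np.uint8))
        add_view(tmp_path, doc, "v", img)
        with pytest.raises(MetadataError):
            add_view(tmp_path, doc, "v", img)


class TestBatchAnnotate:
    def make_files(self, tmp_path, n):
        paths = []
        for i in range(n):
            p = tmp_path / f"d{i}.xml"
            write_metadata(p, MetadataDoc())
            paths.append(p)
        return paths

    def test_all_documents_rewritten(self, tmp_path):
        paths = self.make_files(tmp_path, 10)
        assert batch_annotate(paths, "user.rating", 4) == 10
        assert all(read_metadata(p).user.rating == 4 for p in paths)

    def test_unchanged_values_still_count_as_written(self, tmp_path):
        paths = self.make_files(tmp_path, 10)
        batch_annotate(paths[:3], "user.rating", 4)
        mtimes = [p.stat().st_mtime_ns for p in paths]
        assert batch_annotate(paths, "user.rating", 4) == 10
        # every document rewritten, even the 3 already at the value
        assert all(p.stat().st_mtime_ns >= m for p, m in zip(paths, mtimes))

    def test_bad_path_writes_nothing(self, tmp_path):
        paths = self.make_files(tmp_path, 4)
        before = [p.read_bytes() for p in paths]
        with pytest.raises(MetadataError):
            batch_annotate(paths, "nonsense.field", 1)
        assert [p.read_bytes() for p in paths] == before
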