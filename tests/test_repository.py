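"""Bundle/collection layout, raw-data integrity, compression, locking."""

import zipfile

import pytest
from hypothesis import given, settings, strategies as st

from bebkit.metadata import read_metadata
from bebkit.repository import (
    SUBFOLDERS,
    Collection,
    LockError,
    RepositoryError,
    create_bundle,
    create_collection,
    import_dataset,
    lock_collection,
    md5_file,
    rebuild_cache,
    release_lock,
    verify_integrity,
)
from bebkit.vocab import ProtocolStore, VocabularyEntry

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")

MD5_EMPTY = "d41d8cd98f00b204e9800998ecf8427e"


def write_source(tmp_path, name, data: bytes):
    p = tmp_path / name
    p.write_bytes(data)
    return p


class TestCreate:
    def test_bundle_has_four_subfolders(self, tmp_path):
        b = create_bundle(tmp_path, "exp1")
        assert b.fs_path.name == "exp1.bundle"
        assert sorted(p.name for p in b.fs_path.iterdir() if p.is_dir()) == sorted(SUBFOLDERS)

    def test_no_silent_overwrite(self, tmp_path):
        b = create_bundle(tmp_path, "exp1")
        marker = b.root.annotations_dir / "collection.xml"
        before = marker.read_bytes()
        with pytest.raises(RepositoryError):
            create_bundle(tmp_path, "exp1")
        assert marker.read_bytes() == before

    def test_path_separators_rejected(self, tmp_path):
        with pytest.raises(RepositoryError):
            create_bundle(tmp_path, "a/b")
        with pytest.raises(RepositoryError):
            create_bundle(tmp_path, "")

    def test_collection_with_protocol_defaults(self, tmp_path, bundle):
        store = ProtocolStore()
        store.library.add(VocabularyEntry("org", "Organism", default="HEK293"))
        store.assemble_protocol("lm-timelapse", ["org"])
        coll = create_collection(bundle.root, "CellCulture", "lm-timelapse", protocols=store)
        assert coll.path == bundle.fs_path / "Collections" / "CellCulture"
        doc = coll.read_metadata()
        assert doc.protocols[0].entry("org").value == "HEK293"

    def test_unknown_protocol_named_in_error(self, bundle):
        with pytest.raises(RepositoryError, match="nope"):
            create_collection(bundle.root, "C", "nope", protocols=ProtocolStore())

    def test_duplicate_sibling_rejected(self, bundle):
        create_collection(bundle.root, "C")
        with pytest.raises(RepositoryError):
            create_collection(bundle.root, "C")

    def test_nesting_depth_five(self, bundle):
        node = bundle.root
        for i in range(5):
            node = create_collection(node, f"L{i}")
        rel = node.path.relative_to(bundle.fs_path)
        assert list(rel.parts).count("Collections") == 5

    @given(st.lists(st.sampled_from("abcde"), min_size=0, max_size=49))
    def test_every_collection_has_exactly_four_subfolders(self, tmp_path_factory, names):
        """Random trees of <=50 collections; oracle is a directory walk."""
        tmp = tmp_path_factory.mktemp("tree")
        b = create_bundle(tmp, "t")
        nodes = [b.root]
        for i, base in enumerate(names):
            parent = nodes[i % len(nodes)]
            nodes.append(create_collection(parent, f"{base}{i}"))
        for coll in b.walk():
            subdirs = sorted(p.name for p in coll.path.iterdir() if p.is_dir())
            assert subdirs == sorted(SUBFOLDERS)


class TestImport:
    def test_empty_file_reference_md5(self, tmp_path, bundle):
        src = write_source(tmp_path, "empty.dat", b"")
        rec = import_dataset(bundle.root, [src])
        assert rec.raw_files[0].md5_hex == MD5_EMPTY
        assert src.exists()  # source untouched

    def test_compression_round_trip_preserves_md5(self, tmp_path, bundle, rng):
        data = rng.integers(0, 256, 5000, dtype="uint8").tobytes()
        src = write_source(tmp_path, "blob.bin", data)
        rec = import_dataset(bundle.root, [src], compress=True)
        stored = rec.stored_path(rec.raw_files[0])
        assert stored.suffix == ".zip" and zipfile.is_zipfile(stored)
        assert rec.read_raw(rec.raw_files[0]) == data
        assert rec.raw_files[0].md5_hex == md5_file(src)

    def test_sidecar_attribute_file_ingested(self, tmp_path, bundle):
        src = write_source(tmp_path, "img.dat", b"xyz")
        write_source(tmp_path, "img.dat.attr", b"stage_x=12\nstage_y=-3\n")
        rec = import_dataset(bundle.root, [src])
        assert rec.doc.embedded_get("stage_x") == "12"
        assert rec.doc.embedded_get("stage_y") == "-3"

    def test_unreadable_source_leaves_no_partial_dataset(self, tmp_path, bundle):
        ok = write_source(tmp_path, "a.dat", b"a")
        with pytest.raises(RepositoryError):
            import_dataset(bundle.root, [ok, tmp_path / "missing.dat"])
        assert bundle.root.dataset_ids() == []

    def test_unregistered_datatype_rejected(self, tmp_path, bundle):
        src = write_source(tmp_path, "a.dat", b"a")
        with pytest.raises(RepositoryError):
            import_dataset(bundle.root, [src], datatype_id="no-such-type")


class TestIntegrity:
    def test_fresh_bundle_passes(self, tmp_path, bundle):
        for i in range(3):
            import_dataset(bundle.root, [write_source(tmp_path, f"f{i}.dat", bytes([i] * 10))])
        rep = verify_integrity(bundle)
        assert rep.checked == 3 and rep.passed == 3 and rep.failures == []

    def test_single_byte_corruption_detected(self, tmp_path, bundle):
        src = write_source(tmp_path, "f.dat", b"hello world")
        rec = import_dataset(bundle.root, [src])
        stored = rec.stored_path(rec.raw_files[0])
        data = bytearray(stored.read_bytes())
        data[3] ^= 0x01
        stored.write_bytes(bytes(data))
        rep = verify_integrity(bundle)
        assert len(rep.failures) == 1
        assert rep.failures[0][0] == str(stored)
        assert rep.checked == rep.passed + len(rep.failures)

    def test_missing_file_reported_not_raised(self, tmp_path, bundle):
        src = write_source(tmp_path, "f.dat", b"hello")
        rec = import_dataset(bundle.root, [src])
        rec.stored_path(rec.raw_files[0]).unlink()
        rep = verify_integrity(bundle)
        assert rep.failures == [(str(rec.stored_path(rec.raw_files[0])), rec.raw_files[0].md5_hex, "missing")]


class TestLocking:
    def test_other_owner_refused(self, tmp_path, bundle):
        lock_collection(bundle.root, "macro-7")
        src = write_source(tmp_path, "f.dat", b"x")
        with pytest.raises(LockError, match="macro-7"):
            import_dataset(bundle.root, [src], owner="gui")

    def test_release_then_import_succeeds(self, tmp_path, bundle):
        lock_collection(bundle.root, "macro-7")
        release_lock(bundle.root, "macro-7")
        src = write_source(tmp_path, "f.dat", b"x")
        import_dataset(bundle.root, [src], owner="gui")

    def test_owner_can_still_mutate(self, tmp_path, bundle):
        lock_collection(bundle.root, "macro-7")
        src = write_source(tmp_path, "f.dat", b"x")
        import_dataset(bundle.root, [src], owner="macro-7")

    def test_relock_same_owner_idempotent(self, bundle):
        lock_collection(bundle.root, "a")
        lock_collection(bundle.root, "a")
        assert bundle.root.lock_owner() == "a"

    def test_steal_refused(self, bundle):
        lock_collection(bundle.root, "a")
        with pytest.raises(LockError, match="'a'"):
            lock_collection(bundle.root, "b")
        with pytest.raises(LockError):
            release_lock(bundle.root, "b")


class TestCache:
    def test_rebuild_is_deterministic(self, demo_result):
        coll = demo_result.cellculture
        rebuild_cache(coll)
        listing1 = {p.name: md5_file(p) for p in coll.cache_dir.iterdir()}
        rebuild_cache(coll)
        listing2 = {p.name: md5_file(p) for p in coll.cache_dir.iterdir()}
        assert listing1 == listing2 and listing1

    def test_raw_data_untouched_by_rebuild(self, demo_result):
        before = verify_integrity(demo_result.bundle)
        for coll in demo_result.bundle.walk():
            rebuild_cache(coll)
        after = verify_integrity(demo_result.bundle)
        assert before.failures == after.failures == []
        assert before.checked == after.checked

    def test_empty_collection_rebuild_is_zero(self, bundle):
        assert rebuild_cache(bundle.root) == 0


@given(blob=st.binary(min_size=0, max_size=200_000))
def test_zip_round_trip_is_identity(tmp_path_factory, blob):
    """Compression then transparent read returns the original bytes."""
    tmp = tmp_path_factory.mktemp("zip")
    b = create_bundle(tmp, "z")
    src = tmp / "blob.bin"
    src.write_bytes(blob)
    rec = import_dataset(b.root, [src], compress=True)
    assert rec.read_raw(rec.raw_files[0]) == blob
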