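"""Vocabulary propagation, template assembly, support-folder sync."""

import pytest
from hypothesis import given, settings, strategies as st

from bebkit.vocab import (
    EntryRef,
    ProtocolStore,
    UpdateReport,
    VocabError,
    VocabularyEntry,
    read_manifest,
    sync_support_folder,
    write_manifest,
)

settings.register_profile("ci", derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def store():
    s = ProtocolStore()
    for i in range(6):
        s.library.add(VocabularyEntry(f"u{i}", f"Title {i}", default=f"d{i}"))
    s.assemble_protocol("p0", ["u0", "u1"])
    s.assemble_protocol("p1", ["u1", "u2"])
    s.assemble_protocol("p2", ["u1"], dataset_refs=["u3"])
    s.assemble_protocol("p3", [EntryRef("u1", title_override="Local")], ["u4"])
    s.assemble_protocol("p4", ["u5"])
    return s


class TestPropagation:
    def test_update_reaches_referencing_templates(self, store):
        # u1 referenced plainly by p0, p1, p2; p3 overrides it
        affected = store.update_vocab_entry("u1", new_title="Renamed")
        assert affected == ["p0", "p1", "p2"]
        ref = store.templates["p0"].collection_part[1]
        assert store.templates["p0"].resolve(ref).title == "Renamed"

    def test_override_shields_template(self, store):
        store.update_vocab_entry("u1", new_title="Renamed")
        ref = store.templates["p3"].collection_part[0]
        assert store.templates["p3"].resolve(ref).title == "Local"

    def test_unknown_uid_rejected(self, store):
        with pytest.raises(VocabError):
            store.update_vocab_entry("zz", new_title="x")

    def test_duplicate_uid_in_library_rejected(self, store):
        with pytest.raises(VocabError):
            store.library.add(VocabularyEntry("u0", "again"))

    @given(st.data())
    def test_incremental_equals_recompute_from_scratch(self, data):
        """Random edit sequences; oracle rebuilds effective values fresh."""
        store = ProtocolStore()
        for i in range(6):
            store.library.add(VocabularyEntry(f"u{i}", f"Title {i}", default=f"d{i}"))
        store.assemble_protocol("p0", ["u0", "u1"])
        store.assemble_protocol("p1", ["u1", "u2"])
        store.assemble_protocol("p3", [EntryRef("u1", title_override="Local")], ["u4"])
        edits = data.draw(
            st.lists(
                st.tuples(st.sampled_from([f"u{i}" for i in range(6)]),
                          st.text("abcdef", min_size=1, max_size=5)),
                max_size=10,
            )
        )
        expected_titles = {f"u{i}": f"Title {i}" for i in range(6)}
        for uid, title in edits:
            store.update_vocab_entry(uid, new_title=title)
            expected_titles[uid] = title
        for tmpl in store.templates.values():
            for ref in tmpl.collection_part + tmpl.dataset_part:
                effective = tmpl.resolve(ref).title
                oracle = ref.title_override if ref.title_override is not None else expected_titles[ref.uid]
                assert effective == oracle


class TestAssembly:
    def test_order_preserved(self, store):
        t = store.assemble_protocol("q", ["u3", "u0", "u2", "u1"])
        assert [r.uid for r in t.collection_part] == ["u3", "u0", "u2", "u1"]

    def test_duplicate_uid_kept_twice(self, store):
        t = store.assemble_protocol("q", ["u0", "u0"])
        assert [r.uid for r in t.collection_part] == ["u0", "u0"]

    def test_missing_uids_listed(self, store):
        with pytest.raises(VocabError, match="zz"):
            store.assemble_protocol("q", ["u0", "zz"])

    def test_persistence_round_trip(self, store, tmp_path):
        store.update_vocab_entry("u1", new_title="Edited")
        store.save(tmp_path)
        back = ProtocolStore.load(tmp_path)
        assert set(back.templates) == set(store.templates)
        assert back.library.get("u1").title == "Edited"
        ref = back.templates["p3"].collection_part[0]
        assert back.templates["p3"].resolve(ref).title == "Local"


def make_repo(tmp_path, version="1.0.0", core_min="0.0.1", core_max="1.0.0"):
    repo = tmp_path / "repo"
    (repo / "protocols").mkdir(parents=True)
    (repo / "macros").mkdir()
    (repo / "protocols" / "vocabulary.xml").write_text("<beb-vocabulary/>", encoding="utf-8")
    (repo / "macros" / "clean.macro").write_text("LOG cleaning\n", encoding="utf-8")
    write_manifest(repo, version, core_min, core_max)
    return repo


class TestSupportSync:
    def test_fresh_sync_adds_everything(self, tmp_path):
        repo = make_repo(tmp_path)
        local = tmp_path / "support"
        rep = sync_support_folder(local, repo)
        assert rep.added == 2 and rep.replaced == 0 and rep.removed == 0
        assert (local / "macros" / "clean.macro").exists()

    def test_rerun_is_a_no_op(self, tmp_path):
        repo = make_repo(tmp_path)
        local = tmp_path / "support"
        sync_support_folder(local, repo)
        assert sync_support_folder(local, repo) == UpdateReport(0, 0, 0)

    def test_changed_and_stale_files_handled(self, tmp_path):
        repo = make_repo(tmp_path)
        local = tmp_path / "support"
        sync_support_folder(local, repo)
        (local / "macros" / "clean.macro").write_text("LOG tampered\n", encoding="utf-8")
        (local / "macros" / "stale.macro").write_text("LOG old\n", encoding="utf-8")
        rep = sync_support_folder(local, repo)
        assert (rep.added, rep.replaced, rep.removed) == (0, 1, 1)
        assert (local / "macros" / "clean.macro").read_text() == "LOG cleaning\n"
        assert not (local / "macros" / "stale.macro").exists()

    def test_incompatible_core_changes_nothing(self, tmp_path):
        repo = make_repo(tmp_path, core_min="9.0.0", core_max="9.9.9")
        local = tmp_path / "support"
        rep = sync_support_folder(local, repo)
        assert rep.incompatible and not local.exists()

    def test_unreachable_repo_leaves_local_untouched(self, tmp_path):
        local = tmp_path / "support"
        local.mkdir()
        (local / "keep.txt").write_text("x", encoding="utf-8")
        with pytest.raises(FileNotFoundError):
            sync_support_folder(local, tmp_path / "nowhere")
        assert (local / "keep.txt").read_text() == "x"

    def test_manifest_round_trip(self, tmp_path):
        repo = make_repo(tmp_path, version="2.3.4")
        m = read_manifest(repo)
        assert m.version == "2.3.4" and len(m.files) == 2
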