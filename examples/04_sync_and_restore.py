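"""Generate the demo correlative bundle, sync it to a store, restore it.

Run:  python examples/04_sync_and_restore.py
"""

import shutil
import tempfile
from pathlib import Path

from bebkit.demo import DemoParams, generate_demo_bundle
from bebkit.dbsync import DirectoryStore, download, sync_bundle
from bebkit.repository import verify_integrity

with tempfile.TemporaryDirectory() as td:
    work = Path(td)
    result = generate_demo_bundle(DemoParams(seed=42, n_frames=3), work)
    print("demo bundle:", [c.path.name for c in result.bundle.walk()])

    store = DirectoryStore(work / "server")
    report = sync_bundle(result.bundle, store)
    print(f"synced: {report.uploaded} files uploaded, "
          f"{report.excluded_cache_files} cache files excluded")
    print("re-sync uploads:", sync_bundle(result.bundle, store).uploaded)

    # offload: delete the local collection, then pull it back from the server
    sid = result.cellculture.read_metadata().database_id
    shutil.rmtree(result.cellculture.path)
    restored = download(sid, store, result.bundle)
    post = verify_integrity(restored)
    print(f"restored {restored.path.name}: {post.passed}/{post.checked} files verify")

# Cache contents are derived data and are never synchronized; after download
# they are regenerated locally from the raw data.
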