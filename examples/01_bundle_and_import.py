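"""Create a bundle, import raw data with checksums, verify integrity.

Run:  python examples/01_bundle_and_import.py
"""

import tempfile
from pathlib import Path

from bebkit import create_bundle, import_dataset, verify_integrity

with tempfile.TemporaryDirectory() as td:
    work = Path(td)
    bundle = create_bundle(work, "experiment1")
    print("bundle at:", bundle.fs_path.name)
    print("subfolders:", sorted(p.name for p in bundle.fs_path.iterdir() if p.is_dir()))

    # any instrument file can be imported; here a plain binary blob
    src = work / "reading.dat"
    src.write_bytes(b"\x00\x01\x02" * 1000)
    record = import_dataset(bundle.root, [src], compress=True)
    f = record.raw_files[0]
    print(f"imported {f.filename}: {f.byte_size} bytes, md5 {f.md5_hex}, zip={f.compressed}")

    report = verify_integrity(bundle)
    print(f"integrity: {report.passed}/{report.checked} files pass")

# The MD5 is computed over the *uncompressed* content at import time, so a
# later verify detects any corruption of the stored copy, compressed or not.
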