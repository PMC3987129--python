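"""Synthetic correlative-experiment generator.

Builds, at desk scale, the canonical correlative workflow: a cell-culture
dish observed by time-lapse light microscopy (LM) defines the root
coordinate frame; one cell is selected and lysed, opening a sub-frame at
the cell's position; its lysate is imaged by electron microscopy (EM) in
a sub-sub-frame.  A fluorescence-intensity trace of the selected cell is
stored as an equally spaced wave.  All content is simulated — LM frames
are Gaussian-blob "cells" over Poisson-like background noise, EM images
are fields of small dark particles on a bright background — and every
source of randomness and time runs off the seed and a mocked clock, so a
given seed always produces a byte-identical bundle.

Geometry: LM pixels are 100 nm (1e5 pm); EM pixels are 1 nm (1000 pm).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .hcoords import HCoord, Timestamp128, add_duration, make_timestamp
from .metadata import read_metadata, write_metadata
from .repository import (
    Bundle,
    Collection,
    DatasetRecord,
    create_bundle,
    create_collection,
    import_dataset,
    md5_file,
)
from .vocab import EntryRef, ProtocolStore, VocabularyEntry

__all__ = ["DemoParams", "DemoResult", "default_protocols", "generate_demo_bundle"]

#: pm per LM pixel (100 nm) and per EM pixel (1 nm).
LM_PIXEL_PM = 100_000
EM_PIXEL_PM = 1_000


@dataclass(frozen=True)
class DemoParams:
    seed: int = 42
    n_frames: int = 5
    frame_interval: float = 60.0  # seconds between LM frames
    image_size: int = 64  # LM/EM frames are square, this many pixels
    n_cells: int = 3
    cell_drift_pm: int = 50_000  # per-frame drift of each cell
    n_em_images: int = 2

    def __post_init__(self) -> None:
        for name in ("n_frames", "image_size", "n_cells", "n_em_images"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class DemoResult:
    bundle: Bundle
    cellculture: Collection
    lysis: Collection
    em: Collection
    #: expected absolute (x, y, z) pm of each EM image, for bookkeeping checks
    em_expected_abs: list[tuple[int, int, int]] = field(default_factory=list)
    t0: Timestamp128 = Timestamp128(0, 0)

    def md5_manifest(self) -> dict[str, str]:
        """Relative path -> MD5 for every file in the bundle."""
        root = self.bundle.fs_path
        return {
            p.relative_to(root).as_posix(): md5_file(p)
            for p in sorted(root.rglob("*"))
            if p.is_file()
        }


def default_protocols() -> ProtocolStore:
    """A small controlled vocabulary and the three workflow protocols."""
    store = ProtocolStore()
    lib = store.library
    lib.add(VocabularyEntry("organism", "Organism", "text", default="HEK293"))
    lib.add(VocabularyEntry("medium", "Culture medium", "text", default="DMEM"))
    lib.add(
        VocabularyEntry(
            "temp", "Incubation temperature", "enum", default="37C",
            allowed=["4C", "25C", "37C"],
        )
    )
    lib.add(VocabularyEntry("operator", "Operator", "text", default=""))
    lib.add(VocabularyEntry("stain", "Stain", "text", default="methylamine tungstate"))
    lib.add(VocabularyEntry("exposure", "Exposure time", "number", default="0.1"))
    store.assemble_protocol(
        "lm-timelapse",
        collection_refs=["organism", "medium", "temp", "operator"],
        dataset_refs=["exposure"],
        init=[("workflow-step", "cell-culture")],
    )
    store.assemble_protocol(
        "single-cell-lysis",
        collection_refs=["operator"],
        dataset_refs=[],
        init=[("workflow-step", "lysis")],
    )
    store.assemble_protocol(
        "em-imaging",
        collection_refs=["stain", "operator"],
        dataset_refs=[EntryRef("exposure", default_override="1.0")],
        init=[("workflow-step", "em")],
    )
    return store


def _lm_frame(rng: np.random.Generator, size: int, cells_px: np.ndarray) -> np.ndarray:
    """One LM frame: Gaussian spots (sigma 2-4 px) over noisy background."""
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), 20.0)
    for cx, cy, sigma, amp in cells_px:
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    img += rng.poisson(lam=4.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _em_image(rng: np.random.Generator, size: int) -> np.ndarray:
    """Synthetic EM micrograph: small dark particle disks, bright field."""
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), 200.0)
    for _ in range(12):
        cx, cy = rng.uniform(0, size, 2)
        r = rng.uniform(1.5, 3.5)
        img -= 120.0 * ((xx - cx) ** 2 + (yy - cy) ** 2 < r**2)
    img += rng.normal(0, 3, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _freeze_mtime(path: Path) -> None:
    # fixed mtime so ZIP archives built from this file are reproducible
    os.utime(path, (946684800, 946684800))


def generate_demo_bundle(params: DemoParams, out_dir: Path, name: str = "demo") -> DemoResult:
    """Generate the full correlative demo bundle under ``out_dir``."""
    rng = np.random.default_rng(params.seed)
    protocols = default_protocols()
    bundle = create_bundle(out_dir, name)
    t0 = make_timestamp(2014, 3, 26, 9, 0, 0)

    # --- cell culture: LM time lapse, the coordinate root ------------------
    cellculture = create_collection(
        bundle.root, "CellCulture", "lm-timelapse", protocols=protocols
    )
    doc = cellculture.read_metadata()
    doc.coords = HCoord(
        rootflag=True, scale=1_000_000.0, t=t0,
        description="cell culture dish, LM stage frame (display in um)",
    )
    cellculture.write_metadata(doc)

    # cells drift linearly; positions in LM pixels
    cells0 = rng.uniform(params.image_size * 0.2, params.image_size * 0.8, (params.n_cells, 2))
    sigmas = rng.uniform(2.0, 4.0, params.n_cells)
    amps = rng.uniform(80, 160, params.n_cells)
    drift_px = params.cell_drift_pm / LM_PIXEL_PM

    with tempfile.TemporaryDirectory() as td:
        frame_paths = []
        for k in range(params.n_frames):
            pos = cells0 + k * drift_px
            cells_px = np.column_stack([pos[:, 0], pos[:, 1], sigmas, amps])
            frame = _lm_frame(rng, params.image_size, cells_px)
            p = Path(td) / f"lm_frame_{k:03d}.png"
            Image.fromarray(frame, mode="L").save(p)
            _freeze_mtime(p)
            frame_paths.append(p)
        lm_ds = import_dataset(cellculture, frame_paths, datatype_id="image.grey")
    lm_doc = lm_ds.doc
    lm_doc.coords = HCoord(t=t0, description="LM time-lapse stack")
    for k in range(params.n_frames):
        ts = add_duration(t0, k * params.frame_interval)
        lm_doc.embedded_set(f"frame.{k}.seconds", str(ts.seconds))
        lm_doc.embedded_set(f"frame.{k}.fraction", str(ts.fraction))
    lm_ds.save()

    # --- fluorescence trace of the selected cell ----------------------------
    selected = int(rng.integers(params.n_cells))
    trace = 100.0 + 10.0 * np.sin(np.arange(params.n_frames) / 3.0) + rng.normal(0, 1, params.n_frames)
    with tempfile.TemporaryDirectory() as td:
        wave_path = Path(td) / "fluorescence_trace.csv"
        lines = ["# name = fluorescence", "# unit = s", "# start = 0",
                 f"# spacing = {params.frame_interval}", "# element-unit = a.u."]
        lines += [f"{v:.6f}" for v in trace]
        wave_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        _freeze_mtime(wave_path)
        wave_ds = import_dataset(
            cellculture, [wave_path], datatype_id="wave.equally-spaced", compress=True
        )
    wave_doc = wave_ds.doc
    wave_doc.coords = HCoord(t=t0, description=f"fluorescence trace of cell {selected}")
    wave_ds.save()

    # --- single cell lysis: sub-frame at the selected cell ------------------
    lysis_time = add_duration(t0, params.n_frames * params.frame_interval)
    cell_px = cells0[selected] + (params.n_frames - 1) * drift_px
    cell_pm = (int(round(cell_px[0] * LM_PIXEL_PM)), int(round(cell_px[1] * LM_PIXEL_PM)))
    lysis = create_collection(
        cellculture, "SingleCellLysis", "single-cell-lysis", protocols=protocols
    )
    doc = lysis.read_metadata()
    doc.coords = HCoord(
        x=cell_pm[0], y=cell_pm[1], z=0,
        dx=LM_PIXEL_PM, dy=LM_PIXEL_PM,  # localized to one LM pixel
        t=lysis_time, dt=1.0,
        description=f"lysed cell {selected}, position relative to dish frame",
    )
    lysis.write_metadata(doc)

    # --- EM of the lysate: sub-sub-frame ------------------------------------
    em = create_collection(lysis, "EM", "em-imaging", protocols=protocols)
    em_grid_offset = (2_000_000, -1_500_000, 0)  # EM grid relative to lysis point
    doc = em.read_metadata()
    doc.coords = HCoord(
        x=em_grid_offset[0], y=em_grid_offset[1], z=em_grid_offset[2],
        dx=10_000, dy=10_000,
        t=add_duration(lysis_time, 1800), dt=5.0,
        description="EM grid frame, relative to lysis point",
    )
    em.write_metadata(doc)

    result = DemoResult(bundle, cellculture, lysis, em, t0=t0)
    for i in range(params.n_em_images):
        with tempfile.TemporaryDirectory() as td:
            p = Path(td) / f"em_{i:03d}.tif"
            Image.fromarray(_em_image(rng, params.image_size), mode="L").save(p, format="TIFF")
            _freeze_mtime(p)
            ds = import_dataset(em, [p], datatype_id="image.grey")
        offset = (
            int(rng.integers(-500, 500)) * EM_PIXEL_PM,
            int(rng.integers(-500, 500)) * EM_PIXEL_PM,
            0,
        )
        ds_doc = ds.doc
        ds_doc.coords = HCoord(
            x=offset[0], y=offset[1], z=offset[2],
            dx=EM_PIXEL_PM, dy=EM_PIXEL_PM,
            t=add_duration(lysis_time, 1800 + 60 * i), dt=5.0,
            description=f"EM image {i}",
        )
        ds.save()
        result.em_expected_abs.append(
            (
                cell_pm[0] + em_grid_offset[0] + offset[0],
                cell_pm[1] + em_grid_offset[1] + offset[1],
                0,
            )
        )
    return result
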