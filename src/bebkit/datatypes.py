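"""Built-in data types: greyscale raster images and equally spaced waves.

These are the two reference "viewportType" implementations: they define
how a data type is imported (pixels/samples plus embedded header keys and
dataset properties), how its thumbnail and preview PNGs are produced, and
which derived views exist (real-space look-up-table rendering and the 2-D
power spectrum used to judge the contrast-transfer function of an imaging
device).

Pixel convention: row-major ``(y, x)``, origin top-left.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .metadata import DatasetProperties, Dimension, ElementDescriptor

__all__ = [
    "GreyImage",
    "WaveSeries",
    "import_image",
    "make_thumbnail",
    "make_preview",
    "power_spectrum_view",
    "apply_lut",
    "LUT_NAMES",
    "import_wave",
    "wave_preview",
]

_DTYPE_TO_PRECISION = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32",
    np.dtype(np.float32): "float32",
    np.dtype(np.float64): "float64",
}


@dataclass
class GreyImage:
    """A 2-D greyscale raster with optional pixel size and header keys."""

    pixels: np.ndarray
    pixel_size: Optional[tuple[float, str]] = None  # (value, unit)
    header: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("greyscale image must be 2-D with positive extent")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (ny, nx)


@dataclass
class WaveSeries:
    """An equally spaced 1-D signal, e.g. a fluorescence-intensity trace."""

    values: np.ndarray
    dimension: Dimension
    element: ElementDescriptor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("wave values must be 1-D")
        if self.dimension.length != len(self.values):
            raise ValueError("dimension length must equal the number of samples")


# --- image import ----------------------------------------------------------

def import_image(path: Path) -> tuple[GreyImage, DatasetProperties]:
    """Load a TIFF/PNG greyscale image with its embedded header keys.

    Color inputs are converted to luminance.  The returned properties
    carry two index dimensions (y, x — row-major) and an element whose
    precision reflects the stored bit depth.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            header = [("format", im.format or ""), ("mode", im.mode)]
            if im.mode in ("I;16", "I;16B", "I;16L"):
                arr = np.array(im, dtype=np.uint16)
            elif im.mode == "F":
                arr = np.array(im, dtype=np.float32)
            elif im.mode == "I":
                arr = np.array(im, dtype=np.int32)
            elif im.mode == "L":
                arr = np.array(im, dtype=np.uint8)
            else:
                arr = np.array(im.convert("L"), dtype=np.uint8)
            header.append(("width", str(arr.shape[1])))
            header.append(("height", str(arr.shape[0])))
            header.append(("bit-depth", str(arr.dtype.itemsize * 8)))
            if im.format == "TIFF":
                for tag_id, value in sorted(im.tag_v2.items()):
                    header.append((f"tiff.{tag_id}", str(value)))
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot decode image {path}: {exc}") from exc
    precision = _DTYPE_TO_PRECISION.get(arr.dtype, "float64")
    props = DatasetProperties(
        dimensions=[
            Dimension("y", kind="index", unit="px", length=arr.shape[0]),
            Dimension("x", kind="index", unit="px", length=arr.shape[1]),
        ],
        element=ElementDescriptor("intensity", unit="counts", kind="numeric", precision=precision),
    )
    return GreyImage(arr, header=header), props


# --- thumbnails / previews -------------------------------------------------

def _normalize_to_u8(pixels: np.ndarray) -> np.ndarray:
    """Linear min->0, max->255 stretch; constant images map to mid-grey."""
    arr = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.full(arr.shape, 128, dtype=np.uint8)
    return np.clip(np.round((arr - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)


def _scaled_png(img: GreyImage, max_side: int) -> bytes:
    u8 = _normalize_to_u8(img.pixels)
    pil = Image.fromarray(u8, mode="L")
    ny, nx = u8.shape
    longest = max(nx, ny)
    if longest > max_side:
        factor = max_side / longest
        pil = pil.resize(
            (max(1, round(nx * factor)), max(1, round(ny * factor))),
            resample=Image.Resampling.BILINEAR,
        )
    buf = io.BytesIO()
    pil.save(buf, format="PNG")
    return buf.getvalue()


def make_thumbnail(img: GreyImage, max_side: int = 128) -> bytes:
    """Aspect-preserving thumbnail PNG, longest side <= 128 px by default."""
    return _scaled_png(img, max_side)


def make_preview(img: GreyImage, max_side: int = 512) -> bytes:
    """Aspect-preserving preview PNG, longest side <= 512 px by default."""
    return _scaled_png(img, max_side)


# --- views -----------------------------------------------------------------

def power_spectrum_view(img: GreyImage) -> GreyImage:
    """Centered log-magnitude power spectrum, normalized to [0, 1].

    v = log(1 + |F|) with the zero frequency shifted to the image center;
    the magnitude spectrum is translation-invariant, so shifted copies of
    an image give the same view.
    """
    F = np.fft.fftshift(np.fft.fft2(np.asarray(img.pixels, dtype=np.float64)))
    mag = np.log1p(np.abs(F))
    hi = mag.max()
    out = mag / hi if hi > 0 else mag
    return GreyImage(out.astype(np.float64), header=[("view", "power-spectrum")])


def _viridis_ramp() -> np.ndarray:
    # interpolated from a handful of viridis anchor colors
    anchors = np.array(
        [
            (68, 1, 84),
            (72, 40, 120),
            (62, 74, 137),
            (49, 104, 142),
            (38, 130, 142),
            (31, 158, 137),
            (53, 183, 121),
            (109, 205, 89),
            (180, 222, 44),
            (253, 231, 37),
        ],
        dtype=np.float64,
    )
    xs = np.linspace(0, 255, len(anchors))
    ramp = np.empty((256, 3), dtype=np.uint8)
    for ch in range(3):
        ramp[:, ch] = np.round(np.interp(np.arange(256), xs, anchors[:, ch]))
    return ramp


_GREY = np.repeat(np.arange(256, dtype=np.uint8)[:, None], 3, axis=1)
LUTS: dict[str, np.ndarray] = {
    "grey": _GREY,
    "inverted": _GREY[::-1].copy(),
    "viridis": _viridis_ramp(),
}
LUT_NAMES = tuple(LUTS)


def apply_lut(
    img: GreyImage, lut_name: str, range_: Optional[tuple[float, float]] = None
) -> np.ndarray:
    """Map intensities through a named 256-entry color table.

    Values are clipped to ``range_`` (default: data min/max) before the
    linear mapping: values at/below the low bound hit entry 0, at/above
    the high bound entry 255.  Returns an (ny, nx, 3) uint8 RGB array.
    """
    if lut_name not in LUTS:
        raise ValueError(f"unknown LUT {lut_name!r} (have {', '.join(LUT_NAMES)})")
    arr = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = range_ if range_ is not None else (float(arr.min()), float(arr.max()))
    if hi <= lo:
        idx = np.full(arr.shape, 128, dtype=np.uint8)
    else:
        idx = np.clip(np.round((arr - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)
    return LUTS[lut_name][idx]


# --- wave data -------------------------------------------------------------

def import_wave(path: Path) -> WaveSeries:
    """Read an equally spaced series from a one-column CSV.

    Optional ``# key = value`` header comments set start/spacing/unit and
    the element name; data rows must be single numbers.
    """
    path = Path(path)
    meta = {"start": 0.0, "spacing": 1.0, "unit": "s", "name": "signal", "element-unit": "a.u."}
    values = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        try:
            values.append(float(line.split(",")[0]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric wave row {line!r}") from None
    if not values:
        raise ValueError(f"{path}: empty wave file")
    dim = Dimension(
        name="t",
        kind="numeric",
        unit=str(meta["unit"]),
        start=float(meta["start"]),
        spacing=float(meta["spacing"]),
        length=len(values),
    )
    el = ElementDescriptor(str(meta["name"]), unit=str(meta["element-unit"]), precision="float64")
    return WaveSeries(np.array(values), dim, el)


def wave_preview(series: WaveSeries, size: tuple[int, int] = (512, 256)) -> bytes:
    """Deterministic polyline plot of the series as PNG bytes."""
    w, h = size
    img = Image.new("L", (w, h), color=255)
    draw = ImageDraw.Draw(img)
    v = series.values
    lo, hi = float(v.min()), float(v.max())
    span = (hi - lo) or 1.0
    margin = 8
    n = len(v)
    xs = (
        np.full(n, w / 2.0)
        if n == 1
        else margin + np.arange(n) * (w - 2 * margin) / (n - 1)
    )
    ys = (h - margin) - (v - lo) * (h - 2 * margin) / span
    pts = list(zip(xs.round().astype(int).tolist(), ys.round().astype(int).tolist()))
    if len(pts) == 1:
        draw.point(pts[0], fill=0)
    else:
        draw.line(pts, fill=0, width=1)
    draw.rectangle([0, 0, w - 1, h - 1], outline=128)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
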