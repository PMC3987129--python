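"""Greyscale image views: normalization, LUTs and the power spectrum.

Run:  python examples/05_views_and_datatypes.py
"""

import numpy as np

from bebkit.datatypes import GreyImage, apply_lut, make_thumbnail, power_spectrum_view

# a synthetic fringe pattern: zero-mean 5-period horizontal cosine, so the
# spectrum has no DC term and the two side peaks stand alone
n, k = 128, 5
pixels = 50 * np.tile(np.cos(2 * np.pi * k * np.arange(n) / n), (n, 1))
img = GreyImage(pixels)

png = make_thumbnail(img)
print(f"thumbnail: {len(png)} bytes of PNG, longest side <= 128 px")

rgb = apply_lut(img, "viridis")
print("viridis view shape:", rgb.shape, "dtype:", rgb.dtype)

spec = power_spectrum_view(img)
peaks = np.argwhere(spec.pixels > 0.99)
print("power-spectrum peaks (row, col), center is (64, 64):")
for p in peaks:
    print("  ", tuple(int(v) for v in p))

# A k-period cosine produces exactly two spectral peaks at +/-k columns from
# the image center - the standard check that the Fourier view is calibrated.
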