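"""Hierarchical coordinates: dish frame -> lysed cell -> EM image.

Run:  python examples/02_coordinates_and_time.py
"""

from bebkit import HCoord, make_timestamp, resolve_absolute, displayed_value

t0 = make_timestamp(2014, 3, 26, 9, 0, 0)
print("experiment start: seconds since 1904 =", t0.seconds)

dish = HCoord(rootflag=True, scale=1e6, t=t0, description="culture dish (display um)")
cell = HCoord(x=3_200_000, y=1_500_000, dx=100_000, dy=100_000, t=t0 + 300.0,
              scale=1e6, description="selected cell, pm relative to dish")
em = HCoord(x=2_000, y=-750, dx=1_000, dy=1_000, t=t0 + 2100.0,
            description="EM image, pm relative to cell")

absolute = resolve_absolute([dish, cell, em])
print(f"EM image in dish frame: x={absolute.x} pm, y={absolute.y} pm")
print(f"position error (quadrature): dx={absolute.dx:.0f} pm")
print(f"display units (scale 1e6 -> um): x={absolute.x / dish.scale:.4f} um")
print("display helper:", displayed_value(cell, "x"), "um for the cell x")

# Coordinates add exactly (integer picometers); position errors combine in
# quadrature; the timestamp is absolute per entity, taken from the target.
print("EM timestamp - start =", float(absolute.t - t0), "s")
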