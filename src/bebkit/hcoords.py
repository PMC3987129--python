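"""Hierarchical coordinate (HC) system.

Correlative experiments nest coordinate frames along the collection tree:
a cell culture dish defines a root frame, a lysed single cell a sub-frame,
and electron-microscopy images sub-sub-frames.  Each entity stores its
Cartesian position *relative to its parent* as signed 64-bit picometer
integers, so frames compose by plain vector addition and no floating-point
error accumulates across scales (from metres of stage travel down to
sub-nanometre image features).

Time is absolute, not hierarchical: every entity carries a 128-bit
fixed-point timestamp (64-bit signed seconds since 1904-01-01 00:00:00 UT,
ignoring leap seconds, plus a 64-bit unsigned fraction in units of 2**-64 s).
Two instruments calibrated against the same reference clock therefore
produce directly comparable stamps.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "EPOCH",
    "INT64_MIN",
    "INT64_MAX",
    "FRACTION_UNIT",
    "Timestamp128",
    "HCoord",
    "AbsoluteCoord",
    "make_timestamp",
    "to_calendar",
    "add_duration",
    "resolve_absolute",
    "displayed_value",
    "now",
]

#: Epoch of the timestamp representation (classic Macintosh epoch).
EPOCH = datetime(1904, 1, 1, 0, 0, 0)

INT64_MIN = -(2**63)
INT64_MAX = 2**63 - 1
#: One fractional unit is 2**-64 seconds.
FRACTION_UNIT = Fraction(1, 2**64)

#: Seconds between the 1904 epoch and the Unix epoch (24107 days).
UNIX_EPOCH_OFFSET = 2_082_844_800


class TimestampOverflowError(OverflowError):
    """Raised when a timestamp leaves the signed 64-bit seconds range."""


@dataclass(frozen=True, order=True)
class Timestamp128:
    """128-bit fixed-point instant: seconds since 1904 plus 2**-64 s fraction.

    Ordering is lexicographic on ``(seconds, fraction)``, which coincides
    with temporal order because the fraction is unsigned.
    """

    seconds: int
    fraction: int = 0

    def __post_init__(self) -> None:
        if not (INT64_MIN <= self.seconds <= INT64_MAX):
            raise TimestampOverflowError(
                f"seconds {self.seconds} outside signed 64-bit range"
            )
        if not (0 <= self.fraction < 2**64):
            raise ValueError(f"fraction {self.fraction} outside [0, 2**64)")

    def as_fraction(self) -> Fraction:
        """Exact value in seconds since the 1904 epoch."""
        return Fraction(self.seconds) + Fraction(self.fraction, 2**64)

    def __add__(self, dsec: float | Fraction | int) -> "Timestamp128":
        return add_duration(self, dsec)

    def __sub__(self, other: "Timestamp128") -> Fraction:
        return self.as_fraction() - other.as_fraction()


def make_timestamp(
    year: int,
    month: int,
    day: int,
    hour: int = 0,
    minute: int = 0,
    second: int = 0,
    frac: float | Fraction = 0,
) -> Timestamp128:
    """Build a timestamp from a Gregorian calendar instant.

    Days are uniformly 86400 s (leap seconds ignored).  ``frac`` is the
    sub-second part in ``[0, 1)``; dyadic rationals convert exactly.
    """
    cal = datetime(year, month, day, hour, minute, second)
    delta = cal - EPOCH
    seconds = delta.days * 86400 + delta.seconds
    frac = Fraction(frac)
    if not 0 <= frac < 1:
        raise ValueError("fractional part must be in [0, 1)")
    fraction = int(frac * 2**64)
    return Timestamp128(seconds, fraction)


def to_calendar(ts: Timestamp128) -> tuple[int, int, int, int, int, int, Fraction]:
    """Inverse of :func:`make_timestamp`, exact to 2**-64 s."""
    cal = EPOCH + timedelta(seconds=ts.seconds)
    return (
        cal.year,
        cal.month,
        cal.day,
        cal.hour,
        cal.minute,
        cal.second,
        Fraction(ts.fraction, 2**64),
    )


def add_duration(ts: Timestamp128, dsec: float | Fraction | int) -> Timestamp128:
    """Add a (possibly negative) duration in seconds, with exact carry.

    The duration is converted to an exact rational, scaled to 2**-64 s
    units and rounded half-to-even once; dyadic durations are exact.
    """
    total = ts.seconds * 2**64 + ts.fraction
    delta_units = Fraction(dsec) * 2**64
    total += round(delta_units)
    seconds, fraction = divmod(total, 2**64)
    return Timestamp128(seconds, fraction)  # range check in constructor


def now(clock_offset: float = 0.0, _clock=None) -> Timestamp128:
    """Current instant as a 1904-epoch timestamp.

    ``clock_offset`` (seconds) is added to the system clock; it is the
    injection point for external clock calibration, so instruments sharing
    one calibration source produce comparable stamps.  ``_clock`` is a
    zero-argument callable returning Unix seconds, for tests.
    """
    unix = Fraction((_clock or _time.time)()) + Fraction(clock_offset)
    return add_duration(Timestamp128(UNIX_EPOCH_OFFSET, 0), unix)


@dataclass
class HCoord:
    """One entity's coordinate record, relative to its parent frame.

    ``x, y, z`` are picometer integers; ``dx, dy, dz`` estimated standard
    errors in pm; ``t`` is absolute; ``dt`` its standard error in seconds.
    ``scale`` is a display divisor basis: 1000 shows nanometres.
    """

    x: int = 0
    y: int = 0
    z: int = 0
    rootflag: bool = False
    scale: float = 1.0
    dx: int = 0
    dy: int = 0
    dz: int = 0
    t: Timestamp128 = field(default_factory=lambda: Timestamp128(0, 0))
    dt: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not isinstance(v, int) or not (INT64_MIN <= v <= INT64_MAX):
                raise ValueError(f"{name}={v!r} not a signed 64-bit pm integer")
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name}={v!r} must be a non-negative pm integer")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.dt < 0:
            raise ValueError("dt must be non-negative")

    def replace(self, **kw) -> "HCoord":
        return replace(self, **kw)


@dataclass(frozen=True)
class AbsoluteCoord:
    """Coordinates resolved into the root frame (pm / seconds)."""

    x: int
    y: int
    z: int
    dx: float
    dy: float
    dz: float
    t: Timestamp128
    dt: float
    root: HCoord


class RootError(ValueError):
    """Raised when a resolution path has no root or more than one root."""


def resolve_absolute(path: Sequence[HCoord]) -> AbsoluteCoord:
    """Resolve a root-to-target path of coordinate records.

    The first entry must be the (sole) frame root; its own x, y, z define
    the origin and are excluded from the sum.  Spatial offsets of the
    remaining entries are summed exactly; standard errors combine in
    quadrature (independent errors).  Time and its error are taken from
    the target — time is absolute per entity, never accumulated.
    """
    if not path:
        raise RootError("empty coordinate path")
    if not path[0].rootflag:
        raise RootError("first entity on the path is not a coordinate root")
    roots = [i for i, c in enumerate(path) if c.rootflag]
    if len(roots) > 1:
        raise RootError(f"multiple coordinate roots on path (indices {roots})")
    tail = path[1:]
    x = sum(c.x for c in tail)
    y = sum(c.y for c in tail)
    z = sum(c.z for c in tail)
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not (INT64_MIN <= v <= INT64_MAX):
            raise OverflowError(f"absolute {name}={v} overflows signed 64-bit pm")
    dx = math.sqrt(sum(c.dx**2 for c in tail))
    dy = math.sqrt(sum(c.dy**2 for c in tail))
    dz = math.sqrt(sum(c.dz**2 for c in tail))
    target = path[-1]
    return AbsoluteCoord(x, y, z, dx, dy, dz, target.t, target.dt, root=path[0])


def displayed_value(coord: HCoord, axis: str) -> float:
    """Stored pm value divided by the display scale (1000 -> nm)."""
    if axis not in ("x", "y", "z"):
        raise ValueError(f"unknown axis {axis!r}")
    return getattr(coord, axis) / coord.scale
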