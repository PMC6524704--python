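"""Interval barcoding: map a property vector to its 9-digit class code.

The range of each descriptor is split into three intervals; a peptide's
class ("barcode") is the concatenation of its interval digits in canonical
descriptor order (length, GRAVY, bulkiness, polarity, net charge, basic,
acidic, aromatic, proline). With three intervals per descriptor there are
3**9 = 19,683 possible classes.

Default cut points (a cut-point pair ``(c1, c2)`` with a closure rule):

========== ========== ============== ==========
descriptor interval 1 interval 2     interval 3
========== ========== ============== ==========
length      <= 9       [10; 12]       >= 13
gravy       <= -2      ]-2; -0.5]     > -0.5
bulkiness   <= 12.6    ]12.6; 14.7]   > 14.7
polarity    <= 8.7     ]8.7; 10.1]    > 10.1
net charge  < 0        [0; 1]         > 1
frac_*      = 0        ]0; 0.12]      > 0.12
========== ========== ============== ==========

The scheme is data, not code: alternative cut points for other media or
instruments can be supplied through a plain-text config block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .properties import DESCRIPTOR_ORDER, PropertyVector

__all__ = [
    "DescriptorIntervals",
    "IntervalScheme",
    "DEFAULT_SCHEME",
    "assign_interval",
    "assign_barcode",
    "theoretical_class_count",
]


@dataclass(frozen=True)
class DescriptorIntervals:
    """Three intervals over one descriptor, defined by two ordered cuts.

    ``closure='le'`` (the common case): interval 1 is ``value <= c1``,
    interval 2 is ``c1 < value <= c2``, interval 3 is ``value > c2``.
    For residue fractions (non-negative with cut c1 = 0) this reduces to
    the "zero sub-class" rule: interval 1 means the residue type is absent.

    ``closure='lt'`` (net charge): interval 1 is ``value < c1``, interval 2
    is ``c1 <= value <= c2``, interval 3 is ``value > c2``.
    """

    c1: float
    c2: float
    closure: str = "le"

    def __post_init__(self) -> None:
        if self.closure not in ("le", "lt"):
            raise ValueError(f"unknown closure {self.closure!r}")
        if not self.c1 <= self.c2:
            raise ValueError(f"cuts out of order: {self.c1} > {self.c2}")

    def assign(self, value: float) -> int:
        if math.isnan(value):
            raise ValueError("cannot assign an interval to NaN")
        in_first = value <= self.c1 if self.closure == "le" else value < self.c1
        if in_first:
            return 1
        return 2 if value <= self.c2 else 3

    @property
    def n_intervals(self) -> int:
        return 3


@dataclass(frozen=True)
class IntervalScheme:
    """Per-descriptor interval rules, in canonical descriptor order."""

    intervals: Mapping[str, DescriptorIntervals]

    def __post_init__(self) -> None:
        missing = set(DESCRIPTOR_ORDER) - set(self.intervals)
        if missing:
            raise ValueError(f"scheme missing descriptors: {sorted(missing)}")

    def to_text(self) -> str:
        """Serialize as a plain-text config block (descriptor c1 c2 closure)."""
        lines = ["# descriptor\tc1\tc2\tclosure"]
        for name in DESCRIPTOR_ORDER:
            iv = self.intervals[name]
            lines.append(f"{name}\t{iv.c1!r}\t{iv.c2!r}\t{iv.closure}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "IntervalScheme":
        intervals: dict[str, DescriptorIntervals] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, c1, c2, closure = line.split()
            intervals[name] = DescriptorIntervals(float(c1), float(c2), closure)
        return cls(intervals=intervals)


DEFAULT_SCHEME = IntervalScheme(
    intervals={
        "length": DescriptorIntervals(9, 12),
        "gravy": DescriptorIntervals(-2.0, -0.5),
        "bulkiness": DescriptorIntervals(12.6, 14.7),
        "polarity": DescriptorIntervals(8.7, 10.1),
        "net_charge": DescriptorIntervals(0.0, 1.0, closure="lt"),
        "frac_basic": DescriptorIntervals(0.0, 0.12),
        "frac_acidic": DescriptorIntervals(0.0, 0.12),
        "frac_aromatic": DescriptorIntervals(0.0, 0.12),
        "frac_proline": DescriptorIntervals(0.0, 0.12),
    }
)


def assign_interval(
    value: float, descriptor: str, scheme: IntervalScheme = DEFAULT_SCHEME
) -> int:
    """Interval digit (1, 2 or 3) of *value* for *descriptor*.

    Boundary values resolve by the scheme's closure rules; comparison is
    exact full-precision (no rounding before the cut).
    """
    if descriptor not in scheme.intervals:
        raise KeyError(f"unknown descriptor {descriptor!r}")
    return scheme.intervals[descriptor].assign(value)


def assign_barcode(
    pv: PropertyVector, scheme: IntervalScheme = DEFAULT_SCHEME
) -> str:
    """9-digit class code of a property vector, in canonical order."""
    digits = [
        assign_interval(getattr(pv, name), name, scheme)
        for name in DESCRIPTOR_ORDER
    ]
    return "".join(str(d) for d in digits)


def theoretical_class_count(scheme: IntervalScheme = DEFAULT_SCHEME) -> int:
    """Number of possible class codes: product of interval counts."""
    count = 1
    for name in scheme.intervals:
        count *= scheme.intervals[name].n_intervals
    return count
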