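"""A matplotlib scale for labeled MAD fold-change axes.

The scale (registered under the name ``"madfc"``) places data at its
MAD-transformed coordinate but labels ticks with the *raw* fold change,
so values can be read straight off the axis — a labeled MAD plot.  Raw
MAD coordinates are never shown by default.

Tick positions are integer fold-change-unit coordinates, thinned by the
smallest integer stride that respects ``max_ticks`` while always keeping
the point of no change (display position 0, labeled ``"1"``) when it is in
range.  Labels render in one of three styles: ``fraction`` (``"1/3"``),
``decimal`` (``"0.333"``), or ``exponent`` (``"2^-2"`` when the value is an
exact integer power of the base, decimal fallback otherwise).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from matplotlib import scale as mscale
from matplotlib import transforms as mtransforms
from matplotlib.ticker import FuncFormatter, Locator, NullFormatter, NullLocator

from .transforms import madfc_forward, madfc_inverse

__all__ = [
    "LabelStyle",
    "TickSpec",
    "make_ticks",
    "format_fc_label",
    "parse_fc_label",
    "MadFCScale",
    "register_scale",
]

LabelStyle = Literal["fraction", "decimal", "exponent"]

_STYLES = ("fraction", "decimal", "exponent")

# absolute tolerance for recognizing integers / unit fractions / powers in labels
_SNAP = 1e-9


@dataclass(frozen=True)
class TickSpec:
    """Paired display positions and back-transformed labels for a MAD axis.

    ``positions`` are strictly increasing MAD display coordinates;
    ``labels[i]`` is the raw fold change ``madfc_inverse(positions[i])``
    rendered per the label style.  ``anchor_index`` locates the
    point-of-no-change tick (position 0, label "1") when it is in range.
    """

    positions: tuple = field(default_factory=tuple)
    labels: tuple = field(default_factory=tuple)
    anchor_index: Optional[int] = None

    def __post_init__(self):
        if len(self.positions) != len(self.labels):
            raise ValueError("positions and labels must have equal length")
        pos = np.asarray(self.positions, dtype=float)
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("tick positions must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "positions": [float(p) for p in self.positions],
            "labels": list(self.labels),
            "anchor_index": self.anchor_index,
        }


def _check_style(style: str) -> None:
    if style not in _STYLES:
        raise ValueError(f"unknown label style {style!r}; expected one of {_STYLES}")


def _decimal_str(x: float, precision: int = 4) -> str:
    s = f"{x:.{precision}g}"
    return s


def format_fc_label(x: float, style: LabelStyle = "fraction", *,
                    precision: int = 4, exp_base: int = 2) -> str:
    """Render a raw fold change as an axis tick label.

    The point of no change renders as ``"1"`` in every style.  Fraction
    style emits ``"1/k"`` for unit fractions and plain integers otherwise;
    exponent style emits ``"b^p"`` for exact integer powers of ``exp_base``.
    Values not exactly representable in the requested style fall back to a
    fixed-precision decimal.
    """
    _check_style(style)
    x = float(x)
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"fold change label requires a positive finite value, got {x!r}")
    if abs(x - 1.0) < _SNAP:
        return "1"
    if style == "fraction":
        if x < 1.0:
            inv = 1.0 / x
            if abs(inv - round(inv)) < _SNAP:
                return f"1/{round(inv)}"
        elif abs(x - round(x)) < _SNAP:
            return str(round(x))
        return _decimal_str(x, precision)
    if style == "exponent":
        p = math.log(x, exp_base)
        if abs(p - round(p)) < _SNAP:
            return f"{exp_base}^{round(p)}"
        return _decimal_str(x, precision)
    return _decimal_str(x, precision)


_FRACTION_RE = re.compile(r"^1/(\d+)$")
_EXP_RE = re.compile(r"^(\d+)\^(-?\d+)$")


def parse_fc_label(label: str) -> float:
    """Parse a tick label back to its raw fold change (fraction/exponent aware)."""
    s = label.strip()
    m = _FRACTION_RE.match(s)
    if m:
        return 1.0 / int(m.group(1))
    m = _EXP_RE.match(s)
    if m:
        return float(int(m.group(1)) ** int(m.group(2)))
    return float(s)


def make_ticks(lo: float, hi: float, max_ticks: int = 9,
               style: LabelStyle = "fraction") -> TickSpec:
    """Build tick positions and labels for a MAD display range ``[lo, hi]``.

    Candidates sit at every integer fold-change-unit position in range.  If
    they exceed ``max_ticks`` they are thinned to multiples of the smallest
    integer stride that fits, which keeps position 0 whenever it is in
    range.  Sub-unit ranges (fewer than three integer candidates) fall back
    to five evenly spaced positions with decimal back-transformed labels,
    snapping one of them to the point of no change when it is in range.
    """
    lo, hi = float(lo), float(hi)
    if not (lo < hi):
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    if max_ticks < 3:
        raise ValueError(f"max_ticks must be >= 3, got {max_ticks}")
    _check_style(style)

    candidates = np.arange(math.ceil(lo - _SNAP), math.floor(hi + _SNAP) + 1, dtype=float)

    # labels carry 12 significant digits so decimal fallbacks still satisfy
    # the 1e-9 parse-and-retransform consistency contract; the on-screen
    # formatter renders a friendlier 4-digit form
    if candidates.size < 3:
        positions = np.linspace(lo, hi, 5)
        if lo < 0.0 < hi:
            positions[np.argmin(np.abs(positions))] = 0.0
        positions = np.unique(positions)
        labels = tuple(
            "1" if abs(p) < _SNAP else _decimal_str(float(madfc_inverse(p)), 12)
            for p in positions
        )
    else:
        positions = candidates
        if positions.size > max_ticks:
            stride = 2
            while True:
                kept = positions[np.mod(positions, stride) == 0]
                if kept.size < 2:
                    kept = positions[::stride]
                if kept.size <= max_ticks:
                    positions = kept
                    break
                stride += 1
        labels = tuple(
            format_fc_label(float(madfc_inverse(p)), style, precision=12)
            for p in positions
        )

    pos_tuple = tuple(float(p) for p in positions)
    anchor = None
    for i, p in enumerate(pos_tuple):
        if abs(p) < _SNAP:
            anchor = i
            break
    return TickSpec(positions=pos_tuple, labels=labels, anchor_index=anchor)


class _MadFCTransform(mtransforms.Transform):
    input_dims = output_dims = 1

    def transform_non_affine(self, values):
        a = np.asarray(values, dtype=float)
        return np.asarray(madfc_forward(a.ravel(), policy="propagate")).reshape(a.shape)

    def inverted(self):
        return _MadFCInverseTransform()


class _MadFCInverseTransform(mtransforms.Transform):
    input_dims = output_dims = 1

    def transform_non_affine(self, values):
        a = np.asarray(values, dtype=float)
        return np.asarray(madfc_inverse(a.ravel())).reshape(a.shape)

    def inverted(self):
        return _MadFCTransform()


class _MadFCLocator(Locator):
    def __init__(self, max_ticks: int = 9, style: LabelStyle = "fraction"):
        self.max_ticks = max_ticks
        self.style = style

    def __call__(self):
        vmin, vmax = self.axis.get_view_interval()
        return self.tick_values(vmin, vmax)

    def tick_values(self, vmin, vmax):
        if vmin > vmax:
            vmin, vmax = vmax, vmin
        tiny = np.finfo(float).tiny
        vmin = max(vmin, tiny)
        vmax = max(vmax, vmin * (1 + 1e-9))
        lo = float(madfc_forward(vmin))
        hi = float(madfc_forward(vmax))
        if not (lo < hi):
            lo, hi = lo - 0.5, hi + 0.5
        spec = make_ticks(lo, hi, self.max_ticks, self.style)
        return [float(madfc_inverse(p)) for p in spec.positions]

    def nonsingular(self, v0, v1):
        if not np.isfinite(v0) or not np.isfinite(v1):
            return 0.5, 2.0
        if v0 > v1:
            v0, v1 = v1, v0
        if v0 == v1:
            # pad half a fold-change unit either side in display space
            d = float(madfc_forward(max(v0, np.finfo(float).tiny)))
            return float(madfc_inverse(d - 0.5)), float(madfc_inverse(d + 0.5))
        return v0, v1


class MadFCScale(mscale.ScaleBase):
    """Axis scale mapping raw fold change to MAD display coordinates.

    Usage: ``ax.set_yscale("madfc")`` or
    ``ax.set_xscale("madfc", label_style="exponent", max_ticks=7)``.
    Data at or below zero is masked (out of the fold-change domain).
    The default formatter always back-transforms tick labels to raw fold
    change, so a raw MAD axis is never produced.
    """

    name = "madfc"

    def __init__(self, axis, *, label_style: LabelStyle = "fraction",
                 max_ticks: int = 9):
        super().__init__(axis)
        _check_style(label_style)
        self.label_style = label_style
        self.max_ticks = max_ticks

    def get_transform(self):
        return _MadFCTransform()

    def set_default_locators_and_formatters(self, axis):
        axis.set_major_locator(_MadFCLocator(self.max_ticks, self.label_style))
        style = self.label_style

        def _fmt(value, pos=None):
            if not np.isfinite(value) or value <= 0:
                return ""
            return format_fc_label(value, style)

        axis.set_major_formatter(FuncFormatter(_fmt))
        axis.set_minor_locator(NullLocator())
        axis.set_minor_formatter(NullFormatter())

    def limit_range_for_scale(self, vmin, vmax, minpos):
        if not np.isfinite(minpos):
            minpos = 1e-300
        return (minpos if vmin <= 0 else vmin,
                minpos if vmax <= 0 else vmax)


def register_scale():
    """Register the ``"madfc"`` scale with matplotlib (idempotent)."""
    mscale.register_scale(MadFCScale)
    return MadFCScale


register_scale()
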