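"""Fold-change color normalization for diverging heatmap palettes.

Maps raw fold change to [0, 1] through a chosen coordinate transform
(``linear``, ``log2`` or ``madfc``), rescaling linearly between the
transformed bounds.  A *symmetric* spec re-centers the bounds about the
transform's point of no change (``t(1)``: 0 for log2/MAD, 1 for linear) so
that no change always lands at the colormap midpoint 0.5 and reciprocal
fold-change pairs receive complementary colors under log2 and MAD.  Under
the MAD transform equal steps in fold-change units map to equal steps in
color — the property that keeps large fold changes distinguishable where a
log2 color scale compresses them.

Out-of-range values clip to [0, 1] rather than error: real heatmaps
routinely contain outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from matplotlib.colors import Normalize

from .transforms import DomainPolicy, fold_change_units, fc_to_log2

__all__ = ["ColorNormSpec", "normalize", "MadFCNorm", "spec_from_data",
           "DEFAULT_CMAP"]

ColorTransform = Literal["linear", "log2", "madfc"]

#: blue-white-red diverging palette; a config choice, not science.
DEFAULT_CMAP = "RdBu_r"


def _transform_fn(name: str) -> Callable:
    if name == "linear":
        return lambda x, policy="propagate": np.asarray(x, dtype=float)
    if name == "log2":
        return lambda x, policy="propagate": np.asarray(fc_to_log2(x, policy=policy), dtype=float)
    if name == "madfc":
        return lambda x, policy="propagate": np.asarray(fold_change_units(x, policy=policy), dtype=float)
    raise ValueError(f"unknown color transform {name!r}; expected linear, log2 or madfc")


@dataclass(frozen=True)
class ColorNormSpec:
    """Configuration for mapping fold change onto a colormap.

    ``vmin_fc``/``vmax_fc`` are raw fold-change bounds (both positive,
    ``vmin_fc < vmax_fc``); ``symmetric`` centers the map on no change.
    """

    transform: ColorTransform = "madfc"
    vmin_fc: float = 0.25
    vmax_fc: float = 4.0
    symmetric: bool = True

    def __post_init__(self):
        _transform_fn(self.transform)
        if not (np.isfinite(self.vmin_fc) and np.isfinite(self.vmax_fc)):
            raise ValueError("color bounds must be finite")
        if self.vmin_fc <= 0 or self.vmax_fc <= 0:
            raise ValueError(
                f"color bounds must be positive fold changes, got "
                f"vmin_fc={self.vmin_fc}, vmax_fc={self.vmax_fc}")
        if not self.vmin_fc < self.vmax_fc:
            raise ValueError(
                f"require vmin_fc < vmax_fc, got {self.vmin_fc} >= {self.vmax_fc}")

    def display_bounds(self) -> tuple[float, float]:
        """Bounds in transform space, after symmetric re-centering."""
        t = _transform_fn(self.transform)
        tlo = float(t(self.vmin_fc))
        thi = float(t(self.vmax_fc))
        if self.symmetric:
            center = float(t(1.0))
            radius = max(abs(tlo - center), abs(thi - center))
            tlo, thi = center - radius, center + radius
        return tlo, thi


def normalize(x, spec: ColorNormSpec, policy: DomainPolicy = "propagate"):
    """Map fold change ``x`` (scalar or array) to [0, 1] per ``spec``.

    Values beyond the bounds clip; out-of-domain values follow ``policy``
    (NaN under ``propagate``).
    """
    t = _transform_fn(spec.transform)
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    flat = np.atleast_1d(arr).ravel()
    tx = np.asarray(t(flat, policy=policy), dtype=float)
    tlo, thi = spec.display_bounds()
    with np.errstate(invalid="ignore"):
        out = np.clip((tx - tlo) / (thi - tlo), 0.0, 1.0)
    if scalar:
        return float(out[0])
    return out.reshape(arr.shape)


def denormalize(v, spec: ColorNormSpec):
    """Map normalized color values in [0, 1] back to raw fold change."""
    from .transforms import log2_to_fc, madfc_inverse

    arr = np.asarray(v, dtype=float)
    scalar = arr.ndim == 0
    tlo, thi = spec.display_bounds()
    t = tlo + np.atleast_1d(arr).ravel() * (thi - tlo)
    if spec.transform == "linear":
        fc = t
    elif spec.transform == "log2":
        fc = np.asarray(log2_to_fc(t))
    else:
        fc = np.asarray(madfc_inverse(t))
    if scalar:
        return float(fc[0])
    return fc.reshape(arr.shape)


class MadFCNorm(Normalize):
    """Matplotlib ``Normalize`` backed by a :class:`ColorNormSpec`.

    Lets ``imshow``/``pcolormesh`` consume raw fold-change matrices
    directly while coloring them in transform space.
    """

    def __init__(self, spec: ColorNormSpec):
        super().__init__(vmin=0.0, vmax=1.0, clip=False)
        self.spec = spec

    def __call__(self, value, clip=None):
        return np.ma.masked_invalid(normalize(value, self.spec))

    def inverse(self, value):
        return denormalize(value, self.spec)


def spec_from_data(values, transform: ColorTransform = "madfc",
                   symmetric: bool = True) -> ColorNormSpec:
    """Data-driven spec: bounds at the extreme finite fold changes observed."""
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr) & (arr > 0)]
    if arr.size == 0:
        raise ValueError("no positive finite fold changes to derive color bounds from")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:  # degenerate matrix; pad one fold-change unit either side
        lo, hi = lo / 2.0, hi * 2.0
    return ColorNormSpec(transform=transform, vmin_fc=lo, vmax_fc=hi,
                         symmetric=symmetric)
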