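"""Builders for the six fold-change figure types.

Each builder renders a matplotlib figure under one of three scales —
``linear`` (raw fold change), ``log2``, or ``madfc`` — and returns, next to
the figure, a :class:`PlotSpec`: the computed display positions, tick
specification, significance classes and summary geometry, serializable to
JSON so every visual claim is assertable without pixel inspection.

Conventions shared by all builders:

- display positions are the chosen transform applied to raw fold change
  (NaN where the domain policy propagated an out-of-domain value);
- significance classification never depends on the display scale;
- interval *endpoints* are transformed, never widths — under the MAD scale
  an interval of half-width h fold-change units therefore renders with
  display half-width exactly h;
- box quartiles are computed on raw fold changes and then transformed
  (legitimate because monotone transforms commute with order-statistic
  quantiles); whiskers use the Tukey 1.5·IQR rule in display space;
- violin densities are estimated *in display space* (Gaussian KDE, Scott
  bandwidth, 256-point grid) since densities do not commute with monotone
  transforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import matplotlib
import matplotlib.pyplot as plt

from . import axis_scale  # registers the "madfc" scale on import
from .axis_scale import LabelStyle, TickSpec, make_ticks
from .color_norm import DEFAULT_CMAP, ColorNormSpec, MadFCNorm, normalize, spec_from_data
from .transforms import (
    DomainPolicy,
    fc_to_log2,
    fold_change_units,
    log2_to_fc,
    madfc_forward,
)

__all__ = [
    "SCALE_NAMES",
    "CLASS_COLORS",
    "IntervalEstimate",
    "PlotSpec",
    "as_results_table",
    "classify_significance",
    "scale_transform",
    "volcano",
    "ma_plot",
    "interval_plot",
    "box_plot",
    "violin_plot",
    "heatmap",
]

SCALE_NAMES = ("linear", "log2", "madfc")

#: Up/Down/NS coloring of differential-results scatterplots.
CLASS_COLORS = {"Up": "red", "Down": "blue", "NS": "black"}

_RESULT_COLUMNS = ("feature_id", "fc", "log2fc", "pvalue", "padj", "base_mean")


def scale_transform(scale: str):
    """Forward display transform for a scale name (propagating policy)."""
    if scale == "linear":
        return lambda x: np.asarray(x, dtype=float)
    if scale == "log2":
        return lambda x: np.asarray(fc_to_log2(x, policy="propagate"), dtype=float)
    if scale == "madfc":
        return lambda x: np.asarray(madfc_forward(x, policy="propagate"), dtype=float)
    raise ValueError(f"unknown scale {scale!r}; expected one of {SCALE_NAMES}")


def _apply_scale(ax, scale: str, axis: str = "x",
                 label_style: LabelStyle = "fraction") -> None:
    """Set the matplotlib axis scale so raw fold change can be plotted directly."""
    setter = ax.set_xscale if axis == "x" else ax.set_yscale
    if scale == "madfc":
        setter("madfc", label_style=label_style)
    elif scale == "log2":
        setter("log", base=2)
    # linear is matplotlib's default


def _axis_label(scale: str) -> str:
    return {"linear": "fold change", "log2": "fold change (log2 scale)",
            "madfc": "fold change (MAD scale)"}[scale]


@dataclass(frozen=True)
class IntervalEstimate:
    """A fold-change point estimate with interval endpoints (all positive)."""

    center_fc: float
    lower_fc: float
    upper_fc: float

    def __post_init__(self):
        # equality permitted so zero-width (point) intervals are representable
        if not (0 < self.lower_fc <= self.center_fc <= self.upper_fc):
            raise ValueError(
                "require 0 < lower_fc <= center_fc <= upper_fc, got "
                f"({self.lower_fc}, {self.center_fc}, {self.upper_fc})")

    @classmethod
    def from_fcu(cls, center_fc: float, half_width_fcu: float) -> "IntervalEstimate":
        """Build from a center and a symmetric half-width in fold-change units."""
        from .transforms import madfc_inverse
        c = float(madfc_forward(center_fc))
        return cls(center_fc=float(center_fc),
                   lower_fc=float(madfc_inverse(c - half_width_fcu)),
                   upper_fc=float(madfc_inverse(c + half_width_fcu)))


@dataclass
class PlotSpec:
    """Assertable record of what a builder drew."""

    kind: str
    scale_name: str
    point_positions: dict = field(default_factory=dict)
    tick_spec: Optional[TickSpec] = None
    class_labels: Optional[list] = None
    summary_geometry: Optional[dict] = None

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, TickSpec):
                return obj.to_dict()
            if isinstance(obj, np.ndarray):
                return [None if not np.isfinite(v) else float(v) for v in obj.ravel()]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj
        return {
            "kind": self.kind,
            "scale_name": self.scale_name,
            "point_positions": _clean(self.point_positions),
            "tick_spec": _clean(self.tick_spec),
            "class_labels": _clean(self.class_labels),
            "summary_geometry": _clean(self.summary_geometry),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def as_results_table(table: pd.DataFrame, policy: DomainPolicy = "propagate") -> pd.DataFrame:
    """Validate/complete a differential-results table.

    Exactly one of ``fc``/``log2fc`` must be present on input; the other is
    derived.  ``pvalue``/``padj`` are checked against [0, 1] where present.
    """
    df = table.copy()
    has_fc, has_lfc = "fc" in df, "log2fc" in df
    if not has_fc and not has_lfc:
        raise ValueError("results table needs an 'fc' or 'log2fc' column")
    if has_fc and not has_lfc:
        df["log2fc"] = fc_to_log2(df["fc"].to_numpy(dtype=float), policy=policy)
    elif has_lfc and not has_fc:
        df["fc"] = log2_to_fc(df["log2fc"].to_numpy(dtype=float))
    if "feature_id" not in df:
        df.insert(0, "feature_id", [f"feature{i}" for i in range(len(df))])
    if "pvalue" not in df:
        raise ValueError("results table needs a 'pvalue' column")
    for col in ("pvalue", "padj"):
        if col in df:
            vals = df[col].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if ((vals[finite] < 0) | (vals[finite] > 1)).any():
                raise ValueError(f"{col} values must lie in [0, 1]")
    if len(df) == 0:
        raise ValueError("results table is empty")
    return df


def classify_significance(table: pd.DataFrame, padj_max: float = 0.1,
                          lfc_min: float = 1.0, units: str = "log2") -> np.ndarray:
    """Up/Down/NS calls: adjusted p below ``padj_max`` AND effect magnitude
    above ``lfc_min``.

    ``units`` selects how the magnitude threshold is read: ``"log2"``
    (|log2 FC| > lfc_min, the volcano-tool convention) or ``"fcu"``
    (|fold-change units| > lfc_min).  Rows with missing adjusted p are NS;
    a table with no ``padj`` column falls back to raw p-values with a
    warning.  Classification is independent of any display scale.
    """
    if padj_max < 0 or lfc_min < 0:
        raise ValueError("thresholds must be nonnegative")
    df = as_results_table(table)
    if "padj" in df and df["padj"].notna().any():
        p = df["padj"].to_numpy(dtype=float)
    else:
        warnings.warn("no adjusted p-values present; falling back to raw p-values",
                      stacklevel=2)
        p = df["pvalue"].to_numpy(dtype=float)
    if units == "log2":
        mag = df["log2fc"].to_numpy(dtype=float)
    elif units == "fcu":
        mag = np.asarray(fold_change_units(df["fc"].to_numpy(dtype=float),
                                           policy="propagate"))
    else:
        raise ValueError(f"unknown units {units!r}; expected 'log2' or 'fcu'")
    with np.errstate(invalid="ignore"):
        sig = np.isfinite(p) & (p < padj_max) & np.isfinite(mag)
        up = sig & (mag > lfc_min)
        down = sig & (mag < -lfc_min)
    out = np.full(len(df), "NS", dtype=object)
    out[up] = "Up"
    out[down] = "Down"
    return out


def _tick_spec_for(scale: str, positions: np.ndarray,
                   label_style: LabelStyle = "fraction") -> Optional[TickSpec]:
    """MAD-scale axes carry a back-transformed tick spec; others defer to
    matplotlib's stock locators (log ticks are already raw fold change)."""
    if scale != "madfc":
        return None
    finite = positions[np.isfinite(positions)]
    if finite.size == 0:
        return None
    lo, hi = float(finite.min()), float(finite.max())
    if not lo < hi:
        lo, hi = lo - 0.5, hi + 0.5
    return make_ticks(lo, hi, max_ticks=11, style=label_style)


def volcano(table: pd.DataFrame, scale: str = "madfc", *,
            padj_max: float = 0.1, lfc_min: float = 1.0,
            threshold_units: str = "log2",
            label_style: LabelStyle = "fraction",
            policy: DomainPolicy = "propagate"):
    """Volcano plot: -log10 p-value against fold change under ``scale``.

    Points color by significance class (Up red, Down blue, NS black).
    Returns ``(figure, PlotSpec)``.
    """
    df = as_results_table(table, policy=policy)
    fc = df["fc"].to_numpy(dtype=float)
    x = scale_transform(scale)(fc)
    if not np.isfinite(x).any():
        raise ValueError("no fold change in the table is displayable under this scale")
    p = np.clip(df["pvalue"].to_numpy(dtype=float), 1e-300, 1.0)
    y = -np.log10(p)
    labels = classify_significance(df, padj_max, lfc_min, units=threshold_units)

    fig, ax = plt.subplots(figsize=(5, 4))
    _apply_scale(ax, scale, axis="x", label_style=label_style)
    for cls, color in CLASS_COLORS.items():
        m = labels == cls
        if m.any():
            ax.scatter(fc[m], y[m], s=6, c=color, label=cls, alpha=0.6,
                       linewidths=0)
    ax.set_xlabel(_axis_label(scale))
    ax.set_ylabel("-log10 p-value")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()

    spec = PlotSpec(
        kind="volcano", scale_name=scale,
        point_positions={"x": x, "y": y},
        tick_spec=_tick_spec_for(scale, x, label_style),
        class_labels=list(labels),
    )
    return fig, spec


def ma_plot(table: pd.DataFrame, scale: str = "madfc", *,
            padj_max: float = 0.1, lfc_min: float = 1.0,
            threshold_units: str = "log2",
            pseudocount: float = 0.5,
            label_style: LabelStyle = "fraction",
            policy: DomainPolicy = "propagate"):
    """MA plot: fold change under ``scale`` against log10 mean abundance."""
    df = as_results_table(table, policy=policy)
    if "base_mean" not in df:
        raise ValueError("MA plot requires a 'base_mean' column")
    fc = df["fc"].to_numpy(dtype=float)
    y = scale_transform(scale)(fc)
    if not np.isfinite(y).any():
        raise ValueError("no fold change in the table is displayable under this scale")
    x = np.log10(df["base_mean"].to_numpy(dtype=float) + pseudocount)
    labels = classify_significance(df, padj_max, lfc_min, units=threshold_units)

    fig, ax = plt.subplots(figsize=(5, 4))
    _apply_scale(ax, scale, axis="y", label_style=label_style)
    for cls, color in CLASS_COLORS.items():
        m = labels == cls
        if m.any():
            ax.scatter(x[m], fc[m], s=6, c=color, label=cls, alpha=0.6,
                       linewidths=0)
    ax.set_xlabel("log10 mean abundance")
    ax.set_ylabel(_axis_label(scale))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()

    spec = PlotSpec(
        kind="ma", scale_name=scale,
        point_positions={"x": x, "y": y},
        tick_spec=_tick_spec_for(scale, y, label_style),
        class_labels=list(labels),
    )
    return fig, spec


def interval_plot(groups: Sequence[IntervalEstimate], scale: str = "madfc", *,
                  label_style: LabelStyle = "fraction"):
    """Point estimates with interval bars; endpoints transformed, never widths."""
    if len(groups) == 0:
        raise ValueError("need at least one interval group")
    t = scale_transform(scale)
    centers = t([g.center_fc for g in groups])
    lowers = t([g.lower_fc for g in groups])
    uppers = t([g.upper_fc for g in groups])
    xs = np.arange(len(groups), dtype=float)

    fig, ax = plt.subplots(figsize=(5, 4))
    _apply_scale(ax, scale, axis="y", label_style=label_style)
    raw_centers = np.array([g.center_fc for g in groups])
    raw_err = np.array([[g.center_fc - g.lower_fc for g in groups],
                        [g.upper_fc - g.center_fc for g in groups]])
    ax.errorbar(xs, raw_centers, yerr=raw_err, fmt="o", ms=4, capsize=3,
                color="tab:blue", ecolor="tab:blue")
    ax.set_xlabel("group")
    ax.set_ylabel(_axis_label(scale))
    fig.tight_layout()

    spec = PlotSpec(
        kind="interval", scale_name=scale,
        point_positions={"x": xs, "center": centers},
        tick_spec=_tick_spec_for(scale, np.concatenate([lowers, uppers]), label_style),
        summary_geometry={
            "lower": lowers, "upper": uppers,
            "width": uppers - lowers,
            "half_width_upper": uppers - centers,
            "half_width_lower": centers - lowers,
        },
    )
    return fig, spec


def _group_arrays(samples) -> dict[str, np.ndarray]:
    if isinstance(samples, Mapping):
        return {str(k): np.asarray(v, dtype=float) for k, v in samples.items()}
    return {f"group{i}": np.asarray(v, dtype=float) for i, v in enumerate(samples)}


def box_plot(samples, scale: str = "madfc", *, label_style: LabelStyle = "fraction"):
    """Box plots per group: quartiles raw-then-transformed, Tukey whiskers
    in display space."""
    groups = _group_arrays(samples)
    t = scale_transform(scale)
    stats_list, geometry = [], {}
    for name, vals in groups.items():
        vals = vals[np.isfinite(vals)]
        if vals.size < 5:
            raise ValueError(f"group {name!r} needs >= 5 finite values")
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        dq1, dmed, dq3 = (float(t(q1)), float(t(med)), float(t(q3)))
        disp = t(vals)
        disp = disp[np.isfinite(disp)]
        iqr = dq3 - dq1
        lo_fence, hi_fence = dq1 - 1.5 * iqr, dq3 + 1.5 * iqr
        inside = disp[(disp >= lo_fence) & (disp <= hi_fence)]
        whislo = float(inside.min()) if inside.size else dq1
        whishi = float(inside.max()) if inside.size else dq3
        fliers = disp[(disp < lo_fence) | (disp > hi_fence)]
        stats_list.append({"label": name, "q1": dq1, "med": dmed, "q3": dq3,
                           "whislo": whislo, "whishi": whishi,
                           "fliers": fliers.tolist()})
        geometry[name] = {"q1": dq1, "med": dmed, "q3": dq3,
                          "whislo": whislo, "whishi": whishi}

    fig, ax = plt.subplots(figsize=(6, 4))
    # geometry is precomputed in display space, so draw on a plain axis and
    # relabel ticks per the MAD convention instead of re-transforming.
    ax.bxp(stats_list, showfliers=True)
    all_disp = np.concatenate([[g["whislo"], g["whishi"]] for g in geometry.values()])
    tick = _tick_spec_for("madfc", all_disp, label_style) if scale == "madfc" else None
    if tick is not None:
        ax.set_yticks(tick.positions, tick.labels)
    ax.set_ylabel(_axis_label(scale))
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()

    spec = PlotSpec(
        kind="box", scale_name=scale,
        point_positions={},
        tick_spec=tick,
        summary_geometry=geometry,
    )
    return fig, spec


def violin_plot(samples, scale: str = "madfc", *,
                grid_size: int = 256, cut: float = 3.0,
                label_style: LabelStyle = "fraction"):
    """Violin plots with kernel densities estimated in display space.

    Gaussian kernel with Scott's bandwidth on the transformed values,
    evaluated on a ``grid_size``-point grid extended ``cut`` bandwidths past
    the data range.  Identical groups translated in fold-change units yield
    identical polygons up to translation under the MAD scale.
    """
    from scipy.stats import gaussian_kde

    groups = _group_arrays(samples)
    t = scale_transform(scale)
    geometry = {}
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, (name, vals) in enumerate(groups.items()):
        vals = vals[np.isfinite(vals)]
        if vals.size < 10:
            raise ValueError(f"group {name!r} needs >= 10 finite values")
        disp = t(vals)
        disp = disp[np.isfinite(disp)]
        if np.ptp(disp) == 0:
            raise ValueError(f"group {name!r} is degenerate (zero spread) in display space")
        kde = gaussian_kde(disp)  # Scott's rule by default
        bw = kde.factor * disp.std(ddof=1)
        grid = np.linspace(disp.min() - cut * bw, disp.max() + cut * bw, grid_size)
        dens = kde(grid)
        half = 0.4 * dens / dens.max()
        ax.fill_betweenx(grid, i - half, i + half, alpha=0.7)
        geometry[name] = {"grid": grid, "density": dens}

    all_disp = np.concatenate([g["grid"] for g in geometry.values()])
    tick = _tick_spec_for("madfc", all_disp, label_style) if scale == "madfc" else None
    if tick is not None:
        ax.set_yticks(tick.positions, tick.labels)
    ax.set_xticks(range(len(groups)), list(groups), rotation=90)
    ax.set_ylabel(_axis_label(scale))
    fig.tight_layout()

    spec = PlotSpec(
        kind="violin", scale_name=scale,
        point_positions={},
        tick_spec=tick,
        summary_geometry=geometry,
    )
    return fig, spec


def heatmap(matrix, spec: Optional[ColorNormSpec] = None, *,
            row_labels: Optional[Sequence[str]] = None,
            col_labels: Optional[Sequence[str]] = None,
            cmap: str = DEFAULT_CMAP,
            label_style: LabelStyle = "fraction"):
    """Heatmap of raw fold changes colored through a :class:`ColorNormSpec`.

    Default spec is data-driven symmetric MAD normalization, so no change
    sits at the palette midpoint.  The colorbar carries back-transformed
    fold-change tick labels.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        row_labels = row_labels if row_labels is not None else list(matrix.index)
        col_labels = col_labels if col_labels is not None else list(matrix.columns)
    else:
        values = np.asarray(matrix, dtype=float)
    if spec is None:
        spec = spec_from_data(values)
    normed = normalize(values, spec)

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(values, cmap=cmap, norm=MadFCNorm(spec), aspect="auto")
    if row_labels is not None:
        ax.set_yticks(range(values.shape[0]), row_labels, fontsize=7)
    if col_labels is not None:
        ax.set_xticks(range(values.shape[1]), col_labels, fontsize=8, rotation=90)

    tlo, thi = spec.display_bounds()
    cb_tick = None
    if spec.transform == "madfc":
        from .transforms import madfc_inverse
        cb_tick = make_ticks(tlo, thi, max_ticks=9, style=label_style)
        cbar = fig.colorbar(im, ax=ax)
        cbar.set_ticks([float(madfc_inverse(p)) for p in cb_tick.positions],
                       labels=list(cb_tick.labels))
        cbar.set_label("fold change")
    else:
        fig.colorbar(im, ax=ax, label="normalized fold change")
    fig.tight_layout()

    plot_spec = PlotSpec(
        kind="heatmap", scale_name=spec.transform,
        point_positions={"normalized": normed},
        tick_spec=cb_tick,
        summary_geometry={"vmin_fc": spec.vmin_fc, "vmax_fc": spec.vmax_fc,
                          "symmetric": spec.symmetric,
                          "display_bounds": [tlo, thi]},
    )
    return fig, plot_spec
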