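"""Seeded generators for the simulated datasets used across the toolkit.

Every generator is deterministic given its arguments (and seed where one
applies).  Geometric fixtures are constructed *in fold-change-unit space*
and mapped to raw fold change through the exact inverse transform, so the
intended display geometry under the MAD scale holds to machine precision:

- a dyadic ladder ``2^0 .. 2^k`` for dynamic-range illustrations;
- an integer fold-change-unit span (default -5..5, i.e. raw 1/6..6);
- interval-estimate groups with a common half-width in fold-change units;
- box-plot groups whose five-number summaries are evenly spaced in
  fold-change units, placed so order-statistic quantiles are exact;
- violin groups sharing one base sample translated in fold-change units;
- a differential-expression results table with the statistical shape of a
  DESeq2-style output (spike-and-slab log2 effects, log-normal baseline
  abundance, exact z-test p-values — hence exactly uniform null p-values —
  and Benjamini-Hochberg adjusted p-values).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import madfc_inverse

__all__ = [
    "gen_dyadic_ladder",
    "gen_fcu_span",
    "gen_interval_groups",
    "gen_box_groups",
    "gen_violin_groups",
    "gen_de_results",
]


def gen_dyadic_ladder(max_log2: int = 9) -> np.ndarray:
    """Fold changes ``2^0, 2^1, ..., 2^max_log2`` (default up to 512)."""
    if max_log2 < 0:
        raise ValueError("max_log2 must be >= 0")
    return np.exp2(np.arange(max_log2 + 1, dtype=float))


def gen_fcu_span(lo_fcu: int = -5, hi_fcu: int = 5) -> np.ndarray:
    """Raw fold changes at every integer fold-change unit in [lo, hi].

    Defaults give the eleven values 1/6, 1/5, ..., 1/2, 1, 2, ..., 6.
    """
    if lo_fcu > hi_fcu:
        raise ValueError("require lo_fcu <= hi_fcu")
    grid = np.arange(lo_fcu, hi_fcu + 1, dtype=float)
    return np.asarray(madfc_inverse(grid))


def gen_interval_groups(centers_fcu: Optional[Sequence[float]] = None,
                        half_width_fcu: float = 2.0):
    """Interval estimates with identical dispersion in fold-change units.

    One interval per center; endpoints are the exact inverse transform of
    ``center ± half_width`` so every group has the same display width under
    the MAD scale.  Defaults: 11 groups at integer centers -5..5, ±2 FCU.
    """
    from .plot_builders import IntervalEstimate  # local import; no cycle at module load

    if centers_fcu is None:
        centers_fcu = np.arange(-5, 6, dtype=float)
    if half_width_fcu < 0:
        raise ValueError("half_width_fcu must be >= 0")
    groups = []
    for c in np.asarray(centers_fcu, dtype=float):
        groups.append(IntervalEstimate(
            center_fc=float(madfc_inverse(c)),
            lower_fc=float(madfc_inverse(c - half_width_fcu)),
            upper_fc=float(madfc_inverse(c + half_width_fcu)),
        ))
    return groups


def _quantile_matched_sample(median_fcu: float, gap_fcu: float, n: int) -> np.ndarray:
    """Sample (in FCU space) whose order-statistic five-number summary is
    exactly ``median ± {0, gap, 2 gap}``.

    Requires ``n ≡ 1 (mod 4)`` so the quartile indices ``(n-1)·q`` are
    integers; values are placed piecewise-linearly between the five
    boundaries.
    """
    if n < 5 or (n - 1) % 4 != 0:
        raise ValueError("n must be >= 5 with n ≡ 1 (mod 4) for exact quartiles")
    bounds = median_fcu + gap_fcu * np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    k = (n - 1) // 4
    segs = [np.linspace(bounds[i], bounds[i + 1], k + 1)[:-1] for i in range(4)]
    return np.concatenate(segs + [bounds[-1:]])


def gen_box_groups(median_fcu_range: tuple[int, int] = (-8, 8),
                   quartile_gap_fcu: float = 2.0,
                   n_per_group: int = 5,
                   noise_sd_fcu: float = 0.0,
                   seed: Optional[int] = None) -> dict[str, np.ndarray]:
    """Box-plot groups with medians swept across fold-change units.

    Defaults sweep the median over integer FCU -8..8 (raw fold change 1/9
    to 9) with five-number summaries spaced 2 FCU apart, so each box is
    exactly symmetric in MAD display space.  Placement is deterministic
    (quantile-matched); optional Gaussian noise in FCU space is off by
    default so downstream geometry checks are exact.
    """
    lo, hi = median_fcu_range
    rng = np.random.default_rng(seed)
    groups: dict[str, np.ndarray] = {}
    for m in range(int(lo), int(hi) + 1):
        fcu = _quantile_matched_sample(float(m), quartile_gap_fcu, n_per_group)
        if noise_sd_fcu > 0:
            fcu = fcu + rng.normal(0.0, noise_sd_fcu, size=fcu.shape)
        groups[f"fcu{m:+d}"] = np.asarray(madfc_inverse(np.sort(fcu)))
    return groups


def gen_violin_groups(centers_fcu: Optional[Sequence[float]] = None,
                      shape: str = "normal",
                      scale_fcu: float = 1.0,
                      n: int = 200,
                      seed: Optional[int] = 0) -> dict[str, np.ndarray]:
    """Violin groups: one base sample translated across fold-change units.

    The base draw (standard normal truncated at ±3, scaled by
    ``scale_fcu``; or uniform on ±scale) is shared by every group and only
    translated, so under the MAD scale all groups have literally identical
    distribution shape.  Defaults: 11 groups at integer centers -5..5.
    """
    if centers_fcu is None:
        centers_fcu = np.arange(-5, 6, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if shape == "normal":
        base = stats.truncnorm.rvs(-3.0, 3.0, size=n, random_state=rng) * scale_fcu
    elif shape == "uniform":
        base = rng.uniform(-scale_fcu, scale_fcu, size=n)
    else:
        raise ValueError(f"unknown shape {shape!r}; expected 'normal' or 'uniform'")
    groups = {}
    for c in np.asarray(centers_fcu, dtype=float):
        groups[f"fcu{c:+g}"] = np.asarray(madfc_inverse(base + c))
    return groups


def gen_de_results(n_genes: int = 5000,
                   frac_null: float = 0.8,
                   effect_sd_log2: float = 1.0,
                   se_log2: float = 0.25,
                   seed: Optional[int] = 0) -> pd.DataFrame:
    """Differential-expression results table with DESeq2-like statistical shape.

    Spike-and-slab model: a ``frac_null`` fraction of genes has true log2
    effect 0, the rest draw effects from N(0, effect_sd_log2²).  Observed
    log2 fold changes add Gaussian estimation noise with known standard
    error ``se_log2``; p-values come from the exact two-sided z-test (so
    null p-values are uniform by construction) and are Benjamini-Hochberg
    adjusted.  Baseline abundance is log-normal.

    Returns the package's standardized results schema: ``feature_id``,
    ``fc``, ``log2fc``, ``pvalue``, ``padj``, ``base_mean``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= frac_null <= 1.0:
        raise ValueError("frac_null must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_null = rng.random(n_genes) < frac_null
    effect = np.where(is_null, 0.0, rng.normal(0.0, effect_sd_log2, n_genes))
    log2fc = effect + rng.normal(0.0, se_log2, n_genes)
    z = log2fc / se_log2
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = stats.false_discovery_control(pvalue, method="bh")
    base_mean = rng.lognormal(mean=4.0, sigma=1.5, size=n_genes)
    return pd.DataFrame({
        "feature_id": [f"gene{i:05d}" for i in range(n_genes)],
        "fc": np.exp2(log2fc),
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "base_mean": base_mean,
    })
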