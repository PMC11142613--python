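# madfc — mirrored-axis-distortion fold-change visualization

Differential expression and differential protein abundance are reported as
**fold changes**: positive ratios of an experiment-group mean to a
control-group mean, with FC = 1 meaning no change. Neither of the two usual
ways of plotting them is fully satisfactory. A linear axis compresses all
down-regulation into (0, 1] while up-regulation spreads over (1, ∞), so a
3-fold increase and a 3-fold decrease look nothing alike. A log2 axis is
symmetric, but distances on it are no longer proportional to effect size,
and equal uncertainty intervals render with unequal widths depending on
where they sit.

`madfc` implements the **MAD-FC** (mirrored axis distortion of fold change)
display transform, which keeps a linear axis's proportionality while
gaining log-like symmetry. It measures fold change in **fold-change units**
(FCU) — the signed number of fold changes away from no change:

```
f_U(x) = x − 1        for x ≥ 1
       = 1 − 1/x      for 0 < x < 1
```

so (2, ½, 3, ⅓) map to (1, −1, 2, −2). Equivalently, MAD-FC is a *mirror*
step f_M(x) = x for x ≥ 1, −1/x for 0 < x < 1 (reciprocal pairs become
sign-symmetric) followed by a *contraction* f_C(m) = m ∓ 1 that closes the
gap the mirror leaves on (−1, 1); the composition equals f_U exactly. Axis
tick labels are back-transformed to raw fold change (1/6, …, ½, 1, 2, …, 6),
so values are read straight off the plot: readable, proportional within each
direction, and symmetric about no change, at the cost of a linear scale's
limited (~2⁸) dynamic range.

The package provides:

- `madfc.transforms` — the transform family (forward, inverse, mirror,
  contraction, log2 conversions) with strict/propagate domain policies;
- `madfc.axis_scale` — a matplotlib scale registered as `"madfc"` with
  back-transformed tick labels in fraction, decimal, or exponent style;
- `madfc.color_norm` — diverging colormap normalization proportional to
  fold-change units and centered on no change;
- `madfc.plot_builders` — volcano, MA, interval, box, violin and heatmap
  builders, each returning a figure plus a JSON-serializable `PlotSpec` of
  computed positions, ticks and significance classes;
- `madfc.property_audit` — numeric scores for proportionality, symmetry and
  pixel-budget dynamic range of any candidate transform;
- `madfc.synthetic_data` — seeded generators for all simulated fixtures and
  a DESeq2-shaped differential-results table;
- `madfc.io` / `madfc.cli` — DESeq2-dialect table IO and a thin `madfc`
  command-line tool (`transform`, `volcano`, `ma`, `box`, `violin`,
  `heatmap`, `audit`, `simulate`).

## Worked example

```python
import numpy as np
from madfc import fold_change_units, madfc_forward, madfc_inverse

raw = np.array([2.0, 0.5, 3.0, 1/3, 1.0, 1/6, 6.0])
print(fold_change_units(raw))   # [ 1. -1.  2. -2.  0. -5.  5.]
print(madfc_forward(raw))       # identical: the mirror+contract composition
print(madfc_inverse(madfc_forward(raw)))  # round trip recovers raw
```

The values are distances from no change in whole fold changes: 2 and ½ are
both one doubling away (+1/−1), 6 and 1/6 five (+5/−5). On a MAD axis these
pairs sit mirror-symmetrically about 0 while tick labels stay in raw fold
change:

```python
import matplotlib.pyplot as plt
fig, ax = plt.subplots()
ax.set_yscale("madfc", max_ticks=11)
ax.plot(range(len(raw)), raw, "o")
ax.set_ylim(1/6, 6)
# tick labels: 1/6 1/5 1/4 1/3 1/2 1 2 3 4 5 6  at display positions -5..5
```

Auditing the three display transforms (`examples/06_property_audit.py`)
prints:

```
transform    prop(+)   prop(-)  symmetric  dyn.range
----------------------------------------------------
linear           yes        no         no        8 u
log2              no        no        yes      300 u
madfc            yes       yes        yes        8 u
```

i.e. only MAD-FC is proportional in both directions *and* symmetric; it
shares the linear axis's ~8-doubling dynamic range under a 600-px /
2-px-gap budget, while log2 is limited only by the pixel budget. The
`examples/` directory holds one short script per capability (transforms,
labeled axis, volcano/MA, interval/box/violin fixtures, heatmap, audit).

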