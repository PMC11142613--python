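# Methods

## The transform

Fold change x is a positive real ratio; FC = 1 is the point of no change.
The MAD-FC display coordinate is built from two case maps:

- mirror: f_M(x) = x for x ≥ 1, −1/x for 0 < x < 1. Reversing a fold
  change's direction is taking its reciprocal, so negating the reciprocal
  places reciprocal pairs symmetrically about zero. The range leaves a gap
  on (−1, 1).
- contraction: f_C(m) = m − 1 for m ≥ 1, m + 1 for m < −1, which closes
  the gap by sliding both branches one unit toward zero.

The composition equals the fold-change-unit encoding f_U(x) = x − 1
(x ≥ 1), 1 − 1/x (0 < x < 1): on the upper branch f_C(f_M(x)) = x − 1; on
the lower, f_C(−1/x) = −1/x + 1. The implementation keeps both routes —
`madfc_forward` as the literal composition, `fold_change_units` as the
closed form — and the test suite asserts their equality on a 10⁴-point
log-spaced grid over [2⁻¹⁰, 2¹⁰].

The inverse composes f_C⁻¹(y) = y + 1 (y ≥ 0), y − 1 (y < 0) with
f_M⁻¹(m) = m (m ≥ 1), −1/m (m < −1), i.e. y + 1 for y ≥ 0 and 1/(1 − y)
for y < 0, total on the reals. `madfc_inverse` evaluates this fused closed
form rather than the two steps literally: for denormal-small negative y,
floating-point evaluation of y − 1 rounds onto the gap boundary −1 and
would spuriously leave the inverse-mirror domain. Case boundaries follow
the half-open inequalities above (m ≥ 1, m < −1; y ≥ 0, y < 0), which
makes the forward/inverse pair exact at the point of no change:
forward(1) = 0 and inverse(0) = 1 with no tolerance.

Round-trip equality is asserted at relative 1e−12 (1/x is inexact in
binary floating point); the branch identities, the symmetry law
f(1/x) = −f(x), strict monotonicity, and continuity at x = 1 are property
tests seeded or derandomized for reproducibility.

### Domain policy

The transforms are undefined for x ≤ 0 and non-finite x. Scalar/array APIs
default to `strict` (raise, naming the offending values); table and plot
pipelines default to `propagate` (map to NaN positionally), so a single
out-of-domain feature does not abort a figure. A raw fold change of exactly
0 (complete loss) is deliberately not given a pseudocount: it errors or
propagates. Users with signed ±ratio conventions must convert to positive
ratios first; that encoding is out of scope.

## The axis scale

`"madfc"` is a registered matplotlib scale: data maps through the forward
transform, cursor readback through the inverse, and nonpositive data is
masked. Tick candidates sit at every integer fold-change-unit position in
the view interval. When candidates exceed `max_ticks` they are thinned to
multiples of the smallest integer stride that fits — chosen because
multiples of any stride always retain position 0 (the no-change anchor,
labeled "1") when it is in range. Ranges containing fewer than three
integer positions fall back to five evenly spaced positions with decimal
labels, snapping one to the anchor when it is in range; this covers data
confined within one fold-change unit of no change, where integer ticks
alone would be a single tick or none.

Labels are the inverse transform of each position rendered as fractions
("1/k", ASCII, for portability), decimals, or exponents ("b^p", base
configurable, default 2; exact integer powers only, else decimal
fallback). `TickSpec` labels carry 12 significant digits so that parsing
any label and re-transforming reproduces the tick position to 1e−9 — the
readability contract made numeric — while the on-screen formatter renders
a friendlier 4-significant-digit form. The default formatter always
back-transforms: a raw MAD axis (transform-space labels) is never produced,
because unlike log axes there is no extraction/conversion trade-off to
justify one. Dual inner/outer axis rendering is likewise excluded.

## Color normalization

Fold change maps to [0, 1] by applying the chosen transform (linear, log2,
or MAD) and rescaling linearly between transformed bounds. With
`symmetric=True` the bounds become c ± max(|t(vmin) − c|, |t(vmax) − c|)
where c = t(1) is the transform's own point of no change (0 for log2/MAD,
1 for linear). Centering on c rather than on 0 unconditionally keeps the
invariant "FC = 1 maps to 0.5" true for all three transforms, including
linear; for log2 and MAD, where c = 0, this reduces to the plain ±max
form. Out-of-range values clip rather than error, since real heatmaps
contain outliers. Default bounds are data-driven (the extreme observed
fold changes) with symmetry on; the default palette is a blue–white–red
diverging map, a configuration choice with no scientific content.
Perceptual color modeling is out of scope.

## Plot builders

Every builder returns the figure and a `PlotSpec` record of the computed
geometry, so tests assert numbers, not pixels.

- Volcano / MA: x (or y) is the chosen transform of fold change; the other
  axis is −log10 p (clipped at 1e−300) or log10(baseMean + 0.5), the
  pseudocount configurable because zero counts occur. Significance calls
  (Up/Down/NS) require adjusted p < 0.1 *and* |log2 FC| > 1 by default.
  The magnitude threshold's units are ambiguous in common usage, so the
  reading is switchable (`log2` per the volcano-tool convention, or `fcu`);
  classification never depends on the display scale. Missing per-row
  adjusted p ⇒ NS; a table with no adjusted-p column falls back to raw
  p-values with a warning, since many public tables omit it.
- Intervals: endpoints are transformed, never widths. Under MAD a
  half-width of h fold-change units renders with display half-width exactly
  h, which is the transform's selling point for uncertainty display.
- Boxes: quartiles are computed on raw fold changes with numpy's default
  linear (order-statistic) interpolation and then transformed — legitimate
  because monotone transforms commute with such quantiles, which is itself
  a tested invariant. Whiskers use Tukey's 1.5·IQR rule *in display
  space*, matching what mainstream boxplot implementations would draw on
  that axis.
- Violins: kernel densities are estimated in display space (Gaussian
  kernel, Scott's bandwidth, 256-point grid extended 3 bandwidths past the
  data), because densities do not commute with monotone transforms. Scott
  bandwidth is translation-invariant, so groups identical up to an FCU
  translation produce literally identical polygons under MAD. Degenerate
  (zero-spread or < 10-point) groups raise.
- Heatmaps: cells color through the normalization above; the colorbar
  carries back-transformed fold-change labels from the same tick builder.
- Rendering is deterministic: no jitter anywhere.

## Property audit

`property_audit` scores any strictly increasing display transform:

- Proportionality per direction: the line through (0, c) and the extreme
  probe's (FCU, display) point is the proportional ideal; the score is the
  maximum residual normalized by the branch's display span. Normalization
  makes scores invariant to affine rescaling of the transform.
- Symmetry: max over magnitudes m > 1 of the mismatch between the display
  distances of m and 1/m from c, normalized by the probe set's display span.
- Dynamic range: the largest k such that the ladder 2⁰..2^k, transformed
  and scaled linearly onto `axis_px` pixels, keeps adjacent points at least
  `min_gap_px` apart. Defaults 600 px and 2 px are one operationalization
  of "typically distinguishable"; real limits depend on resolution,
  compression, acuity and viewing distance, so the resulting 8 log2 units
  for a linear axis is an anchor, not a constant of nature.

Pass thresholds for proportionality and symmetry are 1e−9 of display span:
transforms satisfying the law exactly pass at float precision, while
violations by linear (asymmetry, negative-branch curvature) and log2
(curvature in both branches) are orders of magnitude larger, so the
verdict is insensitive to the exact tolerance. Default probes are the
integer-FCU grid −5..5. Readability is deliberately not scored here: it is
a statement about label semantics, enforced as the axis-scale readback
contract.

## Synthetic data

Generators are deterministic given arguments and seed; geometric fixtures
are built in FCU space and mapped through the exact inverse, so MAD display
geometry is exact to machine precision.

- Dyadic ladder 2⁰..2⁹ (dynamic-range illustration).
- FCU span: integer units −5..5, raw 1/6..6.
- Interval groups: 11 groups at integer FCU centers −5..5, half-width
  2 FCU. Captions of the figures being emulated state the dispersion but
  not the group count; 11 integer centers are a declared default, not an
  inference, and are overridable.
- Box groups: medians at integer FCU −8..8 (raw 1/9..9), five-number
  summary spaced 2 FCU. The spacing is read as quartile *boundaries* 2 FCU
  apart; the alternative (2 raw-FC spacing) would contradict the intended
  symmetry in MAD space. Samples need n ≡ 1 (mod 4) so order-statistic
  quantile indices are integers; values are placed piecewise-linearly
  between boundaries, making quantiles exact with no randomness (noise is
  available but off by default so geometry checks are exact).
- Violin groups: one base draw (standard normal truncated at ±3, scaled in
  FCU) shared by all groups and translated — the strongest version of
  "identical dispersion", making shape identity under MAD exact rather
  than approximate.
- DE results: spike-and-slab log2 effects (default 80% null — a typical
  order for genome-wide contrasts — slab sd 1 log2 unit), estimation noise
  with known SE 0.25, exact two-sided z-test p-values (null p-values
  therefore exactly uniform), Benjamini–Hochberg adjustment
  (`scipy.stats.false_discovery_control`), log-normal baseline abundance.
  This emulates only the *statistical shape* of a DESeq2 results table —
  schema, null uniformity, FDR behavior. It does not model counts,
  dispersion–mean trends, shrinkage, independent filtering, or correlated
  genes; tests passing on it validate the visualization pipeline, not any
  claim about real RNA-seq data, whose public datasets are intentionally
  not downloaded or reproduced here.

## Problem sizes

Default test and acceptance runs use the fixture sizes above, a 10⁴-point
transform grid, 10⁴ random symmetry probes, and DE tables of 400–5000
genes — sizes at which every deterministic check is exact and the
stochastic checks (KS uniformity at α = 0.01, FDR within 3 standard errors
of the Benjamini–Hochberg bound) are stable across seeds.

## Known limitations

- Dynamic range shares a linear axis's limits: data spanning much more
  than ~8 log2 units compresses onto the no-change region; a log axis
  serves such data better.
- The audit requires strictly increasing transforms; direction-reversing
  or non-monotone encodings are rejected rather than scored.
- Sub-unit tick fallback uses decimal labels only; no minor ticks are
  generated between fold-change units.
- `MadFCNorm.inverse` exists for colorbar machinery; clipped values are
  not recoverable (clipping is lossy by design).
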