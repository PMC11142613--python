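"""Numeric audits of fold-change visualization properties.

Scores any candidate display transform of fold change on three of the four
properties a fold-change visualization should have:

proportionality
    Within each direction of change, display distance from the point of no
    change should be linear in fold-change units.  Scored as the maximum
    residual from the line joining the point of no change to the most
    extreme probe of that direction, normalized by the branch's display
    span.

symmetry
    A fold change m and its reciprocal 1/m should be equidistant from the
    point of no change.  Scored as the maximum distance mismatch over a set
    of magnitudes, normalized by the display span of the probe set.

dynamic range
    How many doublings stay visually separable in a fixed pixel budget:
    the largest k such that the ladder 2^0 .. 2^k, mapped through the
    transform and scaled linearly onto ``axis_px`` pixels, keeps every
    adjacent pair at least ``min_gap_px`` apart.  Reported in log2 units.

The fourth property, readability, is about label semantics rather than
geometry; it is enforced by the axis machinery's label-readback contract
and deliberately has no numeric score here.

The expected verdict pattern for the three stock transforms: linear is
proportional on the positive branch only and asymmetric; log2 is symmetric
but proportional on neither branch; MAD is proportional and symmetric on
both; log2's dynamic range exceeds linear's, which matches MAD's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .synthetic_data import gen_fcu_span
from .transforms import fc_to_log2, fold_change_units, madfc_forward

__all__ = [
    "TransformUnderTest",
    "AuditReport",
    "BUILTIN_TRANSFORMS",
    "assess_proportionality",
    "assess_symmetry",
    "estimate_dynamic_range",
    "audit",
    "audit_builtins",
    "format_report",
]

#: score below which an exact-law transform is declared to satisfy a property
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class TransformUnderTest:
    """A display transform of raw fold change to be audited.

    ``point_of_no_change_display`` is the display value of FC = 1
    (0 for log2 and MAD, 1 for linear).
    """

    name: str
    forward: Callable
    point_of_no_change_display: float


def _builtin(name: str) -> TransformUnderTest:
    if name == "linear":
        return TransformUnderTest("linear", lambda x: np.asarray(x, dtype=float), 1.0)
    if name == "log2":
        return TransformUnderTest(
            "log2", lambda x: np.asarray(fc_to_log2(x, policy="propagate")), 0.0)
    if name == "madfc":
        return TransformUnderTest(
            "madfc", lambda x: np.asarray(madfc_forward(x, policy="propagate")), 0.0)
    raise ValueError(f"unknown transform {name!r}")


BUILTIN_TRANSFORMS = tuple(_builtin(n) for n in ("linear", "log2", "madfc"))


@dataclass
class AuditReport:
    """Numeric scores plus pass/fail verdicts for one transform."""

    name: str
    proportionality_max_residual_pos: float
    proportionality_max_residual_neg: float
    symmetry_max_deviation: float
    dynamic_range_log2_units: int
    tolerance: float = DEFAULT_TOL
    verdicts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.verdicts = {
            "proportional_pos": self.proportionality_max_residual_pos <= self.tolerance,
            "proportional_neg": self.proportionality_max_residual_neg <= self.tolerance,
            "symmetric": self.symmetry_max_deviation <= self.tolerance,
        }
        self.verdicts["proportional"] = (self.verdicts["proportional_pos"]
                                         and self.verdicts["proportional_neg"])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "proportionality_max_residual_pos": self.proportionality_max_residual_pos,
            "proportionality_max_residual_neg": self.proportionality_max_residual_neg,
            "symmetry_max_deviation": self.symmetry_max_deviation,
            "dynamic_range_log2_units": self.dynamic_range_log2_units,
            "tolerance": self.tolerance,
            "verdicts": dict(self.verdicts),
        }


def _check_monotone(t: TransformUnderTest, probes: np.ndarray) -> None:
    vals = np.asarray(t.forward(np.sort(probes)), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"transform {t.name!r} is undefined on the probe grid")
    if not np.all(np.diff(vals) > 0):
        raise ValueError(f"transform {t.name!r} is not strictly increasing on the probe grid")


def assess_proportionality(t: TransformUnderTest,
                           probe_fcs: Sequence[float]) -> tuple[float, float]:
    """Max residual from the no-change-to-extreme line, per direction.

    Requires at least three probes on each side of FC = 1.  Residuals are
    normalized by each branch's display span, making the score invariant to
    affine rescaling of the transform.
    """
    probes = np.asarray(probe_fcs, dtype=float)
    pos = probes[probes > 1.0]
    neg = probes[(probes > 0.0) & (probes < 1.0)]
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need >= 3 probe fold changes on each side of 1")
    _check_monotone(t, probes)
    c = t.point_of_no_change_display

    def branch_residual(branch: np.ndarray) -> float:
        fcu = np.asarray(fold_change_units(branch))
        disp = np.asarray(t.forward(branch), dtype=float)
        i_ext = np.argmax(np.abs(fcu))
        span = abs(disp[i_ext] - c)
        slope = (disp[i_ext] - c) / fcu[i_ext]
        line = c + slope * fcu
        return float(np.max(np.abs(disp - line)) / span)

    return branch_residual(pos), branch_residual(neg)


def assess_symmetry(t: TransformUnderTest,
                    magnitudes: Sequence[float]) -> float:
    """Max mismatch between distances of m and 1/m from the point of no change."""
    mags = np.asarray(magnitudes, dtype=float)
    if (mags <= 1.0).any():
        raise ValueError("magnitudes must all exceed 1")
    c = t.point_of_no_change_display
    up = np.abs(np.asarray(t.forward(mags), dtype=float) - c)
    down = np.abs(np.asarray(t.forward(1.0 / mags), dtype=float) - c)
    all_disp = np.concatenate([np.asarray(t.forward(mags), dtype=float),
                               np.asarray(t.forward(1.0 / mags), dtype=float),
                               [c]])
    span = float(all_disp.max() - all_disp.min())
    return float(np.max(np.abs(up - down)) / span)


def estimate_dynamic_range(t: TransformUnderTest, axis_px: int = 600,
                           min_gap_px: int = 2, max_log2: int = 512) -> int:
    """Largest k with all adjacent pairs of 2^0..2^k separable on screen.

    The ladder is transformed, linearly scaled to span ``axis_px`` pixels,
    and each adjacent gap checked against ``min_gap_px``.
    """
    if not axis_px > min_gap_px > 0:
        raise ValueError("require axis_px > min_gap_px > 0")
    best = 0
    for k in range(1, max_log2 + 1):
        ladder = np.exp2(np.arange(k + 1, dtype=float))
        disp = np.asarray(t.forward(ladder), dtype=float)
        if not np.all(np.isfinite(disp)):
            break
        span = disp[-1] - disp[0]
        if span <= 0:
            break
        gaps = np.diff(disp) / span * axis_px
        if np.all(gaps >= min_gap_px):
            best = k
        else:
            break
    return best


def audit(t: TransformUnderTest,
          probe_fcs: Optional[Sequence[float]] = None,
          magnitudes: Optional[Sequence[float]] = None,
          axis_px: int = 600, min_gap_px: int = 2,
          tolerance: float = DEFAULT_TOL) -> AuditReport:
    """Run all three assessments for one transform.

    Default probes: the integer fold-change-unit grid -5..5 (raw fold
    change 1/6..6); default symmetry magnitudes are the positive probes.
    """
    if probe_fcs is None:
        probe_fcs = gen_fcu_span(-5, 5)
    probes = np.asarray(probe_fcs, dtype=float)
    if magnitudes is None:
        magnitudes = probes[probes > 1.0]
    res_pos, res_neg = assess_proportionality(t, probes)
    sym = assess_symmetry(t, magnitudes)
    dr = estimate_dynamic_range(t, axis_px=axis_px, min_gap_px=min_gap_px)
    return AuditReport(
        name=t.name,
        proportionality_max_residual_pos=res_pos,
        proportionality_max_residual_neg=res_neg,
        symmetry_max_deviation=sym,
        dynamic_range_log2_units=dr,
        tolerance=tolerance,
    )


def audit_builtins(**kwargs) -> dict[str, AuditReport]:
    """Audit the three stock transforms (linear, log2, madfc)."""
    return {t.name: audit(t, **kwargs) for t in BUILTIN_TRANSFORMS}


def format_report(reports: dict[str, AuditReport]) -> str:
    """Render audit verdicts as a text table (one row per transform)."""
    header = (f"{'transform':<10} {'prop(+)':>9} {'prop(-)':>9} "
              f"{'symmetric':>10} {'dyn.range':>10}")
    lines = [header, "-" * len(header)]
    for name, r in reports.items():
        mark = lambda ok: "yes" if ok else "no"
        lines.append(
            f"{name:<10} {mark(r.verdicts['proportional_pos']):>9} "
            f"{mark(r.verdicts['proportional_neg']):>9} "
            f"{mark(r.verdicts['symmetric']):>10} "
            f"{r.dynamic_range_log2_units:>8} u")
    lines.append("(dyn.range in log2 units; readability is a label contract, not a score)")
    return "\n".join(lines)
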