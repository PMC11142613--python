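"""The MAD-FC transform family.

A *fold change* is a positive real ratio (experiment mean / control mean);
FC = 1 means no change.  Three equivalent views of the same quantity appear
throughout this package:

``fold_change_units``
    The linear encoding of fold change as a signed distance from the point
    of no change: ``x - 1`` for ``x >= 1`` and ``1 - 1/x`` for ``0 < x < 1``.
    Raw fold changes (2, 1/2, 3, 1/3) map to (1, -1, 2, -2) fold change
    units (FCU).

``mirror`` then ``contract``
    The MAD-FC (mirrored axis distortion) transform proper.  The mirror
    step replaces each sub-unit fold change by the negated reciprocal,
    ``-1/x``, so reciprocal pairs become sign-symmetric; its range leaves a
    gap on ``(-1, 1)``.  The contraction step then translates both branches
    one unit toward zero, closing the gap.  The composition is numerically
    identical to ``fold_change_units`` — a provable identity that the test
    suite exercises on dense grids.

``madfc_inverse``
    The exact two-sided inverse, defined on all reals: ``y + 1`` for
    ``y >= 0`` and ``1 / (1 - y)`` for ``y < 0``.

All operations accept scalars or 1-D array-likes and preserve shape.
Out-of-domain inputs (``x <= 0``, NaN, infinities) are governed by a
*domain policy*: ``"strict"`` raises :class:`FoldChangeDomainError` naming
the offending values, ``"propagate"`` maps them to NaN positionally so one
bad feature does not abort a whole-table pipeline.
"""

from __future__ import annotations

from typing import Literal, Union

import numpy as np

__all__ = [
    "FoldChangeDomainError",
    "DomainPolicy",
    "fold_change_units",
    "mirror",
    "contract",
    "madfc_forward",
    "contract_inverse",
    "mirror_inverse",
    "madfc_inverse",
    "log2_to_fc",
    "fc_to_log2",
]

DomainPolicy = Literal["strict", "propagate"]

ArrayLike = Union[float, int, "np.ndarray", list, tuple]


class FoldChangeDomainError(ValueError):
    """An input lies outside the domain of a fold-change transform."""


def _as_array(x: ArrayLike) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    return np.atleast_1d(arr), scalar


def _finish(out: np.ndarray, scalar: bool):
    return float(out[0]) if scalar else out


def _check_policy(policy: str) -> None:
    if policy not in ("strict", "propagate"):
        raise ValueError(f"unknown domain policy {policy!r}; use 'strict' or 'propagate'")


def _handle_bad(arr: np.ndarray, bad: np.ndarray, policy: DomainPolicy, opname: str,
                reason: str) -> None:
    if policy == "strict" and bad.any():
        offending = arr[bad]
        shown = ", ".join(repr(float(v)) for v in offending[:5])
        more = "" if offending.size <= 5 else f" (and {offending.size - 5} more)"
        raise FoldChangeDomainError(
            f"{opname}: {reason}; offending value(s): {shown}{more}"
        )


def fold_change_units(x: ArrayLike, policy: DomainPolicy = "strict"):
    """Encode raw fold change as signed fold-change units.

    Returns ``x - 1`` for ``x >= 1`` and ``1 - 1/x`` for ``0 < x < 1``;
    zero exactly at the point of no change (``x = 1``).
    """
    _check_policy(policy)
    arr, scalar = _as_array(x)
    bad = ~np.isfinite(arr) | (arr <= 0)
    _handle_bad(arr, bad, policy, "fold_change_units", "fold change must be a positive finite ratio")
    safe = np.where(bad, 1.0, arr)
    out = np.where(safe >= 1.0, safe - 1.0, 1.0 - 1.0 / safe)
    out[bad] = np.nan
    return _finish(out, scalar)


def mirror(x: ArrayLike, policy: DomainPolicy = "strict"):
    """Mirror transform: identity on ``x >= 1``, ``-1/x`` on ``0 < x < 1``.

    Stretches sub-unit fold changes so reciprocal pairs sit symmetrically
    about zero; the range is ``(-inf, -1) ∪ [1, inf)``.
    """
    _check_policy(policy)
    arr, scalar = _as_array(x)
    bad = ~np.isfinite(arr) | (arr <= 0)
    _handle_bad(arr, bad, policy, "mirror", "fold change must be a positive finite ratio")
    safe = np.where(bad, 1.0, arr)
    out = np.where(safe >= 1.0, safe, -1.0 / safe)
    out[bad] = np.nan
    return _finish(out, scalar)


def contract(m: ArrayLike, policy: DomainPolicy = "strict"):
    """Contraction transform: ``m - 1`` for ``m >= 1``, ``m + 1`` for ``m < -1``.

    Translates both mirrored branches one unit toward zero, closing the
    ``[-1, 1)`` gap the mirror transform leaves.  Values inside that gap are
    out of domain.
    """
    _check_policy(policy)
    arr, scalar = _as_array(m)
    bad = ~np.isfinite(arr) | ((arr >= -1.0) & (arr < 1.0))
    _handle_bad(arr, bad, policy, "contract", "value lies in the undefined region [-1, 1)")
    safe = np.where(bad, 1.0, arr)
    out = np.where(safe >= 1.0, safe - 1.0, safe + 1.0)
    out[bad] = np.nan
    return _finish(out, scalar)


def madfc_forward(x: ArrayLike, policy: DomainPolicy = "strict"):
    """The MAD-FC transform: contraction composed with mirror.

    Continuous, strictly increasing on ``(0, inf)``, zero at ``x = 1``,
    and numerically equal to :func:`fold_change_units` everywhere.
    """
    return contract(mirror(x, policy=policy), policy=policy)


def contract_inverse(y: ArrayLike):
    """Inverse contraction: ``y + 1`` for ``y >= 0``, ``y - 1`` for ``y < 0``.

    Defined on all reals; moves the point of no change from 0 back to 1.
    """
    arr, scalar = _as_array(y)
    out = np.where(arr >= 0.0, arr + 1.0, arr - 1.0)
    out[~np.isfinite(arr)] = np.nan
    return _finish(out, scalar)


def mirror_inverse(m: ArrayLike, policy: DomainPolicy = "strict"):
    """Inverse mirror: identity on ``m >= 1``, ``-1/m`` on ``m < -1``."""
    _check_policy(policy)
    arr, scalar = _as_array(m)
    bad = ~np.isfinite(arr) | ((arr >= -1.0) & (arr < 1.0))
    _handle_bad(arr, bad, policy, "mirror_inverse", "value lies in the undefined region [-1, 1)")
    safe = np.where(bad, 1.0, arr)
    out = np.where(safe >= 1.0, safe, -1.0 / safe)
    out[bad] = np.nan
    return _finish(out, scalar)


def madfc_inverse(y: ArrayLike):
    """Exact inverse of :func:`madfc_forward`, defined on all reals.

    ``y + 1`` for ``y >= 0``; ``1 / (1 - y)`` for ``y < 0``.  Maps display
    coordinates (equivalently, fold-change units) back to raw fold change.
    """
    arr, scalar = _as_array(y)
    finite = np.isfinite(arr)
    safe = np.where(finite, arr, 0.0)
    # closed form of mirror_inverse(contract_inverse(y)); evaluating the
    # composition literally can round y - 1 onto the gap boundary -1 for
    # denormal-small negative y, so fold the two branch cases directly
    with np.errstate(divide="ignore"):  # np.where evaluates both branches
        out = np.where(safe >= 0.0, safe + 1.0, 1.0 / (1.0 - safe))
    out[~finite] = np.nan
    return _finish(out, scalar)


def log2_to_fc(l: ArrayLike):
    """Convert log2 fold change to raw fold change, ``2**l``."""
    arr, scalar = _as_array(l)
    out = np.exp2(arr)
    return _finish(out, scalar)


def fc_to_log2(x: ArrayLike, policy: DomainPolicy = "strict"):
    """Convert raw fold change to log2 fold change; domain ``x > 0``."""
    _check_policy(policy)
    arr, scalar = _as_array(x)
    bad = ~np.isfinite(arr) | (arr <= 0)
    _handle_bad(arr, bad, policy, "fc_to_log2", "fold change must be a positive finite ratio")
    safe = np.where(bad, 1.0, arr)
    out = np.log2(safe)
    out[bad] = np.nan
    return _finish(out, scalar)
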