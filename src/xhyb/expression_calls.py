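"""Expressed-gene calling from the ranked relative-expression curve.

Background noise makes it unclear which summarized intensities correspond to
transcribed genes.  Expression is first rescaled so that 1.0 equals the
array average; the per-set relative values, ranked in descending order,
typically follow a sigmoid-like curve whose long plateau corresponds to
genuinely expressed genes.  The cutoff is placed where the declining
gradient of the (smoothed) curve is at its shallowest — the end of the
plateau — restricted to an interior band of ranks so the tails cannot
dominate.  Sets at or above the cutoff value are called expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chipmodel import ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class ExpressedCallResult:
    """Expressed probe sets plus the cutoff that produced them.

    ``cutoff_relative_value`` is on the relative-expression scale (1.0 =
    array average); ``cutoff_rank_fraction`` is the position of the cutoff
    on the descending ranked curve as a fraction of all sets.
    """

    cutoff_relative_value: float
    cutoff_rank_fraction: float
    expressed_sets: frozenset
    smoothing_window: int
    relative_values: pd.Series

    @property
    def n_expressed(self) -> int:
        return len(self.expressed_sets)


def relative_expression(expr: ExpressionMatrix, samples=None) -> pd.Series:
    """Per-set mean over ``samples`` divided by the grand mean (output mean 1)."""
    cols = list(expr.sample_ids) if samples is None else list(samples)
    if not cols:
        raise ValidationError("sample subset must be non-empty")
    missing = set(cols) - set(expr.sample_ids)
    if missing:
        raise ValidationError(f"samples {sorted(missing)} absent from matrix")
    per_set = expr.values[cols].mean(axis=1)
    grand = per_set.mean()
    if grand <= 0:
        raise ValidationError(
            f"grand mean expression is {grand:.4g}; relative scaling undefined"
        )
    return per_set / grand


def find_inflection(
    values: pd.Series | np.ndarray,
    smoothing_window: int = 51,
    interior: tuple[float, float] = (0.1, 0.9),
) -> tuple[float, float]:
    """Locate the shallowest-gradient point of the descending ranked curve.

    The values are sorted in descending order, smoothed by a centred moving
    average of width ``smoothing_window``, and differenced; the returned
    cutoff is the interior rank (as a fraction) where the absolute gradient
    is smallest, together with the smoothed curve value there.  Exact
    gradient ties resolve to the smallest rank (the most stringent cutoff).
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    n = len(v)
    if smoothing_window < 1:
        raise ValidationError("smoothing_window must be >= 1")
    if n < 3 * smoothing_window:
        raise ValidationError(
            f"need at least {3 * smoothing_window} values, got {n}"
        )
    lo, hi = interior
    if not 0.0 <= lo < hi <= 1.0:
        raise ValidationError("interior band must satisfy 0 <= lo < hi <= 1")
    smooth = _moving_average(v, smoothing_window)
    grad = np.diff(smooth)
    i_lo = int(np.ceil(lo * len(grad)))
    i_hi = max(i_lo + 1, int(np.floor(hi * len(grad))))
    band = np.abs(grad[i_lo:i_hi])
    best = i_lo + int(np.argmin(band))  # argmin takes the first minimum
    return best / n, float(smooth[best])


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return v.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.r_[np.full(pad, v[0]), v, np.full(window - 1 - pad, v[-1])]
    return np.convolve(padded, kernel, mode="valid")


def call_expressed(
    expr: ExpressionMatrix,
    samples=None,
    override_cutoff: float | None = None,
    smoothing_window: int = 51,
    interior: tuple[float, float] = (0.1, 0.9),
) -> ExpressedCallResult:
    """Call expressed probe sets; cutoff found from the curve or overridden.

    ``override_cutoff`` is on the relative-expression scale (e.g. 0.97, just
    under the array average).  Sets with relative value >= cutoff are
    expressed.
    """
    rel = relative_expression(expr, samples)
    if override_cutoff is None:
        frac, cutoff = find_inflection(rel, smoothing_window, interior)
    else:
        cutoff = float(override_cutoff)
        if not rel.min() <= cutoff <= rel.max():
            warnings.warn(
                f"override cutoff {cutoff:.4g} lies outside the observed "
                f"relative-value range [{rel.min():.4g}, {rel.max():.4g}]",
                stacklevel=2,
            )
        frac = float((rel >= cutoff).mean())
    expressed = frozenset(rel.index[rel >= cutoff])
    return ExpressedCallResult(
        cutoff_relative_value=float(cutoff),
        cutoff_rank_fraction=float(frac),
        expressed_sets=expressed,
        smoothing_window=smoothing_window,
        relative_values=rel,
    )
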