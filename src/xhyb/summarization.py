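"""Masked RMA-style summarization.

Pipeline: restrict the probe-level matrix to the pairs retained by a
genotype's gDNA mask, log2-transform, quantile-normalize across
hybridisations, and summarize each probe set into one value per sample by
Tukey median polish of the probe x sample submatrix (summary = overall +
column effect).  Multiplicative probe affinities become additive row
effects after the log transform and are absorbed by the polish.

The classical convolution (normal + exponential) background-correction
step is deliberately a no-op hook here: the probe model has no optical
background component on binding probes, and masking itself removes the
background-dominated non-binding probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chipmodel import (
    ChipLayout,
    ExpressionMatrix,
    ProbeIntensityMatrix,
    ValidationError,
)
from .masking import ProbeMask


@dataclass
class SummarizationConfig:
    max_polish_iterations: int = 10
    polish_tolerance: float = 0.01  # on the change of total absolute residual
    normalize: bool = True
    normalize_before_mask: bool = False  # normalize over all probes, then mask

    def __post_init__(self) -> None:
        if self.max_polish_iterations < 1:
            raise ValidationError("max_polish_iterations must be >= 1")
        if self.polish_tolerance <= 0:
            raise ValidationError("polish_tolerance must be > 0")


def background_correct(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hook for probe-level background correction; identity by default."""
    return matrix


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the per-rank cross-column mean distribution.

    After normalization all columns share one sorted value multiset and
    within-column rank order is preserved.  Ties within a column receive the
    mean of the reference values at their tied ranks.  A single-column
    matrix is returned unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn(
            "quantile normalization needs >= 2 columns; returning input unchanged",
            stacklevel=2,
        )
        return matrix.copy()
    arr = matrix.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = _map_to_reference(arr[:, j], reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _map_to_reference(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    mapped = reference.copy()
    # average the reference over runs of tied input values
    starts = np.flatnonzero(np.r_[True, np.diff(xs) != 0])
    if len(starts) < len(xs):
        sums = np.add.reduceat(reference, starts)
        lengths = np.diff(np.r_[starts, len(xs)])
        means = sums / lengths
        mapped = np.repeat(means, lengths)
    out = np.empty_like(x)
    out[order] = mapped
    return out


def median_polish(
    submatrix: np.ndarray, config: SummarizationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fit overall + probe + sample effects by alternating median sweeps.

    Returns ``(summary, residuals)`` where ``summary = overall + column
    effect`` is the per-sample expression estimate.  Exact on additive
    matrices; robust to isolated outlier cells otherwise.
    """
    if config is None:
        config = SummarizationConfig()
    z = np.asarray(submatrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValidationError("median polish needs a non-empty 2-D matrix")
    resid = z.copy()
    overall = 0.0
    row = np.zeros(z.shape[0])
    col = np.zeros(z.shape[1])
    total = np.abs(resid).sum()
    for _ in range(config.max_polish_iterations):
        rdelta = np.median(resid, axis=1)
        resid -= rdelta[:, None]
        row += rdelta
        cmed = np.median(col)
        col -= cmed
        overall += cmed
        cdelta = np.median(resid, axis=0)
        resid -= cdelta[None, :]
        col += cdelta
        rmed = np.median(row)
        row -= rmed
        overall += rmed
        new_total = np.abs(resid).sum()
        if abs(total - new_total) < config.polish_tolerance or new_total == 0.0:
            break
        total = new_total
    return overall + col, resid


def rma_summarize(
    intensities: ProbeIntensityMatrix,
    mask: ProbeMask,
    layout: ChipLayout,
    config: SummarizationConfig | None = None,
) -> ExpressionMatrix:
    """Masked RMA: restrict -> log2 -> quantile normalize -> median polish.

    The output has exactly the mask's retained probe sets as rows (sorted)
    and the input hybridisations as columns.
    """
    if config is None:
        config = SummarizationConfig()
    table = layout.table
    keep = table["probe_id"].isin(mask.retained_pairs) & table[
        "probe_set_id"
    ].isin(mask.retained_sets)
    kept = table.loc[keep]
    present = intensities.values.index
    missing_sets = mask.retained_sets - set(
        kept.loc[kept["probe_id"].isin(present), "probe_set_id"]
    )
    if missing_sets:
        raise ValidationError(
            f"retained probe set {sorted(missing_sets)[0]!r} has no probes "
            "in the intensity matrix"
        )

    log2_all = np.log2(intensities.values)
    if config.normalize and config.normalize_before_mask:
        log2_all = quantile_normalize(log2_all)
    sub = log2_all.loc[kept["probe_id"]]
    sub = background_correct(sub)
    if config.normalize and not config.normalize_before_mask:
        sub = quantile_normalize(sub)

    arr = sub.to_numpy()
    set_ids = kept["probe_set_id"].to_numpy()
    order = np.argsort(set_ids, kind="mergesort")
    arr = arr[order]
    set_ids = set_ids[order]
    starts = np.flatnonzero(np.r_[True, set_ids[1:] != set_ids[:-1]])
    bounds = np.r_[starts, len(set_ids)]

    out_sets = set_ids[starts]
    out = np.empty((len(out_sets), arr.shape[1]))
    for i in range(len(out_sets)):
        block = arr[bounds[i] : bounds[i + 1]]
        out[i], _ = median_polish(block, config)
    values = pd.DataFrame(
        out, index=pd.Index(out_sets, name="probe_set_id"), columns=sub.columns
    )
    return ExpressionMatrix(values)
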