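"""Scaling and gene selection applied before clustering and display.

Row scaling (subtract the row mean, divide by the sample standard
deviation) is the default, inherited from the base-R heatmap behaviour
this toolkit stays compatible with; selection of the most variable genes
keeps the N rows with the largest sample standard deviation.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np

from .io import ComputationError, ExpressionMatrix, InputError

logger = logging.getLogger("heatclust")

ScaleMode = Literal["none", "row", "column"]
SCALE_MODES = ("none", "row", "column")


def row_sd(v: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator), missing values excluded.

    Requires at least two finite values.
    """
    v = np.asarray(v, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise ComputationError(
            f"standard deviation needs >=2 finite values, got {finite.size}"
        )
    return float(np.std(finite, ddof=1))


def _row_sds(values: np.ndarray, strict: bool) -> np.ndarray:
    """Per-row sample sd with listwise missing exclusion; NaN rows rejected."""
    n_missing = int(np.isnan(values).sum())
    if n_missing and strict:
        raise InputError(f"{n_missing} missing values present and strict mode is on")
    if n_missing:
        logger.info("sd computation excluding %d missing values", n_missing)
    counts = np.isfinite(values).sum(axis=1)
    bad = np.where(counts < 2)[0]
    if bad.size:
        raise ComputationError(
            f"rows with <2 finite values cannot be ranked by sd: indices {bad.tolist()}"
        )
    return np.asarray(np.nanstd(values, axis=1, ddof=1), dtype=float)


def scale_matrix(m: ExpressionMatrix, mode: ScaleMode = "row",
                 strict: bool = False) -> ExpressionMatrix:
    """Center and scale rows or columns to mean 0, sample sd 1.

    ``mode='none'`` returns the input unchanged.  A zero-variance vector is
    scaled to all zeros (with a warning) so constant genes render as the
    midpoint colour instead of aborting the run; an all-missing vector is an
    error naming it.
    """
    if mode not in SCALE_MODES:
        raise InputError(f"unknown scale mode {mode!r}")
    if mode == "none":
        return m
    values = m.values.copy()
    axis = 1 if mode == "row" else 0
    labels = m.row_labels if mode == "row" else m.col_labels
    n_missing = int(np.isnan(values).sum())
    if n_missing and strict:
        raise InputError(f"{n_missing} missing values present and strict mode is on")

    finite_counts = np.isfinite(values).sum(axis=axis)
    if (finite_counts == 0).any():
        bad = [labels[i] for i in np.where(finite_counts == 0)[0]]
        raise ComputationError(f"all-missing {mode}s cannot be scaled: {', '.join(bad)}")

    with np.errstate(invalid="ignore"):
        means = np.nanmean(values, axis=axis, keepdims=True)
        sds = np.nanstd(values, axis=axis, ddof=1, keepdims=True)
    zero_var = (np.squeeze(sds, axis=axis) == 0) | ~np.isfinite(np.squeeze(sds, axis=axis))
    if zero_var.any():
        names = [labels[i] for i in np.where(zero_var)[0][:10]]
        logger.warning("%d zero-variance %s(s) scaled to all zeros (e.g. %s)",
                       int(zero_var.sum()), mode, ", ".join(names))
    safe_sds = np.where(sds > 0, sds, 1.0)
    scaled = (values - means) / safe_sds
    if mode == "row":
        scaled[zero_var, :] = np.where(np.isnan(values[zero_var, :]), np.nan, 0.0)
    else:
        scaled[:, zero_var] = np.where(np.isnan(values[:, zero_var]), np.nan, 0.0)
    return ExpressionMatrix(scaled, list(m.row_labels), list(m.col_labels))


def top_n_by_sd(m: ExpressionMatrix, n: int, strict: bool = False) -> ExpressionMatrix:
    """Keep the n rows with the largest sample standard deviation.

    Original relative row order is preserved.  Ties at the selection
    boundary are broken by original row index (earlier row wins), so the
    selected set is deterministic.
    """
    if not 1 <= n <= m.n_genes:
        raise InputError(f"top-N must satisfy 1 <= N <= {m.n_genes} rows, got {n}")
    if n == m.n_genes:
        return m
    sds = _row_sds(m.values, strict)
    # stable sort on (-sd, index): earlier row wins ties at the boundary
    ranked = np.argsort(-sds, kind="stable")
    keep = np.sort(ranked[:n])
    return ExpressionMatrix(
        m.values[keep, :],
        [m.row_labels[i] for i in keep],
        list(m.col_labels),
    )
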