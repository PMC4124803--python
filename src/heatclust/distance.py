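"""Pairwise distances between samples (columns) or genes (rows).

Three metrics: Euclidean, centered Pearson (1 - r) and uncentered
Pearson (1 - normalized dot product).  Correlation distances read
"dissimilarity of expression pattern": two samples with proportional
profiles are at distance 0, anticorrelated ones at distance 2.

Missing values are handled by pairwise deletion inside each distance;
a pair with fewer than two complete positions is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import ComputationError, ExpressionMatrix, InputError

logger = logging.getLogger("heatclust")

DistanceMetric = Literal["euclidean", "pearson_centered", "pearson_uncentered"]
METRICS = ("euclidean", "pearson_centered", "pearson_uncentered")

# Default metric differs by axis: samples are clustered on correlation of
# their expression profiles, genes on plain Euclidean distance.
DEFAULT_METRIC_COLUMNS: DistanceMetric = "pearson_centered"
DEFAULT_METRIC_ROWS: DistanceMetric = "euclidean"


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.isfinite(self.d).all():
            raise ComputationError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ComputationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-8):
            raise ComputationError("distance matrix diagonal is not zero")
        if (self.d < -1e-8).any():
            raise ComputationError("distance matrix has negative entries")
        # exact symmetry/zero-diagonal/non-negativity after tolerance checks
        self.d = np.maximum((self.d + self.d.T) / 2.0, 0.0)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def _pairwise_missing(X: np.ndarray, metric: DistanceMetric,
                      labels: list[str]) -> np.ndarray:
    """Slow path: per-pair deletion of positions missing in either vector."""
    n = X.shape[0]
    d = np.zeros((n, n))
    finite = np.isfinite(X)
    for i in range(n):
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            if mask.sum() < 2:
                raise ComputationError(
                    f"<2 complete pairs between {labels[i]!r} and {labels[j]!r}"
                )
            x, y = X[i, mask], X[j, mask]
            if metric == "euclidean":
                d[i, j] = np.sqrt(np.sum((x - y) ** 2))
            elif metric == "pearson_centered":
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    bad = labels[i] if sx == 0 else labels[j]
                    raise ComputationError(
                        f"zero variance for {bad!r} under centered Pearson distance"
                    )
                d[i, j] = 1.0 - float(np.corrcoef(x, y)[0, 1])
            else:
                nx, ny = np.linalg.norm(x), np.linalg.norm(y)
                if nx == 0 or ny == 0:
                    bad = labels[i] if nx == 0 else labels[j]
                    raise ComputationError(
                        f"zero norm for {bad!r} under uncentered Pearson distance"
                    )
                d[i, j] = 1.0 - float(x @ y) / (nx * ny)
            d[j, i] = d[i, j]
    return d


def distance_matrix(m: ExpressionMatrix, axis: Literal["rows", "columns"] = "columns",
                    metric: DistanceMetric | None = None) -> DistanceMatrix:
    """Pairwise distances along one axis of an expression matrix.

    Default metric: centered Pearson for columns (samples), Euclidean for
    rows (genes).
    """
    if axis not in ("rows", "columns"):
        raise InputError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if metric is None:
        metric = DEFAULT_METRIC_COLUMNS if axis == "columns" else DEFAULT_METRIC_ROWS
    if metric not in METRICS:
        raise InputError(f"unknown distance metric {metric!r}")
    X = m.values if axis == "rows" else m.values.T
    labels = list(m.row_labels if axis == "rows" else m.col_labels)
    if X.shape[0] < 2:
        raise InputError(f"need >=2 {axis} to compute distances, got {X.shape[0]}")

    has_missing = not np.isfinite(X).all()
    if has_missing:
        logger.info("pairwise deletion over %d missing values (%s, %s)",
                    int(np.isnan(X).sum()), axis, metric)
        d = _pairwise_missing(X, metric, labels)
        return DistanceMatrix(labels, d)

    if metric == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    elif metric == "pearson_centered":
        sds = X.std(axis=1)
        if (sds == 0).any():
            bad = [labels[i] for i in np.where(sds == 0)[0][:10]]
            raise ComputationError(
                f"zero variance under centered Pearson distance: {', '.join(bad)}"
            )
        d = 1.0 - np.corrcoef(X)
    else:
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = [labels[i] for i in np.where(norms == 0)[0][:10]]
            raise ComputationError(
                f"zero norm under uncentered Pearson distance: {', '.join(bad)}"
            )
        d = 1.0 - (X @ X.T) / np.outer(norms, norms)
    # clamp -1e-17-style round-off before validation
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)
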