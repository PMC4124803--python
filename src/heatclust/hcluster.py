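"""Native agglomerative hierarchical clustering with seven linkage schemes.

The agglomeration repeatedly merges the closest pair of clusters and
updates the remaining distances with the Lance-Williams recurrence.  The
seven classic parameterizations are supported: single, complete, average
(UPGMA), weighted (WPGMA), Ward, centroid (UPGMC) and median (WPGMC).

For the geometric family (Ward, centroid, median) the recurrence operates
on *squared* distances — the input distances are assumed Euclidean — and
the recorded merge height is the square root of the merge cost, i.e. the
"ward.D2"-style convention.  Centroid and median linkage can produce
inversions (a merge lower than an earlier one); these are kept as computed.

Tie-breaking when several pairs share the minimum merge cost: the pair
with the smallest (i, j), i < j, in the current cluster indexing wins,
where clusters are indexed in creation order (leaves first, then merged
clusters as they appear).  This makes the output deterministic and lets
oracle tests mirror the rule exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import ComputationError, InputError
from .distance import DistanceMatrix

Linkage = Literal["single", "complete", "average", "weighted", "ward", "centroid", "median"]
LINKAGES = ("single", "complete", "average", "weighted", "ward", "centroid", "median")
DEFAULT_LINKAGE: Linkage = "complete"

# linkages whose merge heights are guaranteed non-decreasing
MONOTONE_LINKAGES = ("single", "complete", "average", "weighted", "ward")
# linkages whose Lance-Williams update runs on squared distances
_SQUARED_FAMILY = ("ward", "centroid", "median")


@dataclass
class Dendrogram:
    """Binary merge tree over labeled leaves.

    Nodes are integers: leaves ``0 .. n-1``, internal nodes ``n + k`` for
    the k-th merge.  ``merges[k] = (left, right)`` and ``heights[k]`` is
    that merge's height.  The left/right order of children encodes the
    planar embedding: the displayed leaf order is the in-order traversal.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float
    _leaf_order: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=int).reshape(-1, 2)
        self.heights = np.asarray(self.heights, dtype=float).reshape(-1)
        n = len(self.labels)
        if n < 1:
            raise InputError("dendrogram needs at least one leaf")
        if self.merges.shape[0] != n - 1 or self.heights.shape[0] != n - 1:
            raise InputError(
                f"{n} leaves require {n - 1} merges, got {self.merges.shape[0]}"
            )
        if n > 1:
            # every node except the root must be used exactly once as a child
            used = np.bincount(self.merges.ravel(), minlength=2 * n - 1)
            if not (used[:2 * n - 2] == 1).all() or used[2 * n - 2] != 0:
                raise InputError("merges do not form a single binary tree")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def max_height(self) -> float:
        return float(self.heights.max()) if self.heights.size else 0.0

    def node_heights(self) -> np.ndarray:
        """Height of every node; leaves sit at 0."""
        h = np.zeros(2 * self.n_leaves - 1)
        h[self.n_leaves:] = self.heights
        return h

    def subtree_leaves(self, node: int) -> list[int]:
        """Leaves under ``node`` in embedding (left-to-right) order."""
        n = self.n_leaves
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                left, right = self.merges[v - n]
                stack.append(int(right))  # left popped first
                stack.append(int(left))
        return out

    @property
    def leaf_order(self) -> np.ndarray:
        """Display permutation of leaves: in-order traversal of the tree."""
        if self._leaf_order is None:
            self._leaf_order = np.asarray(self.subtree_leaves(self.root), dtype=int)
        return self._leaf_order

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_scipy(self) -> np.ndarray:
        """Convert to a scipy-style (n-1, 4) linkage matrix Z."""
        n = self.n_leaves
        sizes = np.ones(2 * n - 1)
        Z = np.zeros((n - 1, 4))
        for k, (a, b) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            Z[k] = (min(a, b), max(a, b), self.heights[k], sizes[n + k])
        return Z


def agglomerate(d: DistanceMatrix, linkage: Linkage = DEFAULT_LINKAGE) -> Dendrogram:
    """Agglomerative clustering of a distance matrix under one linkage scheme.

    Exactly n-1 merges are recorded.  The implementation is the direct
    O(n^3) scan: find the globally closest active pair, merge, apply the
    Lance-Williams update, repeat.
    """
    if linkage not in LINKAGES:
        raise InputError(f"unknown linkage {linkage!r}")
    n = d.n
    if n < 2:
        raise InputError("agglomeration needs at least 2 entities")
    if not np.isfinite(d.d).all():
        raise ComputationError("non-finite distance; clustering not started")

    squared = linkage in _SQUARED_FAMILY
    # working matrix over active clusters, kept in creation order
    D = d.d.astype(float) ** 2 if squared else d.d.astype(float).copy()
    nodes = list(range(n))          # node id per active cluster slot
    sizes = np.ones(n)
    merges = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)

    for step in range(n - 1):
        k = len(nodes)
        iu, ju = np.triu_indices(k, 1)
        flat = D[iu, ju]
        best = int(np.argmin(flat))  # first occurrence = smallest (i, j)
        i, j = int(iu[best]), int(ju[best])
        cost = float(flat[best])
        height = float(np.sqrt(max(cost, 0.0))) if squared else cost
        merges[step] = (nodes[i], nodes[j])
        heights[step] = height

        ni, nj = sizes[i], sizes[j]
        di, dj, dij = D[i, :], D[j, :], D[i, j]
        if linkage == "single":
            new = np.minimum(di, dj)
        elif linkage == "complete":
            new = np.maximum(di, dj)
        elif linkage == "average":
            new = (ni * di + nj * dj) / (ni + nj)
        elif linkage == "weighted":
            new = (di + dj) / 2.0
        elif linkage == "ward":
            nk = sizes
            new = ((ni + nk) * di + (nj + nk) * dj - nk * dij) / (ni + nj + nk)
        elif linkage == "centroid":
            new = (ni * di + nj * dj) / (ni + nj) - ni * nj * dij / (ni + nj) ** 2
        else:  # median
            new = di / 2.0 + dj / 2.0 - dij / 4.0
        # drop merged slots, append the new cluster (creation order preserved)
        keep = [t for t in range(k) if t not in (i, j)]
        new = new[keep]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new
        D[:-1, -1] = new
        nodes = [nodes[t] for t in keep] + [n + step]
        sizes = np.append(sizes[keep], ni + nj)

    return Dendrogram(list(d.labels), merges, heights)


def reorder_leaves(tree: Dendrogram, weights: np.ndarray) -> Dendrogram:
    """Flip subtrees so the one with the smaller mean leaf weight comes first.

    The topology and merge heights are untouched; only the left/right
    order of children changes.  Equal means keep the existing order, so
    the operation is deterministic and idempotent.
    """
    weights = np.asarray(weights, dtype=float)
    n = tree.n_leaves
    if weights.shape != (n,):
        raise InputError(f"need one weight per leaf ({n}), got shape {weights.shape}")
    merges = tree.merges.copy()

    # subtree (sum, count) bottom-up; merges are in creation order so every
    # child of merge k was created before k
    sums = np.zeros(2 * n - 1)
    counts = np.zeros(2 * n - 1)
    sums[:n] = weights
    counts[:n] = 1
    for k, (a, b) in enumerate(merges):
        sums[n + k] = sums[a] + sums[b]
        counts[n + k] = counts[a] + counts[b]
    means = sums / counts
    for k in range(n - 1):
        a, b = merges[k]
        if means[a] > means[b]:
            merges[k] = (b, a)
    return Dendrogram(list(tree.labels), merges, tree.heights.copy())


def cophenetic_matrix(tree: Dendrogram) -> np.ndarray:
    """Full cophenetic distance matrix: height of each pair's lowest common ancestor."""
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform
    return squareform(cophenet(tree.to_scipy()))
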