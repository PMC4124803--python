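"""Independent brute-force oracles used by the test suite.

These recompute clustering results from first principles — cluster-pair
distances evaluated from the original leaf distances at every step — so
they share no code path with the package's incremental Lance-Williams
implementation.
"""

from __future__ import annotations

from itertools import product

import numpy as np


# cluster trees are nested tuples: a leaf is an int, a merged cluster a pair
def _leaves(t):
    if isinstance(t, int):
        return [t]
    return _leaves(t[0]) + _leaves(t[1])


def _pair_sum_sq(d, A, B):
    return sum(d[a, b] ** 2 for a in A for b in B)


def _centroid_sq(d, A, B):
    """||centroid(A) - centroid(B)||^2 from pairwise distances."""
    n, m = len(A), len(B)
    return (_pair_sum_sq(d, A, B) / (n * m)
            - _pair_sum_sq(d, A, A) / (2 * n * n)
            - _pair_sum_sq(d, B, B) / (2 * m * m))


def _wpgma(d, t1, t2):
    if not isinstance(t1, int):
        return (_wpgma(d, t1[0], t2) + _wpgma(d, t1[1], t2)) / 2.0
    if not isinstance(t2, int):
        return (_wpgma(d, t1, t2[0]) + _wpgma(d, t1, t2[1])) / 2.0
    return d[t1, t2]


def _median_sq(d, t1, t2):
    if not isinstance(t1, int):
        return (_median_sq(d, t1[0], t2) / 2.0 + _median_sq(d, t1[1], t2) / 2.0
                - _median_sq(d, t1[0], t1[1]) / 4.0)
    if not isinstance(t2, int):
        return (_median_sq(d, t1, t2[0]) / 2.0 + _median_sq(d, t1, t2[1]) / 2.0
                - _median_sq(d, t2[0], t2[1]) / 4.0)
    return d[t1, t2] ** 2


def _cluster_distance(d, t1, t2, linkage):
    A, B = _leaves(t1), _leaves(t2)
    pairs = [d[a, b] for a in A for b in B]
    if linkage == "single":
        return min(pairs)
    if linkage == "complete":
        return max(pairs)
    if linkage == "average":
        return float(np.mean(pairs))
    if linkage == "weighted":
        return _wpgma(d, t1, t2)
    if linkage == "ward":
        n, m = len(A), len(B)
        return float(np.sqrt(max(2.0 * n * m / (n + m) * _centroid_sq(d, A, B), 0.0)))
    if linkage == "centroid":
        return float(np.sqrt(max(_centroid_sq(d, A, B), 0.0)))
    if linkage == "median":
        return float(np.sqrt(max(_median_sq(d, t1, t2), 0.0)))
    raise ValueError(linkage)


def naive_agglomerate(d: np.ndarray, linkage: str):
    """O(n^3) re-scan agglomeration: every step recomputes all cluster-pair
    distances from the original matrix.  Ties break on the smallest (i, j)
    in creation order, mirroring the documented rule.

    Returns (merged_leafsets, heights): the frozenset of leaves formed by
    each merge and the merge heights, in merge order.
    """
    n = d.shape[0]
    active: list = list(range(n))
    merged_sets = []
    heights = []
    for _ in range(n - 1):
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                dist = _cluster_distance(d, active[i], active[j], linkage)
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        new = (active[i], active[j])
        active = [t for k, t in enumerate(active) if k not in (i, j)] + [new]
        merged_sets.append(frozenset(_leaves(new)))
        heights.append(dist)
    return merged_sets, np.asarray(heights)


def naive_cut_groups(tree, height: float):
    """Exhaustive subtree scan: groups are nodes with height below the cut
    whose parent (if any) sits at or above it."""
    n = tree.n_leaves
    node_h = tree.node_heights()
    parent = {}
    for k, (a, b) in enumerate(tree.merges):
        parent[int(a)] = n + k
        parent[int(b)] = n + k
    groups = []
    for v in range(2 * n - 1):
        below = node_h[v] < height
        p = parent.get(v)
        if below and (p is None or node_h[p] >= height):
            groups.append(frozenset(tree.subtree_leaves(v)))
    return groups


def exhaustive_reorder(tree, weights: np.ndarray):
    """Enumerate all 2^(n-1) child-flip choices and return the unique leaf
    order satisfying: smaller-mean subtree first, ties keep original order."""
    n = tree.n_leaves
    weights = np.asarray(weights, dtype=float)

    def order_for(flips):
        def walk(v):
            if v < n:
                return [v]
            a, b = tree.merges[v - n]
            kids = [int(a), int(b)]
            if flips[v - n]:
                kids.reverse()
            return walk(kids[0]) + walk(kids[1])
        return walk(tree.root)

    def mean(v):
        return float(np.mean(weights[tree.subtree_leaves(v)]))

    valid = []
    for flips in product([False, True], repeat=n - 1):
        ok = True
        for k, (a, b) in enumerate(tree.merges):
            ma, mb = mean(int(a)), mean(int(b))
            first_mean, second_mean = (mb, ma) if flips[k] else (ma, mb)
            if first_mean > second_mean:
                ok = False
                break
            if first_mean == second_mean and flips[k]:
                ok = False  # ties keep the original orientation
                break
        if ok:
            valid.append(order_for(flips))
    assert len(valid) == 1, f"flip rule not unique: {len(valid)} arrangements"
    return valid[0]


def yates_chi2(table: np.ndarray) -> float:
    """Cell-wise (|O-E|-0.5)^2/E summation for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    assert table.shape == (2, 2)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    E = rowsum @ colsum / table.sum()
    adj = np.maximum(np.abs(table - E) - 0.5, 0.0)
    return float((adj ** 2 / E).sum())
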