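"""Dendrogram cut, per-group phenotype summaries and association tests.

Cutting the sample dendrogram at a height partitions the samples into the
maximal subtrees lying entirely below the cut; groups are numbered
left-to-right in leaf order and colored from a fixed palette.  Each
phenotype is then tested for unequal distribution across groups: a
Pearson chi-square for categorical columns (with Yates continuity
correction when the table is exactly 2x2) and a one-way ANOVA F-test for
continuous columns.  Raw p-values are reported; no multiplicity
correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hcluster import Dendrogram
from .io import (
    AssociationReport,
    CategoricalSummary,
    ComputationError,
    ContinuousSummary,
    CONTINUOUS_STATS,
    InputError,
    PhenotypeAssociation,
    PhenotypeColumn,
    PhenotypeTable,
)

logger = logging.getLogger("heatclust")

# fixed qualitative palette, cycled over groups
GROUP_PALETTE = (
    "#E41A1C", "#377EB8", "#4DAF4A", "#984EA3", "#FF7F00", "#A65628",
    "#F781BF", "#1B9E77", "#66A61E", "#E6AB02", "#7570B3", "#666666",
)

DEFAULT_POSITIVE_LEVEL = "Positive"


@dataclass
class CutResult:
    """Partition of samples produced by cutting the column dendrogram."""

    cut_height: float
    sample_ids: list[str]          # in original (matrix) order
    groups: np.ndarray             # group index per sample, original order
    group_order: list[list[int]]   # per group: member leaf indices, leaf order
    group_colors: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def group_labels(self) -> list[str]:
        return [f"Cluster{g + 1}" for g in range(self.n_groups)]

    def members(self, g: int) -> list[str]:
        return [self.sample_ids[i] for i in self.group_order[g]]


def cut_tree(tree: Dendrogram, cutoff: float, relative: bool = True) -> CutResult:
    """Cut a dendrogram at a height and return the induced sample groups.

    With ``relative=True`` (the default) the cutoff is a fraction of the
    maximum merge height, so the worked value 0.85 means "85% of the way
    up the tree" regardless of the distance units; with ``relative=False``
    the cutoff is an absolute height.  Every maximal subtree whose root
    height is below the cut becomes one group, so groups are contiguous
    blocks of the displayed leaf order.
    """
    if not cutoff > 0:
        raise InputError(f"cutoff must be > 0, got {cutoff}")
    height = cutoff * tree.max_height() if relative else float(cutoff)

    n = tree.n_leaves
    node_h = tree.node_heights()
    groups_leaves: list[list[int]] = []
    if n == 1:
        groups_leaves = [[0]]
    else:
        # descend from the root while node height >= cut height; each
        # remaining subtree (possibly a single leaf) is one group
        stack = [tree.root]
        collected: list[int] = []
        while stack:
            v = stack.pop()
            if v >= n and node_h[v] >= height:
                left, right = tree.merges[v - n]
                stack.append(int(right))
                stack.append(int(left))
            else:
                collected.append(v)
        for v in collected:
            groups_leaves.append(tree.subtree_leaves(v))

    groups = np.empty(n, dtype=int)
    for g, leaves in enumerate(groups_leaves):
        groups[leaves] = g
    colors = [GROUP_PALETTE[g % len(GROUP_PALETTE)] for g in range(len(groups_leaves))]
    return CutResult(
        cut_height=height,
        sample_ids=list(tree.labels),
        groups=groups,
        group_order=groups_leaves,
        group_colors=colors,
    )


# ---------------------------------------------------------------------------
# summaries

def summarize_categorical(ph: PhenotypeColumn, cut: CutResult,
                          positive_level: str | None = None) -> CategoricalSummary:
    """Count each level per group; add positive-percent for binary columns.

    Counts run over non-missing samples only.  ``positive_level`` defaults
    to the level literally named "Positive" when present; positive-percent
    is positives / group non-missing size.
    """
    if ph.kind != "categorical":
        raise InputError(f"column {ph.name!r} is not categorical")
    levels = ph.levels()
    counts = np.zeros((len(levels), cut.n_groups), dtype=int)
    idx = {lev: i for i, lev in enumerate(levels)}
    for g, v in zip(cut.groups, ph.values):
        if v is not None:
            counts[idx[str(v)], g] += 1
    empty = np.where(counts.sum(axis=0) == 0)[0]
    for g in empty:
        logger.warning("phenotype %r: group %d has no non-missing values", ph.name, g + 1)

    if positive_level is None and DEFAULT_POSITIVE_LEVEL in levels and len(levels) == 2:
        positive_level = DEFAULT_POSITIVE_LEVEL
    pos_pct = None
    if positive_level is not None:
        if positive_level not in idx:
            raise InputError(
                f"positive level {positive_level!r} not among levels of {ph.name!r}: {levels}"
            )
        totals = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, counts[idx[positive_level]] / totals, np.nan)
        pos_pct = [float(p) for p in pct]
    return CategoricalSummary(levels=levels, counts=counts,
                              positive_level=positive_level, positive_percent=pos_pct)


def summarize_continuous(ph: PhenotypeColumn, cut: CutResult) -> ContinuousSummary:
    """Six-number summary (min, Q1, median, mean, Q3, max) per group.

    Quartiles use linear interpolation between order statistics.  An empty
    group yields a row of missing values with a warning.
    """
    if ph.kind != "continuous":
        raise InputError(f"column {ph.name!r} is not continuous")
    vals = np.asarray(ph.values, dtype=float)
    out: list[dict[str, float]] = []
    for g in range(cut.n_groups):
        x = vals[(cut.groups == g) & np.isfinite(vals)]
        if x.size == 0:
            logger.warning("phenotype %r: group %d empty, summary is missing", ph.name, g + 1)
            out.append({k: math.nan for k in CONTINUOUS_STATS})
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
        out.append({
            "min": float(x.min()), "q1": float(q1), "median": float(med),
            "mean": float(x.mean()), "q3": float(q3), "max": float(x.max()),
        })
    return ContinuousSummary(stats=out)


# ---------------------------------------------------------------------------
# tests

def chi_square_test(table: np.ndarray) -> tuple[float | None, int, float | None]:
    """Pearson chi-square on a level x group contingency table.

    Yates continuity correction is applied iff the table is exactly 2x2
    after zero-marginal rows/columns are dropped (with a warning).  Returns
    (statistic, df, p); statistic/p are None when fewer than two rows or
    columns remain.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise InputError("contingency table must be two-dimensional")
    if (table < 0).any() or not np.isfinite(table).all():
        raise InputError("contingency table entries must be finite and non-negative")
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        logger.warning("dropping %d zero-marginal rows and %d columns before chi-square",
                       int((~rows).sum()), int((~cols).sum()))
        table = table[np.ix_(rows, cols)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        logger.warning("chi-square skipped: <2 informative rows or columns")
        return None, 0, None
    correction = table.shape == (2, 2)
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_test(ph: PhenotypeColumn, cut: CutResult) -> tuple[float | None, int, int, float | None]:
    """One-way ANOVA of a continuous phenotype across cut groups.

    F = (SSB/df_between) / (SSW/df_within), p from the upper F tail.
    Degenerate cases: SSW = 0 with SSB > 0 gives F = inf, p = 0 (flagged);
    both zero gives an undefined F and a missing p.
    """
    if ph.kind != "continuous":
        raise InputError(f"column {ph.name!r} is not continuous")
    vals = np.asarray(ph.values, dtype=float)
    samples = [vals[(cut.groups == g) & np.isfinite(vals)] for g in range(cut.n_groups)]
    samples = [s for s in samples if s.size > 0]
    k = len(samples)
    n = sum(s.size for s in samples)
    if k < 2:
        raise ComputationError(f"ANOVA needs >=2 groups with data for {ph.name!r}")
    if n <= k:
        raise ComputationError(
            f"ANOVA needs more observations ({n}) than groups ({k}) for {ph.name!r}"
        )
    grand = np.concatenate(samples).mean()
    ssb = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    if ssw == 0 and ssb == 0:
        logger.warning("ANOVA undefined for %r: no variance within or between groups", ph.name)
        return None, df_b, df_w, None
    if ssw == 0:
        logger.warning("ANOVA for %r: zero within-group variance, F infinite, p -> 0", ph.name)
        return math.inf, df_b, df_w, 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def associate_all(ph: PhenotypeTable, cut: CutResult,
                  positive_levels: dict[str, str] | None = None) -> AssociationReport:
    """Run the kind-appropriate summary and test for every phenotype column.

    Per-column failures are recorded as notes in the report rather than
    aborting the remaining columns.
    """
    ph = ph.reconcile(cut.sample_ids)
    positive_levels = positive_levels or {}
    report = AssociationReport(group_labels=cut.group_labels())
    for col in ph.columns:
        note = ""
        try:
            if col.kind == "categorical":
                summary: CategoricalSummary | ContinuousSummary = summarize_categorical(
                    col, cut, positive_levels.get(col.name))
                stat, df, p = chi_square_test(summary.counts)
                if p is None:
                    note = "test skipped: degenerate table"
                entry = PhenotypeAssociation(
                    name=col.name, kind=col.kind, summary=summary,
                    test_name="chi-square", statistic=stat, df=(df,), p_value=p, note=note)
            else:
                summary = summarize_continuous(col, cut)
                F, df_b, df_w, p = anova_test(col, cut)
                if p == 0.0 and F is not None and math.isinf(F):
                    note = "zero within-group variance; p below machine precision"
                elif p is None:
                    note = "test skipped: no variance"
                entry = PhenotypeAssociation(
                    name=col.name, kind=col.kind, summary=summary,
                    test_name="anova", statistic=F, df=(df_b, df_w), p_value=p, note=note)
        except (ComputationError, InputError) as exc:
            logger.warning("phenotype %r skipped: %s", col.name, exc)
            entry = PhenotypeAssociation(
                name=col.name, kind=col.kind,
                summary=(CategoricalSummary([], np.zeros((0, cut.n_groups), dtype=int))
                         if col.kind == "categorical"
                         else ContinuousSummary([])),
                test_name="chi-square" if col.kind == "categorical" else "anova",
                statistic=None, df=(), p_value=None, note=str(exc))
        report.entries.append(entry)
    return report
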