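import math

import numpy as np
import pytest
from scipy import stats

from heatclust import (
    Dendrogram,
    DistanceMatrix,
    PhenotypeColumn,
    PhenotypeTable,
    agglomerate,
    anova_test,
    associate_all,
    chi_square_test,
    cut_tree,
    summarize_categorical,
    summarize_continuous,
)
from heatclust.io import InputError

from _oracles import naive_cut_groups, yates_chi2
from conftest import random_tree


def _chain_tree(heights, labels=None):
    """Caterpillar tree merging leaves left to right at the given heights."""
    n = len(heights) + 1
    labels = labels or [f"S{i}" for i in range(n)]
    merges = [(0, 1)] + [(n + k - 1, k + 1) for k in range(1, n - 1)]
    return Dendrogram(labels, np.array(merges), np.array(heights, dtype=float))


def _cut_for_groups(sizes):
    """Synthetic CutResult over consecutive blocks of the given sizes."""
    from heatclust.cuttest import CutResult, GROUP_PALETTE
    n = sum(sizes)
    groups = np.repeat(np.arange(len(sizes)), sizes)
    order = []
    start = 0
    for s in sizes:
        order.append(list(range(start, start + s)))
        start += s
    return CutResult(1.0, [f"S{i}" for i in range(n)], groups, order,
                     [GROUP_PALETTE[g % 12] for g in range(len(sizes))])


class TestCutTree:
    def test_above_root_single_group(self):
        t = _chain_tree([1, 2, 9])
        cut = cut_tree(t, 10, relative=False)
        assert cut.n_groups == 1 and (cut.groups == 0).all()

    def test_below_first_merge_all_singletons(self):
        t = _chain_tree([1, 2, 9])
        cut = cut_tree(t, 0.5, relative=False)
        assert cut.n_groups == 4

    def test_heights_1_2_9_cut_at_5(self):
        t = _chain_tree([1, 2, 9])
        cut = cut_tree(t, 5, relative=False)
        assert cut.n_groups == 2
        got = {frozenset(g) for g in cut.group_order}
        assert got == set(naive_cut_groups(t, 5))

    def test_relative_cut_uses_max_height(self):
        t = _chain_tree([1, 2, 10])
        assert cut_tree(t, 0.85, relative=True).cut_height == pytest.approx(8.5)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(InputError):
            cut_tree(_chain_tree([1]), 0)

    def test_groups_contiguous_in_leaf_order(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n = int(rng.integers(3, 13))
            t = random_tree(rng, n)
            h = float(rng.uniform(0, t.max_height() * 1.1))
            cut = cut_tree(t, max(h, 1e-6), relative=False)
            order = list(t.leaf_order)
            # each group occupies one contiguous block of the leaf order
            seen = [int(cut.groups[i]) for i in order]
            changes = sum(a != b for a, b in zip(seen, seen[1:]))
            assert changes == cut.n_groups - 1
            # groups numbered left-to-right
            assert sorted(set(seen)) == list(range(cut.n_groups))
            assert seen == sorted(seen)
            # matches the exhaustive subtree scan
            got = {frozenset(g) for g in cut.group_order}
            assert got == set(naive_cut_groups(t, cut.cut_height))

    def test_raising_cut_never_increases_groups(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            t = random_tree(rng, 10, "complete")  # monotone linkage
            hs = np.sort(rng.uniform(0, t.max_height() * 1.05, size=6))
            counts = [cut_tree(t, float(h) + 1e-9, relative=False).n_groups for h in hs]
            assert counts == sorted(counts, reverse=True)

    def test_group_colors_cycle_deterministically(self):
        t = _chain_tree(list(range(1, 15)))
        cut = cut_tree(t, 0.5, relative=False)  # 15 singleton groups
        from heatclust.cuttest import GROUP_PALETTE
        assert cut.group_colors[0] == GROUP_PALETTE[0]
        assert cut.group_colors[12] == GROUP_PALETTE[0]  # palette of 12, cycled


class TestChiSquare:
    def test_table1_er(self):
        stat, df, p = chi_square_test([[2, 11], [13, 4]])
        assert df == 1
        assert round(p, 3) == 0.003

    def test_table1_pr(self):
        _, _, p = chi_square_test([[4, 13], [11, 2]])
        assert round(p, 3) == 0.003

    def test_proportional_columns_statistic_zero(self):
        stat, df, p = chi_square_test([[13, 13], [2, 2]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_yates_cellwise_oracle(self):
        stat, _, _ = chi_square_test([[2, 11], [13, 4]])
        assert stat == pytest.approx(yates_chi2([[2, 11], [13, 4]]), rel=1e-12)

    def test_no_correction_beyond_2x2(self):
        table = [[5, 9, 2], [7, 3, 8]]
        stat, df, p = chi_square_test(table)
        ref = stats.chi2_contingency(np.array(table), correction=False)
        assert df == 2
        assert stat == pytest.approx(ref.statistic)

    def test_row_column_permutation_invariance(self):
        rng = np.random.default_rng(33)
        t = rng.integers(1, 20, size=(3, 4))
        s0, _, p0 = chi_square_test(t)
        s1, _, p1 = chi_square_test(t[::-1, ::-1])
        assert s1 == pytest.approx(s0) and p1 == pytest.approx(p0)

    def test_zero_marginal_dropped_then_skipped(self):
        # after dropping the empty row only one row remains -> p missing
        stat, df, p = chi_square_test([[0, 0], [3, 5]])
        assert stat is None and p is None

    def test_type_one_error_bounded(self):
        """2x2 Yates chi-square under a balanced-margin null keeps the
        rejection rate at or below nominal 0.05 (plus 2 SE)."""
        rng = np.random.default_rng(34)
        reps, n = 1500, 60
        rejections = 0
        tested = 0
        for _ in range(reps):
            ph = rng.random(n) < 0.5
            grp = np.arange(n) < n // 2
            table = [[int((ph & grp).sum()), int((ph & ~grp).sum())],
                     [int((~ph & grp).sum()), int((~ph & ~grp).sum())]]
            _, _, p = chi_square_test(table)
            if p is not None:
                tested += 1
                rejections += p <= 0.05
        se = math.sqrt(0.05 * 0.95 / tested)
        assert rejections / tested <= 0.05 + 2 * se


class TestSummaries:
    def test_table1_positive_percents(self):
        cut = _cut_for_groups([15, 15])
        er = (["Negative"] * 2 + ["Positive"] * 13) + (["Negative"] * 11 + ["Positive"] * 4)
        s = summarize_categorical(PhenotypeColumn("ER", "categorical", er), cut)
        np.testing.assert_array_equal(s.counts, [[2, 11], [13, 4]])
        assert [round(p, 2) for p in s.positive_percent] == [0.87, 0.27]

    def test_pr_cluster1_percent(self):
        cut = _cut_for_groups([15, 15])
        pr = (["Negative"] * 4 + ["Positive"] * 11) + (["Negative"] * 13 + ["Positive"] * 2)
        s = summarize_categorical(PhenotypeColumn("PR", "categorical", pr), cut)
        assert round(s.positive_percent[0], 2) == 0.73

    def test_all_positive_group(self):
        cut = _cut_for_groups([3, 3])
        col = PhenotypeColumn("X", "categorical", ["Positive"] * 3 + ["Negative"] * 3)
        s = summarize_categorical(col, cut)
        assert s.positive_percent[0] == pytest.approx(1.0)

    def test_counts_sum_to_nonmissing(self):
        cut = _cut_for_groups([4, 4])
        col = PhenotypeColumn("X", "categorical",
                              ["A", "B", None, "A", "B", None, None, "B"])
        s = summarize_categorical(col, cut)
        assert s.counts[:, 0].sum() == 3 and s.counts[:, 1].sum() == 2

    def test_continuous_min_median_max(self):
        cut = _cut_for_groups([3])
        s = summarize_continuous(PhenotypeColumn("age", "continuous", [41, 61, 89]), cut)
        g = s.stats[0]
        assert (g["min"], g["median"], g["max"]) == (41, 61, 89)

    def test_single_value_group(self):
        cut = _cut_for_groups([1, 2])
        s = summarize_continuous(PhenotypeColumn("age", "continuous", [50, 1, 2]), cut)
        assert all(v == 50 for v in s.stats[0].values())

    def test_sort_based_oracle(self):
        rng = np.random.default_rng(35)
        vals = list(rng.uniform(30, 90, 30))
        cut = _cut_for_groups([15, 15])
        s = summarize_continuous(PhenotypeColumn("age", "continuous", vals), cut)
        for g in range(2):
            x = sorted(vals[15 * g:15 * (g + 1)])
            assert s.stats[g]["min"] == pytest.approx(x[0])
            assert s.stats[g]["max"] == pytest.approx(x[-1])
            assert s.stats[g]["median"] == pytest.approx(x[7])
            assert s.stats[g]["mean"] == pytest.approx(sum(x) / 15)
            # linear-interpolation quartiles: position 0.25*(n-1) between order stats
            lo, frac = divmod(0.25 * 14, 1)
            assert s.stats[g]["q1"] == pytest.approx(
                x[int(lo)] + frac * (x[int(lo) + 1] - x[int(lo)]))


class TestAnova:
    def test_identical_groups(self):
        cut = _cut_for_groups([3, 3])
        F, dfb, dfw, p = anova_test(
            PhenotypeColumn("age", "continuous", [1, 2, 3, 1, 2, 3]), cut)
        assert F == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert (dfb, dfw) == (1, 4)

    def test_zero_within_variance_limit(self):
        cut = _cut_for_groups([2, 2])
        F, _, _, p = anova_test(
            PhenotypeColumn("age", "continuous", [0, 0, 10, 10]), cut)
        assert math.isinf(F) and p == 0.0

    def test_scipy_cross_check(self):
        rng = np.random.default_rng(36)
        vals = list(rng.normal(size=24))
        cut = _cut_for_groups([8, 8, 8])
        F, dfb, dfw, p = anova_test(PhenotypeColumn("x", "continuous", vals), cut)
        ref = stats.f_oneway(vals[:8], vals[8:16], vals[16:])
        assert F == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_null_p_values_uniform(self):
        """Under a true null the ANOVA p-value is uniform on [0, 1]."""
        rng = np.random.default_rng(37)
        cut = _cut_for_groups([15, 15])
        ps = []
        for _ in range(2000):
            vals = list(rng.normal(size=30))
            *_, p = anova_test(PhenotypeColumn("x", "continuous", vals), cut)
            ps.append(p)
        D = stats.kstest(ps, "uniform").statistic
        assert D < 0.05


class TestAssociateAll:
    def test_planted_association_detected(self, planted):
        from heatclust import distance_matrix, scale_matrix, top_n_by_sd
        m, ph, labels = planted
        sub = top_n_by_sd(scale_matrix(m, "row"), 30)
        tree = agglomerate(distance_matrix(sub, "columns"), "complete")
        cut = cut_tree(tree, 0.85)
        report = associate_all(ph, cut)
        assert [e.test_name for e in report.entries] == ["chi-square", "anova"]
        status = report.entries[0]
        assert status.p_value is not None and status.p_value < 1e-3

    def test_empty_table_empty_report(self):
        cut = _cut_for_groups([2, 2])
        ph = PhenotypeTable([f"S{i}" for i in range(4)], [])
        assert associate_all(ph, cut).entries == []

    def test_bad_column_does_not_abort_report(self):
        cut = _cut_for_groups([2, 2])
        ph = PhenotypeTable([f"S{i}" for i in range(4)], [
            PhenotypeColumn("const", "continuous", [5, 5, 5, 5]),
            PhenotypeColumn("ok", "categorical", ["A", "B", "A", "B"]),
        ])
        report = associate_all(ph, cut)
        assert len(report.entries) == 2
        assert report.entries[0].p_value is None  # no variance anywhere
        assert report.entries[1].statistic is not None

    def test_phenotype_equal_to_groups_is_extreme(self):
        rng = np.random.default_rng(38)
        cut = _cut_for_groups([30, 30])
        ph = PhenotypeTable(
            [f"S{i}" for i in range(60)],
            [PhenotypeColumn("grp", "categorical",
                             ["A"] * 30 + ["B"] * 30)])
        report = associate_all(ph, cut)
        assert report.entries[0].p_value < 1e-4
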