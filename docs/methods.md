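# Methods

## Clustering model

Samples (matrix columns) and genes (rows) are clustered by agglomerative
hierarchical clustering: starting from singletons, the two closest clusters
are merged repeatedly and the distance from the new cluster to every other
one is obtained from the Lance–Williams recurrence.  The seven supported
parameterizations are single, complete, average (UPGMA), weighted (WPGMA),
Ward, centroid (UPGMC) and median (WPGMC) linkage.

For the geometric family (Ward, centroid, median) the recurrence is applied
to *squared* distances and the recorded merge height is the square root of
the merge cost — the "ward.D2" convention.  These three schemes implicitly
assume the input dissimilarities are Euclidean; on non-Euclidean inputs
(e.g. correlation distances) they are still computed formally, and any
negative round-off under the square root is clamped to zero.  Centroid and
median linkage can produce inversions (a merge lower than an earlier one);
these are kept as computed and drawn as-is, matching common practice.

When several cluster pairs tie for the minimum merge cost, the pair with the
smallest `(i, j)`, `i < j`, in creation order wins (leaves first, merged
clusters in the order they appear).  This makes results deterministic and is
mirrored exactly by the brute-force oracle in the test suite.  The
implementation is the direct O(n³) re-scan, which is transparent to verify;
at the few hundred to few thousand leaves typical of sample clustering it
completes in seconds.

Distances: Euclidean, centered Pearson `1 − r`, and uncentered Pearson
`1 − x·y/(‖x‖‖y‖)`.  "Correlation distance" is read as `1 − r` (range
[0, 2]), the conventional choice; `(1 − r)/2` users can rescale downstream.
Defaults differ by axis: samples are compared by the correlation of their
expression profiles (two samples with proportional profiles are "near"
regardless of overall level), genes by Euclidean distance on their
(typically row-scaled) values.  The default linkage is complete for both
axes.  All defaults are overridable per axis.

Leaf display order: at every internal node the subtree with the smaller mean
leaf weight is placed first (ties keep the existing orientation), with the
column weights taken as per-sample mean expression.  The row tree's first
leaf is drawn at the top, the column tree's first leaf at the left.

## Cutting and association testing

The column dendrogram is cut at a height; every maximal subtree whose root
lies strictly below the cut becomes one group, so groups are contiguous
blocks of the leaf order and the group count equals the number of branches
crossing the cut.  The cutoff is interpreted **relative** to the maximum
merge height by default (cut height = cutoff × root height): a value like
0.85 is then dimensionless and transfers across distance metrics, whereas
absolute heights of correlation-distance trees are data-dependent.  An
absolute-height mode (`--cut-absolute`) is provided.  Group colors come from
a fixed 12-color qualitative palette, cycled, numbered left to right.

Categorical phenotypes are tested with the Pearson χ² test on the
level × group contingency table.  Yates' continuity correction
(`(|O − E| − 0.5)²/E`) is applied **iff** the table is exactly 2×2 — the
convention of the standard R test, and the variant consistent with the
reference two-cluster receptor-status p-values the suite reproduces.
Zero-marginal rows/columns are dropped with a warning first; if fewer than
two rows or columns remain the test is skipped and p reported missing.
Binary phenotypes additionally report a per-group positive fraction; the
positive level defaults to one literally named "Positive".

Continuous phenotypes get a per-group six-number summary (min, Q1, median,
mean, Q3, max; quartiles by linear interpolation between order statistics,
the numpy/R-type-7 default) and a one-way ANOVA F-test computed from sums of
squares, so degenerate cases are explicit: identical groups give F = 0,
p = 1; zero within-group variance with distinct means gives F = ∞, p = 0
(flagged); no variance at all gives a missing p with a warning.  P-values
are reported raw (no multiplicity correction) to 3 decimals in TSV and at
full precision in JSON.  A failing column never aborts the rest of the
report.

## Color mapping

The balanced scale takes `M = max|finite value|`, splits `[−M, M]` into an
odd number of equal bins (default 255) and interpolates the
blue → white → red palette linearly in sRGB, so the middle bin — and hence
the color white — represents exactly zero and bin indices satisfy
`idx(−v) = k − 1 − idx(v)` at bin centers.  Bins are half-open with the last
closed; values outside an explicit display range clamp to the end bins;
missing values map to a grey sentinel.  The unbalanced scale spans
`[min, max]`.  An all-equal matrix expands its degenerate range by ±0.5 with
a warning rather than failing.

## Preprocessing

Row scaling (the default, for backward compatibility with the base-R
heatmap behaviour this tool follows) centers each gene to mean 0 and
sample sd 1 (n−1 denominator).  A zero-variance gene scales to all zeros —
rendered as the midpoint color — with a warning rather than an error.
Top-N selection keeps the N genes with the largest sample sd, preserving
original row order; ties at the boundary resolve to the earlier row.
Missing values are excluded listwise from sd computations and pairwise
inside each distance (with logged counts); `--strict-missing` turns any
missing value into an error.  A distance pair with fewer than two complete
positions is an error.

## Synthetic data

`FixtureSpec` defaults describe a clearly separable two-group bulk design:
500 genes × 60 samples, 2 balanced clusters, half the genes informative with
cluster mean profiles 6 sd apart (random per-gene direction), a binary
phenotype agreeing with the cluster label with probability 0.9, and an age
column drawn N(60, 10²) independently of the clusters.  Random sub-streams
are keyed per component from the seed, so adding a phenotype never changes
the matrix.

The generator emulates planted cluster structure and controlled
phenotype–cluster association; it does **not** emulate count overdispersion
(negative-binomial noise), library-size or batch effects, gene–gene
correlation beyond the planted signal, or missing-data patterns.  Passing
tests therefore demonstrate correctness of the clustering/testing machinery
and recoverability of strong planted structure, not robustness to the noise
characteristics of real RNA-seq.

## Validation problem sizes

The suite checks the clustering engine against a from-scratch O(n³) re-scan
oracle and an independent hierarchy implementation on ~200 random matrices
(n ≤ 10, all seven linkages, 1e−9 tolerance), cut invariants on 500 random
trees, full-pipeline planted-label recovery over 100 seeds (Rand index 1.0
plus phenotype χ² p < 1e−4 in ≥ 95 seeds), and type-I error of both tests
under simulated nulls (5,000 χ² tables, 2,000 ANOVA datasets, bound
0.05 + 2·SE).  Figure output is validated structurally (one SVG element per
heatmap cell, layout metadata) and by raster read-back of cell-center pixels
against the color mapping.

## Known limitations

- O(n³) clustering is deliberate; very large gene-side trees (≫ 5,000 rows)
  are slow — restrict with `--top-n` first, which is also the analytically
  sensible choice.
- Centroid/median trees are non-monotone, so relative cut heights and the
  "raising the cut never adds groups" property do not apply to them.
- Visual output aims for structural correctness, not byte-level parity with
  any other plotting system; PNG rendering is best-effort and the vector
  formats are the stable surface.
- Fisher's exact test and post-hoc pairwise comparisons are out of scope;
  for sparse tables the χ² p-values are approximations.
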