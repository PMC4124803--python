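"""Figure composition: heatmap body, dendrograms, legend, annotation tracks.

The layout mirrors the classic clustered-heatmap arrangement: column
dendrogram on top, row dendrogram on the left, a legend color bar at the
top left, the cut-group bar and column-side annotation tracks between the
column dendrogram and the body, and row-side color bars left of the body.
The row tree's first leaf is drawn at the top, the column tree's first
leaf at the left.

Every render writes a sidecar ``<out>.layout.json`` with panel rectangles
(figure fractions), the displayed row/column orders and the group bar
segments, so tests can assert alignment without parsing pixels.  Vector
formats (SVG/PDF) are the deterministic test surface; PNG is best-effort
visual output.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import to_rgb
from matplotlib.patches import Rectangle

from .colormap import ColorScale, MISSING_COLOR, build_scale, index_to_hex, map_colors
from .cuttest import CutResult, cut_tree
from .distance import DistanceMetric, distance_matrix
from .hcluster import Dendrogram, Linkage, agglomerate
from .io import ExpressionMatrix, InputError, PhenotypeColumn, PhenotypeTable
from .preprocess import top_n_by_sd

logger = logging.getLogger("heatclust")

FORMATS = ("png", "svg", "pdf")
# draw individual cell rectangles (stable SVG structure) up to this many cells
_PATCH_CELL_LIMIT = 40_000

TRACK_PALETTE = ("#66C2A5", "#FC8D62", "#8DA0CB", "#E78AC3", "#A6D854", "#FFD92F")


@dataclass
class AnnotationSpec:
    """How one phenotype is drawn in the column-side annotation block."""

    name: str
    style: str  # color_bar | categorical_squares | continuous_scatter
    level_colors: dict[str, str] | None = None
    mark_color: str = "black"
    axis_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.style not in ("color_bar", "categorical_squares", "continuous_scatter"):
            raise InputError(f"unknown annotation style {self.style!r}")


# ---------------------------------------------------------------------------
# panel primitives (each draws into a prepared Axes)

def _bare(ax) -> None:
    ax.set_xticks([])
    ax.set_yticks([])
    for s in ax.spines.values():
        s.set_visible(False)


def _draw_dendrogram(ax, tree: Dendrogram, orientation: str = "top") -> None:
    """Elbow-style dendrogram; leaves at half-integer positions in leaf order."""
    n = tree.n_leaves
    order = tree.leaf_order
    pos = np.empty(n)
    pos[order] = np.arange(n) + 0.5
    heights = tree.node_heights()
    xs = np.zeros(2 * n - 1)
    xs[:n] = pos
    for k, (a, b) in enumerate(tree.merges):
        xs[n + k] = (xs[a] + xs[b]) / 2.0
    for k, (a, b) in enumerate(tree.merges):
        h = heights[n + k]
        seg_x = [xs[a], xs[a], xs[b], xs[b]]
        seg_y = [heights[a], h, h, heights[b]]
        if orientation == "top":
            ax.plot(seg_x, seg_y, color="black", lw=0.8)
        else:  # left: positions run down the y axis, heights grow leftwards
            ax.plot([-y for y in seg_y], [n - x for x in seg_x], color="black", lw=0.8)
    top = max(tree.max_height(), 1e-12)
    if orientation == "top":
        ax.set_xlim(0, n)
        ax.set_ylim(0, top * 1.05)
    else:
        ax.set_xlim(-top * 1.05, 0)
        ax.set_ylim(0, n)
    _bare(ax)


def _cell_rgb(values: np.ndarray, scale: ColorScale) -> np.ndarray:
    idx = map_colors(values, scale)
    hexes = index_to_hex(idx, scale)
    rgb = np.empty(values.shape + (3,))
    flat = hexes.ravel()
    out = rgb.reshape(-1, 3)
    cache: dict[str, tuple] = {}
    for i, h in enumerate(flat):
        if h not in cache:
            cache[h] = to_rgb(h)
        out[i] = cache[h]
    return rgb


def _draw_body(ax, values: np.ndarray, scale: ColorScale) -> None:
    """Heatmap cells; matplotlib Rectangle per cell on small matrices so SVG
    output has one element per cell, image fallback for big ones."""
    nr, nc = values.shape
    if values.size <= _PATCH_CELL_LIMIT:
        idx = map_colors(values, scale)
        hexes = index_to_hex(idx, scale)
        for i in range(nr):
            for j in range(nc):
                r = Rectangle((j, nr - 1 - i), 1, 1, facecolor=hexes[i, j],
                              edgecolor="none", antialiased=False)
                r.set_gid(f"cell-{i}-{j}")
                ax.add_patch(r)
    else:
        rgb = _cell_rgb(values, scale)
        ax.imshow(rgb, aspect="auto", interpolation="nearest",
                  extent=(0, nc, 0, nr), origin="upper")
    ax.set_xlim(0, nc)
    ax.set_ylim(0, nr)
    _bare(ax)


def render_legend_colorbar(ax, scale: ColorScale) -> None:
    """Gradient strip with min/mid/max value ticks; balanced scales tick 0 in the middle."""
    rgb = np.array([to_rgb(c) for c in scale.colors])[None, :, :]
    ax.imshow(rgb, aspect="auto", interpolation="nearest",
              extent=(scale.v_min, scale.v_max, 0, 1))
    mid = 0.0 if scale.balanced else (scale.v_min + scale.v_max) / 2.0
    ax.set_xticks([scale.v_min, mid, scale.v_max])
    ax.set_xticklabels([f"{scale.v_min:g}", f"{mid:g}", f"{scale.v_max:g}"], fontsize=6)
    ax.set_yticks([])
    ax.tick_params(length=2, pad=1)


def render_group_bar(ax, cut: CutResult) -> None:
    """Contiguous colored segments, one per cut group, in leaf order."""
    x = 0
    for g, leaves in enumerate(cut.group_order):
        w = len(leaves)
        ax.add_patch(Rectangle((x, 0), w, 1, facecolor=cut.group_colors[g],
                               edgecolor="none", antialiased=False))
        x += w
    ax.set_xlim(0, x)
    ax.set_ylim(0, 1)
    _bare(ax)


def render_color_bar_track(ax, column: PhenotypeColumn, order: Sequence[int],
                           level_colors: dict[str, str] | None = None) -> None:
    """One colored cell per sample for a categorical phenotype (mutually
    exclusive levels)."""
    levels = column.levels()
    if level_colors is None:
        level_colors = {lev: TRACK_PALETTE[i % len(TRACK_PALETTE)]
                        for i, lev in enumerate(levels)}
    for x, i in enumerate(order):
        v = column.values[i]
        color = MISSING_COLOR if v is None else level_colors.get(str(v), MISSING_COLOR)
        ax.add_patch(Rectangle((x, 0), 1, 1, facecolor=color, edgecolor="none",
                               antialiased=False))
    ax.set_xlim(0, len(order))
    ax.set_ylim(0, 1)
    _bare(ax)


def render_categorical_squares(ax, columns: Sequence[PhenotypeColumn],
                               order: Sequence[int], mark_color: str = "black") -> None:
    """Black-square tracks: each phenotype level gets a row; a filled square
    marks every sample carrying that level.  Suits phenotypes that are not
    mutually exclusive (a sample can be TN and ER-negative at once).
    Phenotypes with more than two levels are drawn as a color bar instead,
    with a warning, by the layout assembly — this primitive expects the
    binary-style ones."""
    rows: list[tuple[str, list[bool]]] = []
    for col in columns:
        levels = col.levels()
        for lev in levels:
            rows.append((f"{col.name}/{lev}",
                         [col.values[i] is not None and str(col.values[i]) == lev
                          for i in order]))
        if not levels:
            rows.append((f"{col.name}/(all missing)", [False] * len(order)))
    nrows = max(len(rows), 1)
    for r, (label, mask) in enumerate(rows):
        y = nrows - 1 - r
        for x, hit in enumerate(mask):
            if hit:
                ax.add_patch(Rectangle((x + 0.15, y + 0.15), 0.7, 0.7,
                                       facecolor=mark_color, edgecolor="none",
                                       antialiased=False))
    ax.set_xlim(0, len(order))
    ax.set_ylim(0, nrows)
    ax.set_yticks([nrows - 1 - r + 0.5 for r in range(len(rows))])
    ax.set_yticklabels([lab for lab, _ in rows], fontsize=5)
    ax.set_xticks([])
    for s in ax.spines.values():
        s.set_visible(False)
    ax.tick_params(length=0)


def render_continuous_scatter(ax, column: PhenotypeColumn, order: Sequence[int],
                              axis_range: tuple[float, float] | None = None) -> None:
    """One point per sample at its column center; values labeled on the right axis."""
    vals = np.asarray(column.values, dtype=float)
    xs = [i + 0.5 for i in range(len(order))]
    ys = vals[list(order)]
    ok = np.isfinite(ys)
    ax.scatter(np.asarray(xs)[ok], ys[ok], s=6, color="black", zorder=3)
    if axis_range is None:
        if ok.any():
            lo, hi = float(ys[ok].min()), float(ys[ok].max())
        else:
            lo, hi = 0.0, 1.0
        pad = 0.05 * (hi - lo) if hi > lo else 0.5
        axis_range = (lo - pad, hi + pad)
    ax.set_xlim(0, len(order))
    ax.set_ylim(*axis_range)
    ax.yaxis.tick_right()
    ax.tick_params(axis="y", labelsize=5, length=2)
    ax.set_xticks([])
    for name, s in ax.spines.items():
        s.set_visible(name == "right")
    ax.set_ylabel(column.name, fontsize=6)
    ax.yaxis.set_label_position("right")


def _run_hook(ax, hook: Callable, ordered_ids: list[str], name: str) -> None:
    """Custom-annotation hook: called with (axes, samples in display order).

    A failing hook leaves its panel blank but never kills the figure."""
    try:
        hook(ax, list(ordered_ids))
    except Exception as exc:  # noqa: BLE001 - user code must not kill the figure
        logger.warning("annotation hook %r failed (%s); panel left empty", name, exc)
        ax.cla()
        _bare(ax)


def make_show_ann_hook(phenotypes: PhenotypeTable,
                       specs: Sequence[AnnotationSpec]) -> list[tuple[str, float, Callable]]:
    """Build the built-in annotation tracks as hook callables.

    Returns (name, height weight, hook) triples; the built-in square and
    scatter tracks go through exactly the same hook interface a user
    function would.
    """
    tracks: list[tuple[str, float, Callable]] = []
    square_cols: list[PhenotypeColumn] = []
    for spec in specs:
        col = phenotypes.column(spec.name)
        if spec.style == "categorical_squares":
            if col.kind != "categorical":
                raise InputError(f"categorical_squares needs a categorical column, "
                                 f"got {spec.name!r}")
            if len(col.levels()) > 2:
                logger.warning("phenotype %r has >2 levels; falling back to color bar",
                               spec.name)
                tracks.append(_color_bar_track(phenotypes, spec))
            else:
                square_cols.append(col)
        elif spec.style == "color_bar":
            tracks.append(_color_bar_track(phenotypes, spec))
        else:
            if col.kind != "continuous":
                raise InputError(f"continuous_scatter needs a continuous column, "
                                 f"got {spec.name!r}")
            tracks.append(_scatter_track(phenotypes, spec))
    if square_cols:
        def hook(ax, ordered_ids, _cols=tuple(square_cols)):
            order = [phenotypes.sample_ids.index(s) for s in ordered_ids]
            render_categorical_squares(ax, _cols, order)
        n_rows = sum(max(len(c.levels()), 1) for c in square_cols)
        tracks.insert(0, ("categorical_squares", 0.6 * n_rows, hook))
    return tracks


def _color_bar_track(phenotypes: PhenotypeTable, spec: AnnotationSpec):
    def hook(ax, ordered_ids):
        col = phenotypes.column(spec.name)
        order = [phenotypes.sample_ids.index(s) for s in ordered_ids]
        render_color_bar_track(ax, col, order, spec.level_colors)
    return (f"color_bar:{spec.name}", 0.6, hook)


def _scatter_track(phenotypes: PhenotypeTable, spec: AnnotationSpec):
    def hook(ax, ordered_ids):
        col = phenotypes.column(spec.name)
        order = [phenotypes.sample_ids.index(s) for s in ordered_ids]
        render_continuous_scatter(ax, col, order, spec.axis_range)
    return (f"scatter:{spec.name}", 2.0, hook)


# ---------------------------------------------------------------------------
# full-figure composition

@dataclass
class HeatmapLayout:
    """Panel rectangles in figure fractions plus display metadata."""

    panels: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)
    groups: list[dict] = field(default_factory=list)
    n_rows: int = 0
    n_cols: int = 0

    def to_dict(self) -> dict:
        return {
            "panels": {k: list(v) for k, v in self.panels.items()},
            "row_order": self.row_order, "col_order": self.col_order,
            "groups": self.groups, "n_rows": self.n_rows, "n_cols": self.n_cols,
        }


def _check_overlap(panels: dict[str, tuple[float, float, float, float]]) -> None:
    items = list(panels.items())
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            (x0, y0, w0, h0), (x1, y1, w1, h1) = items[a][1], items[b][1]
            eps = 1e-9
            if (x0 < x1 + w1 - eps and x1 < x0 + w0 - eps and
                    y0 < y1 + h1 - eps and y1 < y0 + h0 - eps):
                raise InputError(f"layout panels overlap: {items[a][0]} / {items[b][0]}")


def render_heatmap(
    m: ExpressionMatrix,
    row_tree: Dendrogram | None = None,
    col_tree: Dendrogram | None = None,
    scale: ColorScale | None = None,
    phenotypes: PhenotypeTable | None = None,
    annotations: Sequence[AnnotationSpec] | None = None,
    custom_hooks: Sequence[tuple[str, Callable]] | None = None,
    cut: CutResult | None = None,
    row_colors: dict[str, list[str]] | None = None,
    out: str = "heatmap.png",
    fmt: str | None = None,
    show_row_dendrogram: bool = True,
    show_col_dendrogram: bool = True,
    show_row_labels: bool = False,
    col_side_width: float = 1.2,
    margins: tuple[float, float] = (7, 0),
    figsize: tuple[float, float] | None = None,
    dpi: int = 100,
) -> HeatmapLayout:
    """Compose and write the full clustered-heatmap figure.

    The matrix is drawn in the trees' leaf orders (columns left-to-right,
    rows top-to-bottom); hiding a dendrogram suppresses the tree panel but
    keeps its ordering.  ``margins`` is the (bottom, right) pair in
    character-width units.  Returns the layout, also written as JSON next
    to the figure.
    """
    if fmt is None:
        fmt = out.rsplit(".", 1)[-1].lower() if "." in out else "png"
    if fmt not in FORMATS:
        raise InputError(f"unknown output format {fmt!r}")

    row_order = list(row_tree.leaf_order) if row_tree is not None else list(range(m.n_genes))
    col_order = list(col_tree.leaf_order) if col_tree is not None else list(range(m.n_samples))
    if row_tree is not None and list(row_tree.labels) != list(m.row_labels):
        raise InputError("row tree labels do not match matrix row labels")
    if col_tree is not None and list(col_tree.labels) != list(m.col_labels):
        raise InputError("column tree labels do not match matrix column labels")
    ordered_cols = [m.col_labels[j] for j in col_order]
    ordered_rows = [m.row_labels[i] for i in row_order]
    body = m.values[np.ix_(row_order, col_order)]
    if scale is None:
        scale = build_scale(m.values)
    if phenotypes is not None:
        phenotypes = phenotypes.reconcile(list(m.col_labels))

    tracks: list[tuple[str, float, Callable]] = []
    if phenotypes is not None and annotations:
        tracks.extend(make_show_ann_hook(phenotypes, annotations))
    for name, hook in (custom_hooks or []):
        tracks.append((name, 1.0, hook))

    nr, nc = body.shape
    if figsize is None:
        figsize = (min(3.0 + 0.14 * nc, 14.0), min(3.0 + 0.05 * nr, 12.0))

    # --- layout (figure fractions) ---
    bottom = min(0.02 + 0.012 * margins[0], 0.25)
    right = min(0.03 + 0.010 * margins[1], 0.25) + (0.05 if any(
        t[0].startswith("scatter:") for t in tracks) else 0.0)
    left_edge = 0.02
    row_dendro_w = 0.12 if (row_tree is not None and show_row_dendrogram) else 0.0
    row_colors_w = 0.022 * len(row_colors) if row_colors else 0.0
    col_dendro_h = 0.16 if (col_tree is not None and show_col_dendrogram) else 0.0
    group_bar_h = 0.02 if cut is not None else 0.0
    track_weight = sum(w for _, w, _ in tracks)
    ann_h = min(0.045 * track_weight * (col_side_width / 1.2), 0.32) if tracks else 0.0
    label_w = 0.08 if show_row_labels else 0.0

    body_x0 = left_edge + row_dendro_w + row_colors_w
    body_w = 1.0 - body_x0 - right - label_w
    body_y0 = bottom
    body_h = 1.0 - bottom - 0.02 - col_dendro_h - group_bar_h - ann_h
    if body_w <= 0 or body_h <= 0:
        raise InputError("margins leave no room for the heatmap body")

    panels: dict[str, tuple[float, float, float, float]] = {
        "body": (body_x0, body_y0, body_w, body_h)}
    y = body_y0 + body_h
    if tracks:
        panels["annotation_block"] = (body_x0, y, body_w, ann_h)
        y += ann_h
    if cut is not None:
        panels["group_bar"] = (body_x0, y, body_w, group_bar_h)
        y += group_bar_h
    if col_dendro_h:
        panels["col_dendrogram"] = (body_x0, y, body_w, col_dendro_h)
    if row_dendro_w:
        panels["row_dendrogram"] = (left_edge, body_y0, row_dendro_w, body_h)
    if row_colors_w:
        panels["row_colors"] = (left_edge + row_dendro_w, body_y0, row_colors_w, body_h)
    panels["legend"] = (0.02, 0.90, 0.14, 0.04)
    _check_overlap({k: v for k, v in panels.items() if k != "legend"})

    fig = plt.figure(figsize=figsize, dpi=dpi)
    ax_body = fig.add_axes(panels["body"])
    _draw_body(ax_body, body, scale)
    if show_row_labels:
        ax_body.set_yticks([nr - 1 - i + 0.5 for i in range(nr)])
        ax_body.set_yticklabels(ordered_rows, fontsize=5)
        ax_body.yaxis.tick_right()
        ax_body.tick_params(length=0)
    ax_body.set_xticks([i + 0.5 for i in range(nc)])
    ax_body.set_xticklabels(ordered_cols, rotation=90, fontsize=5)
    ax_body.tick_params(length=0)

    if "col_dendrogram" in panels:
        _draw_dendrogram(fig.add_axes(panels["col_dendrogram"]), col_tree, "top")
    if "row_dendrogram" in panels:
        _draw_dendrogram(fig.add_axes(panels["row_dendrogram"]), row_tree, "left")
    if "group_bar" in panels:
        render_group_bar(fig.add_axes(panels["group_bar"]), cut)
    if "row_colors" in panels:
        ax_rc = fig.add_axes(panels["row_colors"])
        ntr = len(row_colors)
        for t, (tname, colors) in enumerate(row_colors.items()):
            if len(colors) != m.n_genes:
                raise InputError(f"row color track {tname!r} has {len(colors)} entries "
                                 f"for {m.n_genes} rows")
            for yy, i in enumerate(row_order):
                ax_rc.add_patch(Rectangle((t, nr - 1 - yy), 1, 1, facecolor=colors[i],
                                          edgecolor="none", antialiased=False))
        ax_rc.set_xlim(0, ntr)
        ax_rc.set_ylim(0, nr)
        _bare(ax_rc)
    if tracks:
        x0, y0, w, h = panels["annotation_block"]
        yy = y0 + h
        for name, weight, hook in tracks:
            th = h * weight / track_weight
            yy -= th
            ax_t = fig.add_axes((x0, yy, w, th))
            _run_hook(ax_t, hook, ordered_cols, name)
    render_legend_colorbar(fig.add_axes(panels["legend"]), scale)

    try:
        fig.savefig(out, format=fmt, dpi=dpi)
    except OSError as exc:
        plt.close(fig)
        raise InputError(f"cannot write figure to {out}: {exc}") from exc
    plt.close(fig)

    layout = HeatmapLayout(
        panels=panels, row_order=ordered_rows, col_order=ordered_cols,
        groups=([] if cut is None else [
            {"group": g + 1, "size": len(leaves), "color": cut.group_colors[g],
             "members": [cut.sample_ids[i] for i in leaves]}
            for g, leaves in enumerate(cut.group_order)]),
        n_rows=nr, n_cols=nc,
    )
    with open(str(out) + ".layout.json", "w", encoding="utf-8") as fh:
        json.dump(layout.to_dict(), fh, indent=2)
    return layout


def render_dendrogram_panels(
    m: ExpressionMatrix,
    top_ns: Sequence[int],
    cutoff: float = 0.85,
    relative: bool = True,
    metric: DistanceMetric = "pearson_centered",
    linkage: Linkage = "complete",
    out: str = "dendrograms.png",
    fmt: str | None = None,
    dpi: int = 100,
) -> list[tuple[int, Dendrogram, CutResult]]:
    """Multi-panel dendrogram comparison across top-N gene selections.

    For each N the N most variable genes are selected, the sample
    clustering re-run, and the tree drawn with its own cut-group bar;
    sample labels are shared on the bottom panel.  Duplicate N values are
    de-duplicated with a warning.
    """
    seen: list[int] = []
    for n in top_ns:
        if n in seen:
            logger.warning("duplicate top-N value %d dropped", n)
        else:
            seen.append(n)
    for n in seen:
        if n > m.n_genes:
            raise InputError(f"top-N {n} exceeds {m.n_genes} rows")
    if fmt is None:
        fmt = out.rsplit(".", 1)[-1].lower() if "." in out else "png"

    results: list[tuple[int, Dendrogram, CutResult]] = []
    npanels = len(seen)
    fig, axes = plt.subplots(npanels * 2, 1, figsize=(10, 2.6 * npanels), dpi=dpi,
                             gridspec_kw={"height_ratios": [8, 1] * npanels,
                                          "hspace": 0.15})
    axes = np.atleast_1d(axes)
    for p, n in enumerate(seen):
        sub = top_n_by_sd(m, n)
        tree = agglomerate(distance_matrix(sub, "columns", metric), linkage)
        cut = cut_tree(tree, cutoff, relative)
        ax_tree, ax_bar = axes[2 * p], axes[2 * p + 1]
        _draw_dendrogram(ax_tree, tree, "top")
        ax_tree.set_title(f"top {n} genes" if n < m.n_genes else "all genes", fontsize=8)
        reordered_cut = CutResult(
            cut.cut_height, cut.sample_ids, cut.groups, cut.group_order, cut.group_colors)
        render_group_bar(ax_bar, reordered_cut)
        if p == npanels - 1:
            ax_bar.set_xticks([i + 0.5 for i in range(tree.n_leaves)])
            ax_bar.set_xticklabels(tree.ordered_labels(), rotation=90, fontsize=5)
            ax_bar.tick_params(length=0)
        results.append((n, tree, cut))
    fig.savefig(out, format=fmt, dpi=dpi)
    plt.close(fig)

    meta = [{"top_n": n,
             "leaf_order": t.ordered_labels(),
             "groups": [len(g) for g in c.group_order]} for n, t, c in results]
    with open(str(out) + ".layout.json", "w", encoding="utf-8") as fh:
        json.dump({"panels": meta}, fh, indent=2)
    return results
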