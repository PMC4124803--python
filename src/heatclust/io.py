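"""Reading and writing every external representation the toolkit touches.

Expression matrices and phenotype tables come in as delimited text
(genes in rows by default, matching the common counts-matrix layout);
trees go out as Newick; association reports go out as TSV (human) or
JSON (machine, full precision).

Missing values: ``NA`` and the empty string are accepted on input and
``NA`` is written on output, matching the files R users bring.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("heatclust")

MISSING_TOKENS = ("NA", "")
MISSING_OUT = "NA"


# ---------------------------------------------------------------------------
# errors

class HeatclustError(Exception):
    """Base class for all toolkit errors."""


class InputError(HeatclustError):
    """Invalid or malformed user input (exit code 2 at the CLI)."""


class LabeledInputError(InputError):
    """Duplicate or otherwise invalid row/column labels."""


class EmptyInputError(InputError):
    """A matrix or table with no usable content."""


class ReconciliationError(InputError):
    """Sample identifiers that cannot be matched between inputs."""


class ComputationError(HeatclustError):
    """A computation could not be carried out (exit code 3 at the CLI)."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ExpressionMatrix:
    """Labeled numeric matrix, rows = genes, columns = samples.

    Values are unitless expression measures (typically log2 scale).
    Entries may be NaN (missing) but never infinite.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if self.values.ndim != 2:
            raise InputError("expression matrix must be two-dimensional")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_labels)} row labels x {len(self.col_labels)} column labels"
            )
        if self.values.size == 0:
            raise EmptyInputError("expression matrix is empty")
        _check_unique(self.row_labels, "gene")
        _check_unique(self.col_labels, "sample")
        if np.isinf(self.values).any():
            raise InputError("expression matrix contains infinite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


@dataclass
class PhenotypeColumn:
    """One per-sample annotation column, typed categorical or continuous."""

    name: str
    kind: Literal["categorical", "continuous"]
    values: list  # str|None for categorical, float (NaN = missing) for continuous

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise InputError(f"unknown phenotype kind {self.kind!r} for column {self.name!r}")
        if self.kind == "continuous":
            self.values = [float(v) if v is not None else math.nan for v in self.values]

    def missing_mask(self) -> np.ndarray:
        if self.kind == "continuous":
            return np.isnan(np.asarray(self.values, dtype=float))
        return np.array([v is None for v in self.values])

    def levels(self) -> list[str]:
        if self.kind != "categorical":
            raise InputError(f"column {self.name!r} is not categorical")
        seen: dict[str, None] = {}
        for v in self.values:
            if v is not None:
                seen.setdefault(str(v))
        return sorted(seen)


@dataclass
class PhenotypeTable:
    """Per-sample annotation columns, aligned on a shared sample-id list."""

    sample_ids: list[str]
    columns: list[PhenotypeColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        for col in self.columns:
            if len(col.values) != len(self.sample_ids):
                raise InputError(
                    f"phenotype column {col.name!r} has {len(col.values)} values "
                    f"for {len(self.sample_ids)} samples"
                )

    def column(self, name: str) -> PhenotypeColumn:
        for col in self.columns:
            if col.name == name:
                return col
        raise InputError(f"no phenotype column named {name!r}")

    def reconcile(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Reorder to the given sample ids; every id must be present here."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ReconciliationError(
                f"samples absent from phenotype table: {', '.join(missing)}"
            )
        order = [index[s] for s in sample_ids]
        cols = [
            PhenotypeColumn(c.name, c.kind, [c.values[i] for i in order])
            for c in self.columns
        ]
        return PhenotypeTable(list(sample_ids), cols)


# --- association report -----------------------------------------------------

@dataclass
class CategoricalSummary:
    """Per-group level counts for one categorical phenotype.

    ``counts[i][j]`` is the number of non-missing samples with level i in
    group j.  ``positive_percent`` is the per-group fraction carrying the
    designated positive level (None when no positive level applies).
    """

    levels: list[str]
    counts: np.ndarray  # (n_levels, n_groups) int
    positive_level: str | None = None
    positive_percent: list[float] | None = None


CONTINUOUS_STATS = ("min", "q1", "median", "mean", "q3", "max")


@dataclass
class ContinuousSummary:
    """Six-number summary per group: min, Q1, median, mean, Q3, max."""

    stats: list[dict[str, float]]  # one dict per group, keys CONTINUOUS_STATS


@dataclass
class PhenotypeAssociation:
    name: str
    kind: str
    summary: CategoricalSummary | ContinuousSummary
    test_name: str
    statistic: float | None
    df: tuple[int, ...]  # (df,) for chi-square, (df_between, df_within) for ANOVA
    p_value: float | None
    note: str = ""


@dataclass
class AssociationReport:
    """Machine form of the per-group phenotype/cluster association tables."""

    group_labels: list[str]
    entries: list[PhenotypeAssociation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# matrix / phenotype readers and writers

def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise LabeledInputError(f"duplicate {what} labels: {', '.join(sorted(set(dups)))}")


def read_matrix(path, delimiter: str = "\t", genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a labeled expression matrix from delimited text.

    First row holds sample labels and first column gene labels (swap the
    roles with ``genes_in_rows=False``).  Non-numeric cells other than the
    missing tokens are rejected.
    """
    try:
        df = pd.read_csv(
            path, sep=delimiter, index_col=0, header=0,
            na_values=list(MISSING_TOKENS), keep_default_na=False,
            dtype=str, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty matrix file") from exc
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: parse error ({exc})") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyInputError(f"{path}: matrix has no data cells")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise InputError(
                f"{path}: non-numeric cell in column {col!r}: {exc}"
            ) from exc
    m = ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if not genes_in_rows:
        m = ExpressionMatrix(m.values.T, m.col_labels, m.row_labels)
    n_missing = int(np.isnan(m.values).sum())
    if n_missing:
        logger.warning("%s: %d missing values in expression matrix", path, n_missing)
    return m


def write_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    df = m.to_frame()
    df.to_csv(path, sep=delimiter, na_rep=MISSING_OUT)


def read_phenotypes(path, type_spec: dict[str, str], delimiter: str = ",",
                    sample_col: str | None = None) -> PhenotypeTable:
    """Read a phenotype table; ``type_spec`` maps column name -> kind.

    The sample-id column is the first column unless ``sample_col`` names it.
    Only columns listed in ``type_spec`` are kept.  Unparseable continuous
    entries become missing, with a logged warning per column.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, dtype=str,
                         na_values=list(MISSING_TOKENS), keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty phenotype file") from exc
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: parse error ({exc})") from exc
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: phenotype table has no rows")
    if sample_col is None:
        sample_col = df.columns[0]
    if sample_col not in df.columns:
        raise InputError(f"{path}: sample-id column {sample_col!r} not found")
    unknown = [c for c in type_spec if c not in df.columns]
    if unknown:
        raise InputError(f"{path}: type_spec names absent columns: {', '.join(unknown)}")
    sample_ids = list(df[sample_col].astype(str))
    cols: list[PhenotypeColumn] = []
    for name, kind in type_spec.items():
        raw = df[name]
        if kind == "continuous":
            parsed = pd.to_numeric(raw, errors="coerce")
            bad = int((parsed.isna() & raw.notna()).sum())
            if bad:
                logger.warning("%s: column %r: %d unparseable continuous entries set to missing",
                               path, name, bad)
            n_missing = int(parsed.isna().sum())
            if n_missing:
                logger.info("%s: column %r: %d missing values", path, name, n_missing)
            cols.append(PhenotypeColumn(name, "continuous", list(parsed.astype(float))))
        elif kind == "categorical":
            vals = [None if pd.isna(v) else str(v) for v in raw]
            cols.append(PhenotypeColumn(name, "categorical", vals))
        else:
            raise InputError(f"unknown kind {kind!r} for column {name!r}")
    return PhenotypeTable(sample_ids, cols)


def write_phenotypes(ph: PhenotypeTable, path, delimiter: str = ",") -> None:
    data = {"sample": ph.sample_ids}
    for col in ph.columns:
        if col.kind == "continuous":
            data[col.name] = [MISSING_OUT if math.isnan(v) else repr(v) for v in col.values]
        else:
            data[col.name] = [MISSING_OUT if v is None else v for v in col.values]
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Newick export

def _newick_label(label: str) -> str:
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree) -> str:
    """Serialize a dendrogram as a Newick string.

    Leaves sit at height 0; each branch length is the parent's merge
    height minus the child's (negative for linkage inversions, which are
    kept as computed).
    """
    n = tree.n_leaves
    if n == 0:
        raise InputError("cannot serialize an empty tree")
    if n == 1:
        return _newick_label(tree.labels[0]) + ";"

    heights = tree.node_heights()

    def emit(node: int, parent_h: float) -> str:
        blen = parent_h - heights[node]
        if node < n:
            return f"{_newick_label(tree.labels[node])}:{blen:.17g}"
        left, right = tree.merges[node - n]
        h = heights[node]
        return f"({emit(int(left), h)},{emit(int(right), h)}):{blen:.17g}"

    root = n + tree.merges.shape[0] - 1
    left, right = tree.merges[-1]
    h = heights[root]
    return f"({emit(int(left), h)},{emit(int(right), h)});"


# ---------------------------------------------------------------------------
# association report writers

def _fmt_p(p: float | None, decimals: int = 3) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return MISSING_OUT
    return f"{p:.{decimals}f}"


def _summary_text(entry: PhenotypeAssociation) -> str:
    s = entry.summary
    if isinstance(s, CategoricalSummary):
        parts = [
            f"{lev}:" + "/".join(str(int(c)) for c in s.counts[i])
            for i, lev in enumerate(s.levels)
        ]
        if s.positive_percent is not None:
            parts.append("positive_percent:" +
                         "/".join(f"{p:.2f}" for p in s.positive_percent))
        return ";".join(parts)
    parts = []
    for stat in CONTINUOUS_STATS:
        vals = "/".join(
            MISSING_OUT if math.isnan(g[stat]) else f"{g[stat]:g}" for g in s.stats
        )
        parts.append(f"{stat}:{vals}")
    return ";".join(parts)


REPORT_COLUMNS = ("phenotype", "kind", "test", "statistic", "df", "p_value", "groups", "summary")


def write_report(report: AssociationReport, path, format: Literal["tsv", "json"] = "tsv") -> None:
    """Write an association report; TSV rounds p to 3 decimals, JSON keeps full precision."""
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for e in report.entries:
                stat = MISSING_OUT if e.statistic is None else f"{e.statistic:.4g}"
                fh.write("\t".join([
                    e.name, e.kind, e.test_name, stat,
                    ",".join(str(d) for d in e.df) or MISSING_OUT,
                    _fmt_p(e.p_value),
                    ",".join(report.group_labels),
                    _summary_text(e),
                ]) + "\n")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
            fh.write("\n")
    else:
        raise InputError(f"unknown report format {format!r}")


def report_to_dict(report: AssociationReport) -> dict:
    out = {"group_labels": list(report.group_labels), "phenotypes": []}
    for e in report.entries:
        d: dict = {
            "name": e.name, "kind": e.kind, "test": e.test_name,
            "statistic": _none_if_nan(e.statistic),
            "df": list(e.df),
            "p_value": _none_if_nan(e.p_value),
            "note": e.note,
        }
        s = e.summary
        if isinstance(s, CategoricalSummary):
            d["summary"] = {
                "levels": list(s.levels),
                "counts": [[int(c) for c in row] for row in s.counts],
                "positive_level": s.positive_level,
                "positive_percent": (None if s.positive_percent is None
                                     else [float(p) for p in s.positive_percent]),
            }
        else:
            d["summary"] = {
                "stats": [{k: _none_if_nan(g[k]) for k in CONTINUOUS_STATS} for g in s.stats]
            }
        out["phenotypes"].append(d)
    return out


def report_from_dict(d: dict) -> AssociationReport:
    entries = []
    for e in d["phenotypes"]:
        s = e["summary"]
        if "levels" in s:
            summary: CategoricalSummary | ContinuousSummary = CategoricalSummary(
                levels=list(s["levels"]),
                counts=np.asarray(s["counts"], dtype=int),
                positive_level=s["positive_level"],
                positive_percent=s["positive_percent"],
            )
        else:
            summary = ContinuousSummary(
                stats=[{k: _nan_if_none(g[k]) for k in CONTINUOUS_STATS} for g in s["stats"]]
            )
        entries.append(PhenotypeAssociation(
            name=e["name"], kind=e["kind"], summary=summary, test_name=e["test"],
            statistic=_nan_if_none(e["statistic"], allow_none=True),
            df=tuple(e["df"]),
            p_value=_nan_if_none(e["p_value"], allow_none=True),
            note=e.get("note", ""),
        ))
    return AssociationReport(group_labels=list(d["group_labels"]), entries=entries)


def _none_if_nan(v):
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v


def _nan_if_none(v, allow_none: bool = False):
    if v is None:
        return None if allow_none else math.nan
    return float(v)


def write_assignments(sample_ids: Sequence[str], groups: Sequence[int], path) -> None:
    """Write the sample -> cut-group assignment as two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s, g in zip(sample_ids, groups):
            fh.write(f"{s}\t{int(g) + 1}\n")
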