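"""Sample × feature tables of VOC detections.

The universal currency of the pipeline is a :class:`FeatureTable`: one row per
urine sample, one column per volatile organic compound (VOC), holding either
relative abundances or {0,1} presence flags, together with a two-class label
(cancer / control) and optional continuous covariates such as serum PSA in
ng/mL.

Two preprocessing steps live here because they define the modelling data set:

* :func:`binarize` — presence is *abundance strictly greater than a threshold*
  (default 0); any positive abundance in a processed GC-MS table counts as
  "detected".
* :func:`prevalence_filter` — the dual prevalence rule: a compound is dropped
  as *rare* when detected in fewer than 20% of patients in **both** groups,
  and as *common* when detected in more than 90% of patients in **both**
  groups.  Both comparisons are strict and always per class, never pooled.

Missing cells are rejected outright; there is no imputation procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "FilterReport",
    "TableFormatError",
    "TableValidationError",
    "ContractError",
    "read_feature_table",
    "write_feature_table",
    "binarize",
    "prevalence_filter",
]


class TableFormatError(ValueError):
    """The input file cannot be interpreted as a cohort table."""


class TableValidationError(ValueError):
    """The table violates a FeatureTable invariant."""


class ContractError(ValueError):
    """An operation was called on a table that does not satisfy its precondition."""


@dataclass
class FeatureTable:
    """A validated sample × feature matrix with labels and covariates.

    Parameters
    ----------
    values : pandas.DataFrame
        Samples in rows (index = sample ids), VOC features in columns.
        Non-negative abundances, or {0,1} flags when ``binary`` is True.
    labels : pandas.Series
        Per-sample class, exactly two distinct values (e.g. ``cancer`` /
        ``control``), index aligned with ``values``.
    covariates : pandas.DataFrame
        Named continuous per-sample vectors (e.g. ``psa``); may be empty.
    binary : bool
        Whether ``values`` holds presence flags.
    """

    values: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame = None  # type: ignore[assignment]
    binary: bool = False

    def __post_init__(self) -> None:
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.values.index)
        self._validate()

    def _validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise TableValidationError("duplicate feature names")
        if not self.labels.index.equals(idx) or not self.covariates.index.equals(idx):
            raise TableValidationError("labels/covariates not aligned with samples")
        overlap = set(self.values.columns) & set(self.covariates.columns)
        if overlap:
            raise TableValidationError(f"names used as both feature and covariate: {sorted(overlap)}")
        classes = pd.unique(self.labels)
        if len(classes) != 2:
            raise TableValidationError(
                f"exactly two classes required, found {len(classes)}: {list(classes)[:5]}"
            )
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("feature values must be numeric")
        if arr.size and np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise TableValidationError(
                f"missing value at sample {idx[r]!r}, feature {self.values.columns[c]!r}"
            )
        if self.covariates.size and np.isnan(self.covariates.to_numpy(float)).any():
            raise TableValidationError("missing covariate value")
        if self.binary and arr.size and not np.isin(arr, (0, 1)).all():
            raise TableValidationError("binary table contains values outside {0, 1}")

    # -- conveniences -----------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple:
        """The two class labels, sorted."""
        return tuple(sorted(pd.unique(self.labels)))

    def class_counts(self) -> dict:
        return self.labels.value_counts().to_dict()

    def design_matrix(self, feature_set: Sequence[str]) -> pd.DataFrame:
        """Columns of ``values`` and ``covariates`` selected by name, in the given order."""
        cols = []
        for name in feature_set:
            if name in self.values.columns:
                cols.append(self.values[name])
            elif name in self.covariates.columns:
                cols.append(self.covariates[name])
            else:
                raise KeyError(f"unknown feature or covariate: {name!r}")
        if not cols:
            raise ValueError("empty feature set")
        return pd.concat(cols, axis=1)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        return replace(self, values=self.values[list(names)])


@dataclass
class FilterReport:
    """Outcome of the dual prevalence filter.

    ``kept``, ``removed_rare`` and ``removed_common`` partition the original
    feature list; ``prevalence`` holds the exact per-class detection fraction
    (features × classes).
    """

    kept: list[str]
    removed_rare: list[str]
    removed_common: list[str]
    prevalence: pd.DataFrame
    low: float
    high: float

    def to_frame(self) -> pd.DataFrame:
        status = {}
        for f in self.kept:
            status[f] = "kept"
        for f in self.removed_rare:
            status[f] = "removed_rare"
        for f in self.removed_common:
            status[f] = "removed_common"
        out = self.prevalence.copy()
        out.insert(0, "status", [status[f] for f in out.index])
        return out


# -- I/O -------------------------------------------------------------------

def read_feature_table(
    path,
    label_column: str = "class",
    covariate_columns: Iterable[str] = (),
    sample_id_column: str = "sample_id",
) -> FeatureTable:
    """Read a cohort CSV (RFC-4180, header row) into a FeatureTable.

    One sample per row.  The sample-id column (``sample_id`` by default, else
    the first column), the label column, and any declared covariate columns
    are routed out of the matrix; every remaining column is a feature.
    Column order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.columns.size == 0:
        raise TableFormatError("empty file")
    if label_column not in df.columns:
        raise TableFormatError(f"missing label column {label_column!r}")
    id_col = sample_id_column if sample_id_column in df.columns else df.columns[0]
    if id_col == label_column:
        raise TableFormatError("cannot use the label column as sample ids")
    covariate_columns = list(covariate_columns)
    for c in covariate_columns:
        if c not in df.columns:
            raise TableFormatError(f"missing covariate column {c!r}")
    df = df.set_index(id_col)
    labels = df[label_column]
    feature_cols = [c for c in df.columns if c != label_column and c not in covariate_columns]

    def _numeric(block: pd.DataFrame, what: str) -> pd.DataFrame:
        out = block.apply(pd.to_numeric, errors="coerce")
        bad = out.isna() & block.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise TableFormatError(
                f"non-numeric {what} cell at sample {block.index[r]!r}, column {block.columns[c]!r}: "
                f"{block.iat[r, c]!r}"
            )
        return out

    values = _numeric(df[feature_cols], "feature")
    covs = _numeric(df[covariate_columns], "covariate") if covariate_columns else None
    arr = values.to_numpy(float)
    binary = bool(arr.size) and bool(np.isin(arr, (0.0, 1.0)).all())
    return FeatureTable(values=values, labels=labels, covariates=covs, binary=binary)


def write_feature_table(table: FeatureTable, path, label_column: str = "class") -> None:
    """Write the standard cohort CSV dialect (sample_id, class, covariates, features)."""
    out = pd.DataFrame(index=table.values.index)
    out[label_column] = table.labels
    for c in table.covariates.columns:
        out[c] = table.covariates[c]
    for c in table.values.columns:
        out[c] = table.values[c]
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path)


# -- preprocessing ---------------------------------------------------------

def binarize(table: FeatureTable, threshold: float = 0.0) -> FeatureTable:
    """Convert abundances to presence/absence: 1 where value > threshold, else 0.

    Idempotent at threshold 0; the boundary is excluded by the strict
    inequality (an abundance exactly equal to the threshold maps to 0).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    flags = (table.values > threshold).astype(np.int8)
    return replace(table, values=flags, binary=True)


def prevalence_filter(
    table: FeatureTable, low: float = 0.20, high: float = 0.90
) -> tuple[FeatureTable, FilterReport]:
    """Remove compounds rare in both groups (< ``low``) or common in both (> ``high``).

    Prevalence is the exact detection fraction within each class.  A feature
    is removed only when the condition holds in *both* classes; boundaries
    are strict on both sides (prevalence exactly ``low`` or ``high`` is kept).
    Feature order of the kept set is preserved.
    """
    if not table.binary:
        raise ContractError("prevalence_filter requires a binary table (run binarize first)")
    if not (0 <= low < high <= 1):
        raise ValueError(f"require 0 <= low < high <= 1, got low={low}, high={high}")
    classes = table.classes
    prev = pd.DataFrame(
        {cls: table.values[table.labels == cls].mean(axis=0) for cls in classes}
    )
    arr = prev.to_numpy()
    rare = (arr < low).all(axis=1)
    common = (arr > high).all(axis=1)
    names = np.asarray(table.feature_names, dtype=object)
    report = FilterReport(
        kept=list(names[~rare & ~common]),
        removed_rare=list(names[rare]),
        removed_common=list(names[common]),
        prevalence=prev,
        low=low,
        high=high,
    )
    return table.subset_features(report.kept), report
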