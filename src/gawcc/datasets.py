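"""Dataset container and tabular I/O.

A :class:`FeatureTable` is the universe a feature selector searches over: a
numeric samples x features matrix, a label vector (categorical for
classification, real for regression) and per-feature names.  Missing feature
values are carried as NaN until :func:`canonicalize` resolves them.

Feature indices are 1-based in every external interface (reports, CLI, logs);
internally the matrix is addressed 0-based and conversion happens at the
boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = [
    "FeatureTable",
    "read_table",
    "canonicalize",
    "write_report",
    "read_report",
    "DegenerateDatasetError",
]

#: cell contents treated as missing markers in CSV input
_MISSING_MARKERS = {"?", "", "na", "n/a", "nan", "null"}

CLASSIFICATION = "classification"
REGRESSION = "regression"


class DegenerateDatasetError(ValueError):
    """Raised when canonicalization would leave an unusable table."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix plus labels.

    Parameters
    ----------
    matrix:
        ``(n_samples, n_features)`` float array; NaN marks a missing value.
    labels:
        Length ``n_samples`` array. Categorical (any dtype, >=2 distinct
        values) for classification; float for regression.
    feature_names:
        Unique names, one per column.
    task:
        ``"classification"`` or ``"regression"``.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    task: str

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if matrix.shape[0] != labels.shape[0]:
            raise ValueError(
                f"row count {matrix.shape[0]} != label count {labels.shape[0]}"
            )
        if len(self.feature_names) != matrix.shape[1]:
            raise ValueError("feature_names length must equal column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == CLASSIFICATION:
            if len(np.unique(labels)) < 2:
                raise ValueError("classification needs >=2 distinct labels")
        else:
            if not np.issubdtype(labels.dtype, np.number):
                raise ValueError("regression labels must be numeric")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    def columns(self, indices_1based: Sequence[int]) -> np.ndarray:
        """Column slice by 1-based feature indices."""
        idx = np.asarray(list(indices_1based), dtype=int) - 1
        if idx.size == 0:
            raise ValueError("empty index set")
        if idx.min() < 0 or idx.max() >= self.n_features:
            raise IndexError(
                f"feature index out of range 1..{self.n_features}"
            )
        return self.matrix[:, idx]

    def subset(self, indices_1based: Sequence[int]) -> "FeatureTable":
        """New table restricted to the given 1-based feature columns."""
        idx = sorted(set(int(i) for i in indices_1based))
        mat = self.columns(idx)
        names = tuple(self.feature_names[i - 1] for i in idx)
        return FeatureTable(mat, self.labels, names, self.task)


def _coerce_numeric(series: pd.Series, col: str) -> np.ndarray:
    """Feature column -> float array with NaN for missing markers.

    Raises a parse error naming the first offending row/column.
    """
    raw = series.astype(object)
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = np.nan
            continue
        s = str(v).strip()
        if s.lower() in _MISSING_MARKERS:
            out[i] = np.nan
            continue
        try:
            out[i] = float(s)
        except ValueError as exc:
            raise ValueError(
                f"non-numeric value {v!r} at row {i}, column {col!r}"
            ) from exc
    return out


def _infer_task(labels: np.ndarray) -> str:
    """Numeric labels with many distinct values -> regression, else classification."""
    if not np.issubdtype(np.asarray(labels).dtype, np.number):
        return CLASSIFICATION
    uniq = np.unique(labels[~pd.isna(labels)])
    if uniq.size <= max(20, int(0.05 * len(labels))) and np.allclose(
        uniq, np.round(uniq)
    ):
        return CLASSIFICATION
    return REGRESSION


def read_table(
    path: str | Path,
    format: str | None = None,
    label_column: str | None = None,
    task: str | None = None,
) -> FeatureTable:
    """Read a CSV or dense ARFF file into a :class:`FeatureTable`.

    ``label_column`` defaults to the last column. Missing markers ("?",
    empty cell, NA) become NaN flags; no rows are dropped. ``task`` is
    inferred from the label dtype when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
    elif format == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:  # scipy returns nominal attributes as bytes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")

    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise KeyError(
            f"label column {label_column!r} not in {list(df.columns)}"
        )

    feature_cols = [c for c in df.columns if c != label_column]
    matrix = np.column_stack(
        [_coerce_numeric(df[c], c) for c in feature_cols]
    ) if feature_cols else np.empty((len(df), 0))

    raw_labels = df[label_column]
    try:
        labels = pd.to_numeric(raw_labels).to_numpy()
    except (ValueError, TypeError):
        labels = raw_labels.astype(str).str.strip().to_numpy()
    if task is None:
        task = _infer_task(labels)
    if task == REGRESSION:
        labels = np.asarray(labels, dtype=float)
    return FeatureTable(matrix, labels, tuple(feature_cols), task)


def canonicalize(
    table: FeatureTable,
    impute: str = "mean",
    scale: str = "none",
) -> FeatureTable:
    """Resolve missing values and optionally rescale feature columns.

    ``impute``: mean | median | drop_row; ``scale``: none | minmax | zscore.
    The label column is untouched. Global imputation; the cross-validated
    scorer re-fits imputation on training folds to avoid leakage, so this
    step mainly serves one-shot model fits and report output.
    Deterministic, idempotent, and a no-op on complete tables with
    ``scale="none"``.
    """
    mat = table.matrix.copy()
    labels = table.labels
    missing = np.isnan(mat)
    if missing.any():
        if impute == "drop_row":
            keep = ~missing.any(axis=1)
            mat, labels = mat[keep], labels[keep]
            if mat.shape[0] == 0:
                raise DegenerateDatasetError("drop_row removed every sample")
            if table.task == CLASSIFICATION and len(np.unique(labels)) < len(
                np.unique(table.labels)
            ):
                raise DegenerateDatasetError(
                    "drop_row removed all samples of a class"
                )
        elif impute in ("mean", "median"):
            agg = np.nanmean if impute == "mean" else np.nanmedian
            for j in range(mat.shape[1]):
                col = mat[:, j]
                if np.isnan(col).all():
                    col[:] = 0.0
                elif np.isnan(col).any():
                    col[np.isnan(col)] = agg(col)
        else:
            raise ValueError(f"unknown impute {impute!r}")

    if scale == "minmax":
        lo, hi = mat.min(axis=0), mat.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)  # constant column -> zeros
        mat = (mat - lo) / span
    elif scale == "zscore":
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant column -> zeros
        mat = (mat - mu) / sd
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")

    return FeatureTable(mat, labels, table.feature_names, table.task)


def write_report(report, path: str | Path) -> None:
    """Serialize an :class:`~gawcc.pipeline.FsReport` as JSON plus a TSV summary.

    The JSON lands at ``path``; a flat ``<stem>.tsv`` summary (one metric per
    row) next to it.  Selected features appear as names and as 1-based
    indices.
    """
    path = Path(path)
    if not report.trajectory:
        raise ValueError("report has an empty trajectory: run never evaluated")
    payload = report.to_dict()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2) + "\n")

    lines = ["key\tvalue"]
    lines.append(f"method\t{payload['method']}")
    lines.append(f"nof\t{payload['nof']}")
    lines.append(
        "selected_indices\t" + ",".join(str(i) for i in payload["selected_indices"])
    )
    lines.append(
        "selected_features\t" + ",".join(payload["selected_features"])
    )
    lines.append(f"fitness\t{payload['fitness']:.6g}")
    for k, v in sorted(payload["metrics"].items()):
        lines.append(f"{k}\t{v:.6g}")
    path.with_suffix(".tsv").write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> dict:
    """Round-trip loader for :func:`write_report` JSON output."""
    return json.loads(Path(path).read_text())
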