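"""Loading and cleaning of response-first numeric tables.

The input convention is a delimited text file with a header row whose FIRST
column is the dependent variable (the modelled endpoint, e.g. -log(LC50))
and whose remaining columns are candidate features (molecular descriptors,
protein abundances, ...).  Columns that are not fully numeric are dropped;
rows with missing values are removed (complete-case analysis).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Tokens recognised as missing values (matched case-insensitively).
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "nan"})


class DatasetError(ValueError):
    """Fatal problem with an input table."""


@dataclass
class RawTable:
    """A delimited table as read from disk, values still text.

    The first column is flagged as the response by convention.
    """

    column_names: list[str]
    columns: list[list[str]]
    n_rows: int

    def __post_init__(self) -> None:
        if len(set(self.column_names)) != len(self.column_names):
            raise DatasetError("duplicate column names in header")
        for name, col in zip(self.column_names, self.columns):
            if len(col) != self.n_rows:
                raise DatasetError(f"column {name!r} has wrong length")


@dataclass
class Dataset:
    """An all-numeric modelling table: response vector + feature matrix.

    ``case_ids`` are ordinal labels assigned at load time; they survive row
    filtering so removed cases can be reported by their original position.
    """

    response_name: str
    y: np.ndarray
    feature_names: list[str]
    X: np.ndarray
    case_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DatasetError("X must be 2-dimensional")
        if len(self.y) != self.X.shape[0]:
            raise DatasetError("length of y must equal rows of X")
        if len(self.feature_names) != self.X.shape[1]:
            raise DatasetError("feature_names must match columns of X")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DatasetError("feature names must be unique")
        if self.response_name in self.feature_names:
            raise DatasetError("response name collides with a feature name")
        if self.case_ids is None:
            self.case_ids = np.arange(len(self.y))
        else:
            self.case_ids = np.asarray(self.case_ids, dtype=int)
            if len(self.case_ids) != len(self.y):
                raise DatasetError("case_ids must match number of rows")

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, ids) -> "Dataset":
        """Rows restricted to the given case ids (order as given)."""
        ids = np.asarray(ids, dtype=int)
        pos = {cid: i for i, cid in enumerate(self.case_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return replace(self, y=self.y[idx], X=self.X[idx], case_ids=ids.copy())

    def subset_features(self, names) -> "Dataset":
        """Columns restricted to the given feature names (order as given)."""
        pos = {n: j for j, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return replace(self, feature_names=list(names), X=self.X[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, self.response_name, self.y)
        df.index = pd.Index(self.case_ids, name="case_id")
        return df

    def write_csv(self, path, delimiter: str = ",") -> None:
        """Write response-first CSV (full float precision, no index)."""
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def load_table(path, delimiter: str = ",") -> RawTable:
    """Read a delimited file with a header row into a :class:`RawTable`.

    Rejects missing files, duplicate header names, ragged rows (reported by
    1-based data-row index), single-column tables and tables with fewer than
    two data rows.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetError(f"empty file: {path}") from None
        header = [h.strip() for h in header]
        if len(header) < 2:
            raise DatasetError("table must have a response column and at least one feature")
        rows = []
        for i, row in enumerate(reader, start=1):
            if not row:
                continue  # ignore trailing blank lines
            if len(row) != len(header):
                raise DatasetError(
                    f"ragged row {i}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append([f.strip() for f in row])
    if len(rows) < 2:
        raise DatasetError("table must have at least two data rows")
    columns = [[row[j] for row in rows] for j in range(len(header))]
    return RawTable(column_names=header, columns=columns, n_rows=len(rows))


def _parse_column(values, missing_tokens) -> np.ndarray | None:
    """Parse a text column to floats; missing tokens become NaN.

    Returns None if any non-missing entry fails to parse (non-numeric column).
    """
    out = np.empty(len(values))
    for i, v in enumerate(values):
        if v.lower() in missing_tokens:
            out[i] = np.nan
            continue
        try:
            out[i] = float(v)
        except ValueError:
            return None
    return out


def coerce_numeric(
    table: RawTable, missing_tokens=DEFAULT_MISSING_TOKENS
) -> tuple[Dataset, list[str]]:
    """Drop non-numeric feature columns and build an all-numeric Dataset.

    The first column is the response and must parse as numeric (missing
    tokens allowed; those rows fall to :func:`drop_missing`).  Every feature
    column with at least one unparseable non-missing entry is dropped and
    reported.  Surviving column order is preserved.
    """
    missing_tokens = frozenset(t.lower() for t in missing_tokens)
    y = _parse_column(table.columns[0], missing_tokens)
    if y is None:
        raise DatasetError(
            f"response column {table.column_names[0]!r} contains non-numeric values"
        )
    kept_names: list[str] = []
    kept_cols: list[np.ndarray] = []
    dropped: list[str] = []
    for name, col in zip(table.column_names[1:], table.columns[1:]):
        parsed = _parse_column(col, missing_tokens)
        if parsed is None:
            dropped.append(name)
        else:
            kept_names.append(name)
            kept_cols.append(parsed)
    if not kept_names:
        raise DatasetError("no numeric feature columns remain")
    X = np.column_stack(kept_cols)
    ds = Dataset(
        response_name=table.column_names[0],
        y=y,
        feature_names=kept_names,
        X=X,
        case_ids=np.arange(table.n_rows),
    )
    return ds, dropped


def drop_missing(ds: Dataset) -> tuple[Dataset, list[int]]:
    """Remove every row with a missing value in y or any feature.

    Complete-case analysis; survivor order preserved.  Idempotent.
    """
    bad = np.isnan(ds.y) | np.isnan(ds.X).any(axis=1)
    if bad.all():
        raise DatasetError("no complete cases remain after missing-value removal")
    removed = [int(c) for c in ds.case_ids[bad]]
    clean = replace(
        ds, y=ds.y[~bad], X=ds.X[~bad], case_ids=ds.case_ids[~bad].copy()
    )
    return clean, removed


def read_dataset(
    path, delimiter: str = ",", missing_tokens=DEFAULT_MISSING_TOKENS
) -> tuple[Dataset, dict]:
    """Convenience: load, coerce and drop missing in one call.

    Non-numeric columns are dropped before row removal so that text-coded
    missing markers in dropped columns cannot delete rows.
    Returns the clean Dataset and a report dict.
    """
    table = load_table(path, delimiter=delimiter)
    ds, dropped_cols = coerce_numeric(table, missing_tokens=missing_tokens)
    ds, removed_rows = drop_missing(ds)
    return ds, {"dropped_columns": dropped_cols, "removed_rows": removed_rows}
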