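"""Labeled matrix I/O as delimited text.

Matrices travel as comma- or tab-delimited files with a header row of column
ids and a first column of row ids.  Reading validates rectangularity,
numeric cells, finiteness and id uniqueness, and names the offending
row/column on failure; writing uses 17 significant digits so a write/read
round trip preserves every float bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "align_rows", "align_columns"]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled numeric matrix (row ids in column 1, column ids in row 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed delimited file: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dup}")
    bad_cols = [c for c in df.columns
                if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        raise ValueError(f"{path}: non-numeric cells in column(s) {bad_cols}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}; impute or drop upstream")
    df = df.astype(float)
    if not np.all(np.isfinite(df.to_numpy())):
        r, c = np.argwhere(~np.isfinite(df.to_numpy()))[0]
        raise ValueError(f"{path}: non-finite value at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r}")
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a labeled matrix with round-trip-exact float formatting."""
    path = Path(path)
    pd.DataFrame(df).to_csv(path, sep=sep, float_format="%.17g")


def _align(df: pd.DataFrame, ids, axis: str, name: str, other: str) -> pd.DataFrame:
    have = df.index if axis == "rows" else df.columns
    missing = [i for i in ids if i not in set(have)]
    extra = [i for i in have if i not in set(ids)]
    if missing or extra:
        raise ValueError(
            f"{axis} of {name} do not match {other}: "
            f"missing {missing[:10]}, unexpected {extra[:10]}")
    return df.loc[list(ids)] if axis == "rows" else df[list(ids)]


def align_rows(df: pd.DataFrame, row_ids, name: str = "matrix",
               other: str = "reference") -> pd.DataFrame:
    """Reorder rows to ``row_ids``; error (listing ids) on any mismatch."""
    return _align(df, list(row_ids), "rows", name, other)


def align_columns(df: pd.DataFrame, col_ids, name: str = "matrix",
                  other: str = "reference") -> pd.DataFrame:
    """Reorder columns to ``col_ids``; error (listing ids) on any mismatch."""
    return _align(df, list(col_ids), "columns", name, other)
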