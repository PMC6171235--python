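"""File input/output: series CSV reading and tidy study tables.

Series files are plain CSV with one numeric value per row, optionally a
label column (timestamps, subgroup names) that is carried through untouched.
Parsing is fail-fast: a missing or non-numeric cell raises an error naming
the offending row — no silent imputation or dropping.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFileError

__all__ = ["SeriesFile", "read_series_csv", "write_study_csv", "read_study_csv"]

STUDY_COLUMNS = ["ruleset", "length", "shift", "tp", "fp", "tn", "fn", "n_reps", "seed"]


@dataclass(frozen=True)
class SeriesFile:
    """A parsed series file: the ordered values, optional row labels, and
    the source path for error messages."""

    path: str
    values: np.ndarray
    labels: list[str] | None = None


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_series_csv(
    path,
    value_column: int | str | None = None,
    label_column: int | str | None = None,
) -> SeriesFile:
    """Read an ordered series from a CSV file, preserving row order.

    The value column may be selected by 0-based position or header name;
    with a single-column file it defaults to that column, with two columns
    the first is taken as labels and the second as values.  A header row is
    auto-detected (first row whose value cell is not numeric).
    """
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh)]
    rows = [row for row in rows if row and any(cell.strip() for cell in row)]
    if not rows:
        raise InputFileError(f"{path}: file is empty")

    ncol = len(rows[0])
    header: list[str] | None = None
    if not all(_is_number(c) for c in rows[0]):
        # candidate header row — but only if a later row IS numeric somewhere
        header = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise InputFileError(f"{path}: no data rows below the header")

    def _resolve(col: int | str | None, default: int | None) -> int | None:
        if col is None:
            return default
        if isinstance(col, int):
            if not 0 <= col < ncol:
                raise InputFileError(f"{path}: column index {col} out of range")
            return col
        if header is None or col not in header:
            raise InputFileError(f"{path}: no column named {col!r}")
        return header.index(col)

    if value_column is None and label_column is None and ncol >= 2:
        label_idx: int | None = 0
        value_idx: int | None = 1
    else:
        value_idx = _resolve(value_column, 0 if ncol == 1 else None)
        label_idx = _resolve(label_column, None)
    if value_idx is None:
        raise InputFileError(
            f"{path}: value column must be selected for files with {ncol} columns"
        )

    values = []
    labels = [] if label_idx is not None else None
    for i, row in enumerate(rows, start=(2 if header else 1)):
        if len(row) <= value_idx:
            raise InputFileError(f"{path}: row {i} has too few columns")
        cell = row[value_idx].strip()
        if not _is_number(cell):
            raise InputFileError(f"{path}: row {i}: non-numeric value {cell!r}")
        values.append(float(cell))
        if labels is not None:
            labels.append(row[label_idx].strip())
    if not values:
        raise InputFileError(f"{path}: no values found")
    return SeriesFile(path=str(path), values=np.asarray(values), labels=labels)


def write_study_csv(table: pd.DataFrame, path) -> None:
    """Write a tidy study table (confusion proportions, optionally with the
    diagnostic summary columns appended) as CSV."""
    table.to_csv(path, index=False)


def read_study_csv(path) -> pd.DataFrame:
    """Read back a tidy study table written by :func:`write_study_csv`."""
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise InputFileError(f"{path}: missing study columns: {', '.join(missing)}")
    return df
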