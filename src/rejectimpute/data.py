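"""Data containers, missingness masks, and case partitioning.

The package represents a dataset as an ``N x D`` real matrix together with a
binary observation mask (1 = observed, 0 = missing).  Missing cells hold NaN
in ``values`` and must never be read as data.  A *missingness pattern* is the
length-``D`` 0/1 row of the mask; cases sharing the row share a pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Cell contents (after stripping, lowercased) treated as missing on read.
MISSING_MARKERS = frozenset({"", "?", "na", "nan"})


class DataError(ValueError):
    """Raised for unusable input data (non-numeric cells, ragged rows, ...)."""


@dataclass
class DataMatrix:
    """An ``N x D`` numeric matrix with an explicit observation mask.

    Attributes
    ----------
    values : ndarray of shape (N, D)
        Feature values; NaN at masked-out cells.
    mask : ndarray of shape (N, D), dtype bool
        True where the cell is observed.
    feature_names : list of str
    row_ids : list of str
    """

    values: np.ndarray
    mask: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise DataError("need at least one row and one feature")
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise DataError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        # Enforce the sentinel invariant: masked cells are NaN.
        self.values = np.where(self.mask, self.values, np.nan)
        if np.isnan(self.values[self.mask]).any():
            raise DataError("observed cells must be numeric (found NaN under mask=1)")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]
        if not self.row_ids:
            self.row_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.feature_names) != self.values.shape[1]:
            raise DataError("feature_names length must equal D")
        if len(self.row_ids) != self.values.shape[0]:
            raise DataError("row_ids length must equal N")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise DataError(f"non-numeric columns not supported: {bad}")
        values = df.to_numpy(dtype=float)
        return cls(
            values=values,
            mask=~np.isnan(values),
            feature_names=[str(c) for c in df.columns],
            row_ids=[str(i) for i in df.index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.feature_names, index=self.row_ids
        )


@dataclass
class CasePartition:
    """Complete/incomplete row split plus deduplicated missingness patterns.

    ``patterns`` holds the M unique patterns of the incomplete rows, in first-
    occurrence order, as an ``(M, D)`` 0/1 integer array (1 = present).
    """

    complete_rows: np.ndarray
    incomplete_rows: np.ndarray
    patterns: np.ndarray
    pattern_of_row: dict[int, int]
    all_missing_rows: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_complete(self) -> int:
        return len(self.complete_rows)

    @property
    def n_incomplete(self) -> int:
        return len(self.incomplete_rows)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def pattern_signatures(self) -> list[str]:
        """Patterns as 0/1 strings, e.g. ``'11010'`` (1 = present)."""
        return ["".join(str(b) for b in row) for row in self.patterns]


def extract_mask(raw_row) -> np.ndarray:
    """Missingness pattern of one row: 1 where observed, 0 where missing.

    ``raw_row`` is a sequence whose missing entries are None or NaN.
    """
    out = np.empty(len(raw_row), dtype=int)
    for j, v in enumerate(raw_row):
        out[j] = 0 if v is None or (isinstance(v, float) and np.isnan(v)) else 1
    return out


def partition_cases(data: DataMatrix) -> CasePartition:
    """Split rows into complete and incomplete cases and deduplicate patterns.

    Rows with *all* features missing are excluded from the incomplete set with
    a warning: no value-similarity kernel can ever be evaluated for them.
    Patterns are kept in first-occurrence order among incomplete rows.
    """
    if data.d < 2:
        raise DataError("need at least 2 features to partition cases")
    mask = data.mask.astype(int)
    complete = np.flatnonzero(mask.all(axis=1))
    none_obs = np.flatnonzero(~data.mask.any(axis=1))
    if none_obs.size:
        warnings.warn(
            f"{none_obs.size} row(s) with all features missing excluded "
            "(no present feature to compute similarity from)",
            UserWarning,
            stacklevel=2,
        )
    incomplete = np.flatnonzero(~mask.all(axis=1) & data.mask.any(axis=1))

    patterns: list[tuple[int, ...]] = []
    index_of: dict[tuple[int, ...], int] = {}
    pattern_of_row: dict[int, int] = {}
    for i in incomplete:
        key = tuple(mask[i])
        if key not in index_of:
            index_of[key] = len(patterns)
            patterns.append(key)
        pattern_of_row[int(i)] = index_of[key]

    n_com = complete.size
    if n_com < 3:
        warnings.warn(
            f"only {n_com} complete case(s); the leave-one-out error simulation "
            "needs at least 3",
            UserWarning,
            stacklevel=2,
        )
    elif n_com < 10:
        warnings.warn(
            f"only {n_com} complete cases; error estimates will be unreliable",
            UserWarning,
            stacklevel=2,
        )

    pat_arr = (
        np.array(patterns, dtype=int)
        if patterns
        else np.empty((0, data.d), dtype=int)
    )
    return CasePartition(
        complete_rows=complete,
        incomplete_rows=incomplete,
        patterns=pat_arr,
        pattern_of_row=pattern_of_row,
        all_missing_rows=none_obs,
    )


def read_dataset(
    path,
    missing_markers=MISSING_MARKERS,
    delimiter: str | None = None,
) -> DataMatrix:
    """Read a CSV/TSV numeric table with a header row into a :class:`DataMatrix`.

    Missing cells may be marked by any of ``missing_markers`` (matched
    case-insensitively after stripping whitespace).  Non-numeric cells that are
    not missing markers raise :class:`DataError` naming the row and column.
    """
    sep = delimiter
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataError(f"cannot parse {path}: {exc}") from exc

    markers = {m.lower() for m in missing_markers}
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            s = str(cell).strip()
            if s.lower() in markers:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(s)
                except ValueError as exc:
                    raise DataError(
                        f"non-numeric cell at row {i}, column '{col}': {s!r}"
                    ) from exc
    return DataMatrix(
        values=values,
        mask=~np.isnan(values),
        feature_names=[str(c) for c in df.columns],
        row_ids=[str(i) for i in df.index],
    )


def write_dataset(data: DataMatrix, path, missing_marker: str = "NA") -> None:
    """Write a :class:`DataMatrix` as CSV, marking missing cells."""
    df = data.to_dataframe()
    df.to_csv(path, index=False, na_rep=missing_marker)


def read_mask_file(path, ones_are_missing: bool = True) -> np.ndarray:
    """Read a whitespace-separated 0/1 mask matrix.

    External mask files conventionally use 1 = *missing*; they are inverted on
    load so the returned array follows the package convention 1 = present.
    Pass ``ones_are_missing=False`` for files already in package convention.
    """
    arr = np.loadtxt(path, dtype=int)
    arr = np.atleast_2d(arr)
    if not np.isin(arr, (0, 1)).all():
        raise DataError("mask file must contain only 0 and 1")
    return 1 - arr if ones_are_missing else arr


def apply_mask_file(data: DataMatrix, mask_present: np.ndarray) -> DataMatrix:
    """Overlay a presence mask (1 = present) on fully observed data."""
    if mask_present.shape != data.values.shape:
        raise DataError(
            f"mask shape {mask_present.shape} does not match data "
            f"shape {data.values.shape}"
        )
    m = mask_present.astype(bool) & data.mask
    return DataMatrix(
        values=np.where(m, data.values, np.nan),
        mask=m,
        feature_names=list(data.feature_names),
        row_ids=list(data.row_ids),
    )
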