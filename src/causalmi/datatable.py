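"""Categorical sample table with missing-value mask.

All estimators in this package operate on a :class:`DataTable`: an N x P
matrix of integer level codes, one ordered level list per variable, and a
boolean missing mask.  Values are never silently discretized or coerced —
every column read from disk is categorical, with level order fixed by first
appearance in the file so that runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataTable", "read_table", "write_table"]

DEFAULT_NA_TOKENS = ("NA", "NaN", "nan", "")


@dataclass
class DataTable:
    """N x P categorical data matrix.

    Parameters
    ----------
    values : ndarray of int, shape (N, P)
        Level codes; entries under ``missing_mask`` are ignored (kept as 0).
    columns : list of str
        Variable names, unique.
    levels : list of list of str
        Ordered level labels per variable; codes index into these lists.
    missing_mask : ndarray of bool, shape (N, P)
        True where the observation is missing.
    n_eff : int or None
        Optional effective number of independent samples, overriding the
        available-sample count in every finite-size (complexity, probability)
        term.  Must satisfy ``1 <= n_eff <= N``.
    """

    values: np.ndarray
    columns: list[str]
    levels: list[list[str]]
    missing_mask: np.ndarray | None = None
    n_eff: int | None = None
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if len(self.columns) != p or len(self.levels) != p:
            raise ValueError("columns/levels length must match number of variables")
        if len(set(self.columns)) != p:
            raise ValueError("duplicate column names")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, p), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape mismatch")
        for j, lv in enumerate(self.levels):
            if len(lv) == 0:
                raise ValueError(f"empty level list for variable {self.columns[j]!r}")
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate levels for variable {self.columns[j]!r}")
            col = self.values[:, j][~self.missing_mask[:, j]]
            if col.size and (col.min() < 0 or col.max() >= len(lv)):
                raise ValueError(f"code out of range for variable {self.columns[j]!r}")
        if self.n_eff is not None:
            if not (1 <= int(self.n_eff) <= n):
                raise ValueError("n_eff must satisfy 1 <= n_eff <= N")
            self.n_eff = int(self.n_eff)
        self._index = {c: j for j, c in enumerate(self.columns)}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def col(self, name: str) -> int:
        """Column index of a variable name."""
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def n_levels(self, name: str) -> int:
        return len(self.levels[self.col(name)])

    def with_n_eff(self, n_eff: int | None) -> "DataTable":
        """Copy sharing arrays but with a different effective sample size."""
        return DataTable(self.values, list(self.columns),
                         [list(l) for l in self.levels],
                         self.missing_mask, n_eff)

    def permuted(self, rng: np.random.Generator) -> "DataTable":
        """Independently permute each column (values and mask together)."""
        n = self.n_samples
        vals = np.empty_like(self.values)
        mask = np.empty_like(self.missing_mask)
        for j in range(self.n_vars):
            perm = rng.permutation(n)
            vals[:, j] = self.values[perm, j]
            mask[:, j] = self.missing_mask[perm, j]
        return DataTable(vals, list(self.columns),
                         [list(l) for l in self.levels], mask, self.n_eff)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_eff: int | None = None,
                   na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS) -> "DataTable":
        """Build from a DataFrame of strings; level order = first appearance."""
        columns = [str(c) for c in df.columns]
        n, p = df.shape
        values = np.zeros((n, p), dtype=np.int64)
        mask = np.zeros((n, p), dtype=bool)
        levels: list[list[str]] = []
        na_set = set(na_tokens)
        for j, c in enumerate(df.columns):
            raw = df[c].astype(object)
            col = np.array(["" if (x is None or (isinstance(x, float) and np.isnan(x)))
                            else str(x) for x in raw], dtype=object)
            miss = np.array([s in na_set for s in col], dtype=bool)
            seen: dict[str, int] = {}
            codes = np.zeros(n, dtype=np.int64)
            for i, s in enumerate(col):
                if miss[i]:
                    continue
                if s not in seen:
                    seen[s] = len(seen)
                codes[i] = seen[s]
            if not seen:          # all-missing column still needs one level
                seen = {"NA": 0}
            values[:, j] = codes
            mask[:, j] = miss
            levels.append(list(seen))
        return cls(values, columns, levels, mask, n_eff)

    def to_frame(self) -> pd.DataFrame:
        """Decode back to a DataFrame of strings with NA for missing."""
        out = {}
        for j, c in enumerate(self.columns):
            lv = np.array(self.levels[j], dtype=object)
            col = lv[self.values[:, j]].copy()
            col[self.missing_mask[:, j]] = "NA"
            out[c] = col
        return pd.DataFrame(out)


def read_table(path, delimiter: str = "\t",
               na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS,
               n_eff: int | None = None) -> DataTable:
    """Read a delimited text file of categorical samples.

    All columns are read as strings (numeric-looking columns stay
    categorical); the header row supplies variable names; level order is
    first appearance in the file.  ``na_tokens`` map to the missing mask.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)
    if len(set(header)) != len(header):
        raise ValueError("duplicate column names")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     na_values=[], skip_blank_lines=True)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"empty table: {path}")
    return DataTable.from_frame(df, n_eff=n_eff, na_tokens=na_tokens)


def write_table(data: DataTable, path, delimiter: str = "\t") -> None:
    data.to_frame().to_csv(path, sep=delimiter, index=False)
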