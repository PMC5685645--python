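"""Plug-in multivariate information estimators with finite-size corrections.

Everything here works on categorical level codes and plug-in (empirical)
probabilities, in nats.  Two complexity criteria translate the finite sample
size into a penalty ``k`` on estimated information: the classical BIC/MDL
count of free parameters, and a decomposable normalized-maximum-likelihood
(NML) regret built from the multinomial parametric complexity ``C(K, n)``.
The penalized ("shifted") information ``I' = I - k/n`` is the quantity every
downstream decision (edge removal, contributor selection, orientation) is
based on.

Missing values are handled by complete-case analysis per variable tuple: all
counts and corrections use the number of rows ``N_a`` with no missing entry
among the variables involved (missing-completely-at-random assumption).  An
explicit effective sample size ``n_eff`` on the table overrides ``N_a`` in
every finite-size term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .datatable import DataTable

__all__ = [
    "ContingencyTable",
    "InfoResult",
    "contingency",
    "entropy",
    "cond_mutual_info",
    "multivariate_information",
    "three_point_info",
    "log_multinomial_complexity",
    "complexity_term",
]

MAX_JOINT_VARS = 12

# ---------------------------------------------------------------------------
# containers


@dataclass
class ContingencyTable:
    """Multi-way counts over the declared levels of a variable tuple."""

    counts: np.ndarray
    n_available: int
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if int(self.counts.sum()) != int(self.n_available):
            raise ValueError("counts must sum to n_available")


@dataclass
class InfoResult:
    """An information value with its finite-size complexity penalty."""

    info: float
    complexity: float
    n_used: int

    @property
    def shifted(self) -> float:
        """Penalized information I' = info - complexity / n_used."""
        return self.info - self.complexity / self.n_used


# ---------------------------------------------------------------------------
# complete-case extraction and entropies


def _complete_rows(data: DataTable, idx: list[int]) -> np.ndarray:
    return ~data.missing_mask[:, idx].any(axis=1)


def _joint_codes(data: DataTable, idx: list[int], rows: np.ndarray) -> tuple[np.ndarray, int]:
    """Mixed-radix joint code over the listed variables, last index fastest."""
    code = np.zeros(int(rows.sum()), dtype=np.int64)
    size = 1
    for j in idx:
        r = len(data.levels[j])
        code = code * r + data.values[rows, j]
        size *= r
        if size > 2**62:
            raise ValueError("joint level space overflow")
    return code, size


def _entropy_codes(codes: np.ndarray, size: int) -> float:
    n = codes.size
    if n == 0:
        raise ValueError("empty table")
    if size <= max(4 * n, 4096):
        counts = np.bincount(codes, minlength=size)
        counts = counts[counts > 0]
    else:
        _, counts = np.unique(codes, return_counts=True)
    p = counts / n
    return float(-(p * np.log(p)).sum())


def contingency(data: DataTable, variables: tuple[str, ...]) -> ContingencyTable:
    """Complete-case contingency table over a variable tuple.

    Counts are over the declared level lists (unobserved levels appear as
    zero cells); ``n_available`` is the number of rows with no missing value
    among the listed variables.
    """
    if not variables:
        raise ValueError("variables must be non-empty")
    if len(variables) > MAX_JOINT_VARS:
        raise ValueError(f"more than {MAX_JOINT_VARS} variables")
    idx = [data.col(v) for v in variables]
    rows = _complete_rows(data, idx)
    n_a = int(rows.sum())
    if n_a == 0:
        raise ValueError("no complete cases for " + ",".join(variables))
    shape = tuple(len(data.levels[j]) for j in idx)
    codes, size = _joint_codes(data, idx, rows)
    counts = np.bincount(codes, minlength=size).reshape(shape)
    return ContingencyTable(counts, n_a, tuple(variables))


def entropy(table: ContingencyTable | np.ndarray) -> float:
    """Plug-in entropy -sum p log p in nats, with 0 log 0 := 0."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# multinomial parametric complexity

_EXACT_C2_MAX = 1000
_c2_cache: dict[int, float] = {}
_ck_cache: dict[tuple[int, int], float] = {}


def _log_c2_exact(n: int) -> float:
    h = np.arange(n + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (gammaln(n + 1) - gammaln(h + 1) - gammaln(n - h + 1)
             + np.where(h > 0, h * np.log(h / n), 0.0)
             + np.where(n - h > 0, (n - h) * np.log((n - h) / n), 0.0))
    return float(logsumexp(t))


def _log_c2(n: int) -> float:
    """log C(2, n): exact summation for small n, Szpankowski expansion above."""
    if n <= 0:
        return 0.0
    v = _c2_cache.get(n)
    if v is None:
        if n <= _EXACT_C2_MAX:
            v = _log_c2_exact(n)
        else:
            v = (0.5 * math.log(n * math.pi / 2.0)
                 + math.sqrt(8.0 / (9.0 * n * math.pi))
                 + (3.0 * math.pi - 16.0) / (36.0 * n * math.pi))
        _c2_cache[n] = v
    return v


def log_multinomial_complexity(K: int, n: int) -> float:
    """log of the multinomial parametric complexity C(K, n).

    C(1, n) = 1 for all n, C(K, 0) = 1, and for K >= 3 the linear
    recurrence C(K, n) = C(K-1, n) + n/(K-2) * C(K-2, n), evaluated in log
    space with memoization.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if K == 1 or n == 0:
        return 0.0
    if K == 2:
        return _log_c2(n)
    key = (K, n)
    v = _ck_cache.get(key)
    if v is None:
        prev2, prev1 = 0.0, _log_c2(n)   # K = 1, 2
        logn = math.log(n)
        for k in range(3, K + 1):
            cur = float(np.logaddexp(prev1, logn - math.log(k - 2) + prev2))
            prev2, prev1 = prev1, cur
            _ck_cache[(k, n)] = cur
        v = prev1
    return v


def _log_c_vec(K: int, counts: np.ndarray) -> np.ndarray:
    """Vectorized log C(K, n) over an array of stratum counts."""
    return np.array([log_multinomial_complexity(K, int(c)) for c in counts])


# ---------------------------------------------------------------------------
# complexity penalties


def _strata_counts(data: DataTable, idx: list[int], rows: np.ndarray) -> np.ndarray:
    if not idx:
        return np.array([int(rows.sum())])
    codes, size = _joint_codes(data, idx, rows)
    if size <= max(4 * codes.size, 4096):
        counts = np.bincount(codes, minlength=size)
        return counts[counts > 0]
    _, counts = np.unique(codes, return_counts=True)
    return counts


def _nml_half_term(data: DataTable, target: int, other: int,
                   cond_idx: list[int], rows: np.ndarray) -> float:
    """One-sided decomposable NML regret for `target` given cond and `other`."""
    r = len(data.levels[target])
    if r <= 1:
        return 0.0
    n_u = _strata_counts(data, cond_idx + [other], rows)
    n_v = _strata_counts(data, cond_idx, rows)
    return float(_log_c_vec(r, n_u).sum() - _log_c_vec(r, n_v).sum())


def complexity_term(data: DataTable, x: str, y: str,
                    cond_set: tuple[str, ...] = (), mode: str = "nml") -> float:
    """Finite-size penalty k for I(X;Y|cond_set), in nats; k >= 0.

    ``bic``: k = (r_x-1)(r_y-1) prod(r_a) * log(n)/2.
    ``nml``: symmetrized decomposable multinomial regret over conditioning
    strata, k = (k_X + k_Y)/2, where k_X sums log C(r_x, .) over the strata
    of cond x Y minus the strata of cond alone (and symmetrically for Y).
    """
    if mode not in ("bic", "nml"):
        raise ValueError("mode must be 'bic' or 'nml'")
    ix, iy = data.col(x), data.col(y)
    ic = [data.col(a) for a in cond_set]
    rows = _complete_rows(data, [ix, iy] + ic)
    n_a = int(rows.sum())
    if n_a == 0:
        raise ValueError("no complete cases")
    n_used = data.n_eff if data.n_eff is not None else n_a
    rx, ry = len(data.levels[ix]), len(data.levels[iy])
    if mode == "bic":
        ra = 1
        for j in ic:
            ra *= len(data.levels[j])
        return 0.5 * (rx - 1) * (ry - 1) * ra * math.log(max(n_used, 2))
    kx = _nml_half_term(data, ix, iy, ic, rows)
    ky = _nml_half_term(data, iy, ix, ic, rows)
    return max(0.0, 0.5 * (kx + ky))


# ---------------------------------------------------------------------------
# information estimators


def _degenerate(data: DataTable, names: tuple[str, ...]) -> bool:
    for v in names:
        if data.n_levels(v) <= 1:
            warnings.warn(f"variable {v!r} has a single level; information set to 0",
                          stacklevel=3)
            return True
    return False


def cond_mutual_info(data: DataTable, x: str, y: str,
                     cond_set: tuple[str, ...] = (), mode: str = "nml") -> InfoResult:
    """Conditional mutual information I(X;Y|{A_i}) with complexity penalty.

    Computed as -H(A) + H(X,A) + H(Y,A) - H(X,Y,A) on the complete cases of
    the full (X, Y, {A}) tuple; an empty conditioning set gives the plain
    mutual information.
    """
    if x == y or x in cond_set or y in cond_set:
        raise ValueError("x, y must be distinct and not in cond_set")
    ix, iy = data.col(x), data.col(y)
    ic = [data.col(a) for a in cond_set]
    rows = _complete_rows(data, [ix, iy] + ic)
    n_a = int(rows.sum())
    if n_a == 0:
        raise ValueError("no complete cases")
    n_used = data.n_eff if data.n_eff is not None else n_a
    if _degenerate(data, (x, y)):
        return InfoResult(0.0, 0.0, n_used)
    h = {}
    for key, idx in (("a", ic), ("xa", [ix] + ic), ("ya", [iy] + ic),
                     ("xya", [ix, iy] + ic)):
        if idx:
            codes, size = _joint_codes(data, idx, rows)
            h[key] = _entropy_codes(codes, size)
        else:
            h[key] = 0.0
    info = max(0.0, -h["a"] + h["xa"] + h["ya"] - h["xya"])
    k = complexity_term(data, x, y, tuple(cond_set), mode)
    return InfoResult(info, k, n_used)


def multivariate_information(data: DataTable, variables: tuple[str, ...]) -> float:
    """Interaction information by inclusion-exclusion over subset entropies.

    For two variables this is the mutual information; the three-variable
    value can be negative (collider signature).
    """
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    if len(variables) > MAX_JOINT_VARS:
        raise ValueError(f"more than {MAX_JOINT_VARS} variables")
    idx = [data.col(v) for v in variables]
    rows = _complete_rows(data, idx)
    if not rows.any():
        raise ValueError("no complete cases")
    total = 0.0
    p = len(idx)
    for k in range(1, p + 1):
        sign = (-1.0) ** (k - 1)
        for sub in combinations(idx, k):
            codes, size = _joint_codes(data, list(sub), rows)
            total += sign * _entropy_codes(codes, size)
    return float(total)


def three_point_info(data: DataTable, x: str, y: str, z: str,
                     cond_set: tuple[str, ...] = (), mode: str = "nml") -> InfoResult:
    """Conditional 3-point information I(X;Y;Z|{A}) = I(X;Y|{A}) - I(X;Y|{A},Z).

    Both terms are evaluated on the complete cases of the full
    (X, Y, Z, {A}) tuple so the decomposition identity is exact.  The
    returned complexity is the penalty increment of adding Z to the
    conditioning set, so ``shifted > 0`` means Z is a significant
    contributor; a significantly negative ``info`` is collider evidence.
    """
    if len({x, y, z}) != 3 or z in cond_set:
        raise ValueError("x, y, z must be distinct and z not in cond_set")
    ix, iy, iz = data.col(x), data.col(y), data.col(z)
    ic = [data.col(a) for a in cond_set]
    rows = _complete_rows(data, [ix, iy, iz] + ic)
    n_a = int(rows.sum())
    if n_a == 0:
        raise ValueError("no complete cases")
    n_used = data.n_eff if data.n_eff is not None else n_a
    if _degenerate(data, (x, y, z)):
        return InfoResult(0.0, 0.0, n_used)
    h = {}
    for key, idx in (("a", ic), ("xa", [ix] + ic), ("ya", [iy] + ic),
                     ("xya", [ix, iy] + ic), ("az", ic + [iz]),
                     ("xaz", [ix] + ic + [iz]), ("yaz", [iy] + ic + [iz]),
                     ("xyaz", [ix, iy] + ic + [iz])):
        if idx:
            codes, size = _joint_codes(data, idx, rows)
            h[key] = _entropy_codes(codes, size)
        else:
            h[key] = 0.0
    i_xy_a = -h["a"] + h["xa"] + h["ya"] - h["xya"]
    i_xy_az = -h["az"] + h["xaz"] + h["yaz"] - h["xyaz"]
    info = float(i_xy_a - i_xy_az)
    k_a = complexity_term(data, x, y, tuple(cond_set), mode)
    k_az = complexity_term(data, x, y, tuple(cond_set) + (z,), mode)
    return InfoResult(info, max(0.0, k_az - k_a), n_used)
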