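"""Step 2: permutation-based edge confidence and partial-correlation signs.

The probability that an edge XY should be removed is P_XY =
min(1, exp(-n I'(X;Y|{A_i}))), using the penalized information so the
unknown normalization constant is absorbed by the complexity term.  The
edge-specific confidence ratio C_XY = P_XY / <P_XY^rand> compares it against
the same probability on column-permuted (hence independent) data: the lower
C_XY, the higher the confidence in the edge.  A ratio is preferred over a
permutation p-value because for strong edges (n I' >> 1) essentially every
permutation gives P_rand > P_XY, so a ratio is informative at small
permutation counts where a p-value would saturate at 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .datatable import DataTable
from .graph import MixedGraph
from .information import cond_mutual_info
from .skeleton import EdgeState, best_contributor

__all__ = ["ConfidenceConfig", "edge_probability", "confidence_ratio",
           "assess_confidence", "filter_edges", "edge_sign"]

logger = logging.getLogger(__name__)


@dataclass
class ConfidenceConfig:
    """Settings for the permutation confidence assessment."""

    n_permutations: int = 100
    threshold: float = 1e-3
    seed: int = 0
    fast_mode: bool = False    # unconditional I' on permuted data

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


def log_edge_probability(edge: EdgeState) -> float:
    """log P_XY = min(0, -n I'(X;Y|{A_i}))."""
    return min(0.0, -edge.n_used * edge.shifted)


def edge_probability(edge: EdgeState) -> float:
    """Probability to remove edge XY, capped at 1."""
    return math.exp(log_edge_probability(edge))


def _pair_log_p(data: DataTable, x: str, y: str, pool: set[str],
                mode: str, fast: bool) -> float:
    """log P_XY on (permuted) data, re-running the per-pair contributor search."""
    r = cond_mutual_info(data, x, y, (), mode)
    st = EdgeState(x, y, info_cond=r.info, complexity=r.complexity, n_used=r.n_used)
    if not fast:
        while st.shifted > 0:
            nxt = best_contributor(data, st, pool, mode)
            if nxt is None:
                break
            st.contributors.append(nxt[0])
            r = cond_mutual_info(data, x, y, tuple(st.contributors), mode)
            st.info_cond, st.complexity, st.n_used = r.info, r.complexity, r.n_used
    return log_edge_probability(st)


def confidence_ratio(data: DataTable, edge: EdgeState, cfg: ConfidenceConfig,
                     mode: str = "nml") -> float:
    """C_XY = P_XY / mean(P_XY^rand) over column-permuted replicates."""
    rng = np.random.default_rng(cfg.seed)
    pool = set(data.columns) - {edge.x, edge.y}
    log_rand = []
    for _ in range(cfg.n_permutations):
        perm = data.permuted(rng)
        log_rand.append(_pair_log_p(perm, edge.x, edge.y, pool, mode,
                                    cfg.fast_mode))
    log_mean_rand = logsumexp(log_rand) - math.log(len(log_rand))
    return float(math.exp(min(700.0, log_edge_probability(edge) - log_mean_rand)))


def assess_confidence(data: DataTable, graph: MixedGraph,
                      states: dict[tuple[str, str], EdgeState],
                      cfg: ConfidenceConfig, mode: str = "nml") -> None:
    """Fill p_xy and confidence for every retained edge, in place.

    All edges share the same B permuted replicates (one seeded stream), so a
    run is reproducible and the permutation cost is paid once.
    """
    rng = np.random.default_rng(cfg.seed)
    retained = [states[pair] for pair in graph.edges()]
    for st in retained:
        st.log_p_xy = log_edge_probability(st)
        st.p_xy = math.exp(st.log_p_xy)
    log_rand: dict[tuple[str, str], list[float]] = {st.pair: [] for st in retained}
    for _ in range(cfg.n_permutations):
        perm = data.permuted(rng)
        for st in retained:
            pool = set(data.columns) - {st.x, st.y}
            log_rand[st.pair].append(
                _pair_log_p(perm, st.x, st.y, pool, mode, cfg.fast_mode))
    for st in retained:
        lr = log_rand[st.pair]
        log_mean = logsumexp(lr) - math.log(len(lr))
        st.confidence = float(math.exp(min(700.0, st.log_p_xy - log_mean)))


def filter_edges(graph: MixedGraph, states: dict[tuple[str, str], EdgeState],
                 threshold: float) -> MixedGraph:
    """Drop edges whose confidence ratio is >= threshold; survivors unchanged."""
    out = graph.copy()
    for (u, v) in graph.edges():
        st = states[(u, v)]
        c = st.confidence
        if c is not None and c >= threshold:
            out.remove_edge(u, v)
            st.status = "filtered"
            logger.info("filtered %s-%s (C=%.3g >= %.3g)", u, v, c, threshold)
    return out


def edge_sign(data: DataTable, edge: EdgeState) -> int:
    """Sign of the partial correlation of X, Y given the edge's contributors.

    Levels are integer-coded in their stored order; the partial correlation
    is read off the inverse correlation matrix.  Returns 0 when undefined
    (constant variable or singular correlation matrix).
    """
    names = [edge.x, edge.y] + list(edge.contributors)
    idx = [data.col(v) for v in names]
    rows = ~data.missing_mask[:, idx].any(axis=1)
    m = data.values[rows][:, idx].astype(float)
    if m.shape[0] < 3:
        return 0
    sd = m.std(axis=0)
    keep = [0, 1] + [j for j in range(2, m.shape[1]) if sd[j] > 0]
    if sd[0] == 0 or sd[1] == 0:
        return 0
    m = m[:, keep]
    corr = np.corrcoef(m, rowvar=False)
    if not np.all(np.isfinite(corr)):
        return 0
    if m.shape[1] == 2:        # no usable contributors: plain correlation
        rho = corr[0, 1]
    else:
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError:
            return 0
        denom = math.sqrt(abs(prec[0, 0] * prec[1, 1]))
        if denom == 0:
            return 0
        rho = -prec[0, 1] / denom
    if abs(rho) < 1e-12:
        return 0
    return 1 if rho > 0 else -1
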