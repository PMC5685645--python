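"""Step 1: iterative skeleton learning by collection of most likely contributors.

Starting from the complete graph, each pair (X, Y) iteratively collects the
conditioning variables ("contributors") that best explain away their mutual
information, one at a time: the next contributor A_n maximizes the penalized
conditional 3-point information I'(X;Y;A_n | {A_i}).  An edge is removed as
soon as its penalized conditional information I'(X;Y|{A_i}) drops to zero or
below, and the contributor list at that moment is stored as the separating
set.  With ``latent=True`` (the default) contributors are searched among all
observed variables, which is what makes the procedure sound in the presence
of unobserved common causes; with ``latent=False`` the search is restricted
to current neighbors of X or Y, as in classical constraint-based methods.

Edges are processed by descending rank R = n * I' of their best next
contributor, with lazy refresh (only the touched edge is re-ranked) and
lexicographic tie-breaking for full determinism.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .datatable import DataTable
from .graph import CIRCLE, MixedGraph
from .information import cond_mutual_info, three_point_info

__all__ = ["EdgeState", "best_contributor", "learn_skeleton"]

logger = logging.getLogger(__name__)


@dataclass
class EdgeState:
    """Per-pair record of the contributor-collection process."""

    x: str
    y: str
    status: str = "pending"            # pending | retained | removed
    contributors: list[str] = field(default_factory=list)
    info_cond: float = 0.0             # I(X;Y|{A_i}), nats
    complexity: float = 0.0            # penalty k, nats
    n_used: int = 0
    rank: float = float("-inf")
    next_candidate: str | None = None
    sep_set: list[str] | None = None   # filled on removal
    log_p_xy: float = 0.0              # filled by the confidence step
    p_xy: float = 1.0
    confidence: float | None = None
    sign: int = 0

    @property
    def shifted(self) -> float:
        return self.info_cond - self.complexity / max(self.n_used, 1)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.x, self.y) if self.x <= self.y else (self.y, self.x)


def _candidate_gains(data: DataTable, x: str, y: str, contributors: list[str],
                     candidates: list[str], mode: str) -> dict[str, float]:
    """Penalized 3-point gain I'(X;Y;Z|{A}) for each candidate Z.

    The selection penalty is the chi-square null bias increment
    ddf/(2n) with ddf = (r_x-1)(r_y-1) prod(r_a) (r_z-1): the plug-in
    3-point estimate is itself biased downward by about this much when Z is
    uninformative, so requiring I3 > ddf/2n is a one-sided significance
    gate at the natural fluctuation scale.  Penalizing by the full model
    complexity here would double-count the finite-size effect (it already
    guards the removal test) and stall weak but genuine contributors.
    """
    gains: dict[str, float] = {}
    cond = tuple(contributors)
    rx, ry = data.n_levels(x), data.n_levels(y)
    ra = 1
    for a in cond:
        ra *= data.n_levels(a)
    if not data.missing_mask.any():
        # shared base term; identical to three_point_info on complete data
        base = cond_mutual_info(data, x, y, cond, mode)
        for z in candidates:
            if data.n_levels(z) <= 1:
                continue
            ext = cond_mutual_info(data, x, y, cond + (z,), mode)
            info3 = base.info - ext.info
            ddf = (rx - 1) * (ry - 1) * ra * (data.n_levels(z) - 1)
            gains[z] = info3 - ddf / (2 * base.n_used)
    else:
        for z in candidates:
            if data.n_levels(z) <= 1:
                continue
            r = three_point_info(data, x, y, z, cond, mode)
            ddf = (rx - 1) * (ry - 1) * ra * (data.n_levels(z) - 1)
            gains[z] = r.info - ddf / (2 * r.n_used)
    return gains


def best_contributor(data: DataTable, edge: EdgeState, search_set,
                     mode: str = "nml") -> tuple[str, float] | None:
    """Most likely next contributor of edge XY, or None.

    Returns the candidate Z maximizing the penalized 3-point gain
    I'(X;Y;Z|{A_i}) subject to the gain being positive; ties break on the
    candidate name.
    """
    pool = sorted(set(search_set) - {edge.x, edge.y} - set(edge.contributors))
    if not pool:
        return None
    gains = _candidate_gains(data, edge.x, edge.y, edge.contributors, pool, mode)
    best = None
    for z in pool:
        g = gains.get(z)
        if g is not None and g > 0 and (best is None or g > best[1]):
            best = (z, g)
    return best


def learn_skeleton(data: DataTable, latent: bool = True, mode: str = "nml"
                   ) -> tuple[MixedGraph, dict[tuple[str, str], EdgeState]]:
    """Learn the undirected skeleton and per-pair edge states.

    Returns a mixed graph whose retained edges carry circle marks at both
    ends, plus the EdgeState map (removed edges included, with their
    separating sets).
    """
    usable = []
    for v in data.columns:
        if data.n_levels(v) <= 1:
            warnings.warn(f"constant variable {v!r} ignored in skeleton")
        else:
            usable.append(v)
    if len(usable) < 2:
        raise ValueError("need at least two non-constant variables")

    graph = MixedGraph(usable)
    states: dict[tuple[str, str], EdgeState] = {}

    # pre-pass: unconditional penalized information
    pending: dict[tuple[str, str], EdgeState] = {}
    for i, x in enumerate(usable):
        for y in usable[i + 1:]:
            r = cond_mutual_info(data, x, y, (), mode)
            st = EdgeState(x, y, info_cond=r.info, complexity=r.complexity,
                           n_used=r.n_used)
            states[st.pair] = st
            if st.shifted <= 0:
                st.status = "removed"
                st.sep_set = []
                logger.info("removed %s-%s unconditionally (I'=%.4g)",
                            x, y, st.shifted)
            else:
                graph.add_edge(x, y, CIRCLE, CIRCLE)
                pending[st.pair] = st

    def pool_for(st: EdgeState) -> set[str]:
        if latent:
            return set(usable) - {st.x, st.y}
        return (graph.neighbors(st.x) | graph.neighbors(st.y)) - {st.x, st.y}

    # initial candidate search
    for st in pending.values():
        _refresh(data, st, pool_for(st), mode)

    # main loop: process edges by descending rank
    active = {k: st for k, st in pending.items() if st.status == "pending"}
    while True:
        live = [st for st in active.values()
                if st.next_candidate is not None]
        if not live:
            break
        st = min(live, key=lambda s: (-s.rank, s.pair))
        z = st.next_candidate
        st.contributors.append(z)
        r = cond_mutual_info(data, st.x, st.y, tuple(st.contributors), mode)
        st.info_cond, st.complexity, st.n_used = r.info, r.complexity, r.n_used
        if st.shifted <= 0:
            st.status = "removed"
            st.sep_set = list(st.contributors)
            st.next_candidate = None
            graph.remove_edge(st.x, st.y)
            del active[st.pair]
            logger.info("removed %s-%s | sep_set=%s (I'=%.4g)",
                        st.x, st.y, st.sep_set, st.shifted)
        else:
            _refresh(data, st, pool_for(st), mode)
            if st.next_candidate is None:
                st.status = "retained"
                del active[st.pair]

    for st in active.values():
        st.status = "retained"
    for st in pending.values():
        if st.status == "pending":     # pragma: no cover - safety net
            st.status = "retained"
    return graph, states


def _refresh(data: DataTable, st: EdgeState, pool: set[str], mode: str) -> None:
    best = best_contributor(data, st, pool, mode)
    if best is None:
        st.next_candidate = None
        st.rank = float("-inf")
    else:
        st.next_candidate, gain = best
        st.rank = st.n_used * gain
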