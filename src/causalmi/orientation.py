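"""Step 3: probabilistic orientation of unshielded triples.

For every unshielded triple <X, Z, Y> (X, Y non-adjacent, both adjacent to
Z) the sign of the conditional 3-point information I(X;Y;Z|{A_i}) — with
{A_i} the separating set that removed the XY edge, minus Z — decides between
the two patterns consistent with X-Z-Y: a significantly negative value is
collider evidence (v-structure X -> Z <- Y), a significantly positive one
supports the chain/fork pattern and propagates an existing arrowhead
(X -> Z becomes X -> Z -> Y).  Significance is handled by shrinking the raw
3-point value toward zero by its complexity increment k/n, so weak triples
land at probability 1/2 and are never oriented.

Orientations are applied greedily by descending probability, never
overwriting an earlier (higher-probability) mark; conflicts are logged.
Edges that end up with arrowheads at both ends are bidirected — the
signature of an unobserved common cause.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .datatable import DataTable
from .graph import ARROW, CIRCLE, TAIL, MixedGraph
from .information import three_point_info
from .skeleton import EdgeState

__all__ = ["TripleScore", "unshielded_triples", "triple_probability", "orient"]

logger = logging.getLogger(__name__)


@dataclass
class TripleScore:
    """Scored unshielded triple <x, z, y> with z in the middle."""

    x: str
    z: str
    y: str
    info3: float        # penalized conditional 3-point information, nats
    n_used: int
    probability: float  # max of the v / non-v probabilities
    kind: str           # "v" | "non-v"


def triple_probability(info3: float, n_used: int) -> float:
    """Probability of the v-structure reading: 1 / (1 + exp(n * info3)).

    Above 1/2 iff info3 < 0; the non-v probability is its complement.
    """
    t = max(-700.0, min(700.0, n_used * info3))
    return 1.0 / (1.0 + math.exp(t))


def _shrink(info3: float, k3: float, n: int) -> float:
    """Shrink the raw 3-point value toward 0 by its complexity increment."""
    pen = k3 / max(n, 1)
    if info3 > 0:
        return max(0.0, info3 - pen)
    return min(0.0, info3 + pen)


def unshielded_triples(data: DataTable, graph: MixedGraph,
                       states: dict[tuple[str, str], EdgeState],
                       mode: str = "nml") -> list[TripleScore]:
    """Score every unshielded triple of the skeleton.

    The conditioning set of a triple is the separating set stored when the
    XY edge was removed (the certificate of their non-adjacency), with Z
    dropped if present; for pairs without a separating set (e.g. filtered in
    Step 2) the collected contributors are used instead.
    """
    out: list[TripleScore] = []
    for z in sorted(graph.nodes):
        nbrs = sorted(graph.neighbors(z))
        for i, x in enumerate(nbrs):
            for y in nbrs[i + 1:]:
                if graph.has_edge(x, y):
                    continue
                pair = (x, y) if x <= y else (y, x)
                st = states.get(pair)
                cond = list(st.sep_set if st and st.sep_set is not None
                            else (st.contributors if st else []))
                cond = tuple(a for a in cond if a != z)
                r = three_point_info(data, x, y, z, cond, mode)
                sv = _shrink(r.info, r.complexity, r.n_used)
                p_v = triple_probability(sv, r.n_used)
                if sv < 0:
                    out.append(TripleScore(x, z, y, sv, r.n_used, p_v, "v"))
                else:
                    out.append(TripleScore(x, z, y, sv, r.n_used, 1.0 - p_v,
                                           "non-v"))
    return out


def _apply_v(graph: MixedGraph, t: TripleScore) -> bool:
    """Arrowheads into z on both edges; only circle marks may be set."""
    marks = [graph.get_mark(t.x, t.z, t.z), graph.get_mark(t.y, t.z, t.z)]
    # applicable when each z-endpoint is circle or already arrow, and at
    # least one circle remains to set
    if not all(m in (CIRCLE, ARROW) for m in marks) or CIRCLE not in marks:
        if TAIL in marks:
            logger.info("orientation conflict: v-structure %s->%s<-%s blocked "
                        "by existing tail", t.x, t.z, t.y)
        return False
    if marks[0] == CIRCLE:
        graph.set_mark(t.x, t.z, t.z, ARROW)
    if marks[1] == CIRCLE:
        graph.set_mark(t.y, t.z, t.z, ARROW)
    return True


def _apply_propagation(graph: MixedGraph, t: TripleScore) -> bool:
    """If one branch points into z, direct the other branch away from z."""
    for a, b in ((t.x, t.y), (t.y, t.x)):
        # pattern a *-> z o-o b  or  a *-> z o-> b
        if graph.get_mark(a, t.z, t.z) != ARROW:
            continue
        if graph.get_mark(b, t.z, t.z) != CIRCLE:
            continue
        mb = graph.get_mark(b, t.z, b)
        if mb not in (CIRCLE, ARROW):
            continue
        graph.set_mark(b, t.z, t.z, TAIL)
        if mb == CIRCLE:
            graph.set_mark(b, t.z, b, ARROW)
        return True
    return False


def orient(graph: MixedGraph, triples: list[TripleScore],
           propagate: bool = True) -> MixedGraph:
    """Greedy orientation by descending probability; stops at p <= 1/2.

    The skeleton is never altered — only circle endpoint marks are replaced
    by tails or arrowheads.  Earlier (higher-probability) assignments are
    never overwritten.
    """
    out = graph.copy()
    pool = sorted((t for t in triples if t.probability > 0.5),
                  key=lambda t: (-t.probability, t.x, t.z, t.y))
    done: set[int] = set()
    progress = True
    while progress:
        progress = False
        for i, t in enumerate(pool):
            if i in done:
                continue
            if not (out.has_edge(t.x, t.z) and out.has_edge(t.y, t.z)):
                done.add(i)
                continue
            if t.kind == "v":
                applied = _apply_v(out, t)
            elif propagate:
                applied = _apply_propagation(out, t)
            else:
                applied = False
            if applied:
                done.add(i)
                progress = True
                break   # restart from the top: highest-probability first
    return out
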