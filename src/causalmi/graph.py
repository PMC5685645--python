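"""Endpoint-marked mixed graphs.

Edges carry a mark at each end: tail (-), arrowhead (>), or circle (o,
undetermined).  The mark combinations give the edge categories of ancestral
graphs: tail-tail = undirected, tail-arrow = directed, arrow-arrow =
bidirected (the signature of a latent common cause), anything with a circle
= partially oriented.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["TAIL", "ARROW", "CIRCLE", "MixedGraph", "ancestral_violations"]

TAIL = "tail"
ARROW = "arrow"
CIRCLE = "circle"
_MARKS = (TAIL, ARROW, CIRCLE)


def _key(u, v):
    return (u, v) if u <= v else (v, u)


class MixedGraph:
    """Simple undirected adjacency with an endpoint mark at each edge end."""

    def __init__(self, nodes=()):
        self.nodes: list = list(nodes)
        self._nodeset = set(self.nodes)
        self._marks: dict[tuple, dict] = {}
        self._adj: dict = {n: set() for n in self.nodes}

    # -- construction -------------------------------------------------------

    def add_node(self, n) -> None:
        if n not in self._nodeset:
            self.nodes.append(n)
            self._nodeset.add(n)
            self._adj[n] = set()

    def add_edge(self, u, v, mark_u: str = CIRCLE, mark_v: str = CIRCLE) -> None:
        if u == v:
            raise ValueError("self-loops not allowed")
        for n in (u, v):
            if n not in self._nodeset:
                raise KeyError(f"unknown node {n!r}")
        if mark_u not in _MARKS or mark_v not in _MARKS:
            raise ValueError("invalid endpoint mark")
        self._marks[_key(u, v)] = {u: mark_u, v: mark_v}
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u, v) -> None:
        self._marks.pop(_key(u, v), None)
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    # -- queries ------------------------------------------------------------

    def has_edge(self, u, v) -> bool:
        return _key(u, v) in self._marks

    def neighbors(self, u) -> set:
        return set(self._adj[u])

    def edges(self) -> list[tuple]:
        """Sorted (u, v) pairs with u <= v."""
        return sorted(self._marks)

    @property
    def n_edges(self) -> int:
        return len(self._marks)

    def get_mark(self, u, v, at) -> str:
        """Endpoint mark of edge (u, v) at node ``at``."""
        return self._marks[_key(u, v)][at]

    def set_mark(self, u, v, at, mark: str) -> None:
        if mark not in _MARKS:
            raise ValueError("invalid endpoint mark")
        self._marks[_key(u, v)][at] = mark

    def category(self, u, v) -> str:
        m = self._marks[_key(u, v)]
        mu, mv = m[u], m[v]
        if mu == TAIL and mv == TAIL:
            return "undirected"
        if {mu, mv} == {TAIL, ARROW}:
            return "directed"
        if mu == ARROW and mv == ARROW:
            return "bidirected"
        return "partially-oriented"

    def skeleton_edges(self) -> set[tuple]:
        return set(self._marks)

    def copy(self) -> "MixedGraph":
        g = MixedGraph(self.nodes)
        for (u, v), m in self._marks.items():
            g.add_edge(u, v, m[u], m[v])
        return g

    def directed_subgraph(self) -> nx.DiGraph:
        """DiGraph of the definitely directed (tail -> arrow) edges."""
        d = nx.DiGraph()
        d.add_nodes_from(self.nodes)
        for (u, v), m in self._marks.items():
            if m[u] == TAIL and m[v] == ARROW:
                d.add_edge(u, v)
            elif m[u] == ARROW and m[v] == TAIL:
                d.add_edge(v, u)
        return d

    def __repr__(self) -> str:
        sym = {TAIL: "-", ARROW: ">", CIRCLE: "o"}
        parts = [f"{u} {sym[m[u]]}-{sym[m[v]]} {v}" for (u, v), m in sorted(self._marks.items())]
        return f"MixedGraph({len(self.nodes)} nodes: " + "; ".join(parts) + ")"


def ancestral_violations(graph: MixedGraph) -> list[dict]:
    """Constraints an ancestral pattern must satisfy, with offenders listed.

    Checks (over definite marks only; circle endpoints are undetermined and
    skipped): no directed cycles; no almost-directed cycles (a bidirected
    edge whose endpoints are connected by a directed path); no arrowheads at
    a node incident to an undirected edge.  Returns one record per violation;
    an empty list means the graph is a valid ancestral pattern.
    """
    out: list[dict] = []
    d = graph.directed_subgraph()
    try:
        for cycle in nx.simple_cycles(d):
            out.append({"kind": "directed-cycle", "nodes": list(cycle)})
    except nx.NetworkXNoCycle:  # pragma: no cover
        pass
    for (u, v) in graph.edges():
        if graph.category(u, v) == "bidirected":
            path = _directed_path(d, u, v) or _directed_path(d, v, u)
            if path:
                out.append({"kind": "almost-directed-cycle", "edge": (u, v),
                            "path": path})
    for (u, v) in graph.edges():
        if graph.category(u, v) == "undirected":
            for end in (u, v):
                for w in graph.neighbors(end):
                    if w in (u, v):
                        continue
                    if graph.get_mark(end, w, end) == ARROW:
                        out.append({"kind": "arrowhead-into-undirected",
                                    "edge": (u, v), "at": end, "from": w})
    return out


def _directed_path(d: nx.DiGraph, u, v) -> list | None:
    if nx.has_path(d, u, v):
        p = nx.shortest_path(d, u, v)
        if len(p) > 1:
            return p
    return None
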