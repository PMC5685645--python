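"""Pipeline orchestration, edge-summary output, and the run report.

The three steps run in order: (1) skeleton learning with contributor
collection, (2) optional permutation-confidence filtering plus partial-
correlation signs, (3) probabilistic orientation.  The run report records
everything needed to re-run the pipeline identically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .confidence import (ConfidenceConfig, assess_confidence, edge_sign,
                         filter_edges, log_edge_probability)
from .datatable import DataTable
from .graph import ARROW, CIRCLE, TAIL, MixedGraph, ancestral_violations
from .orientation import orient, unshielded_triples
from .skeleton import EdgeState, learn_skeleton

__all__ = ["PipelineConfig", "run_pipeline", "write_edge_summary",
           "read_edge_summary"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["x", "y", "ai", "n_xy_ai", "info", "cplx", "info_shifted",
                   "p_xy", "confidence", "sign", "endpoint_x", "endpoint_y",
                   "category"]


@dataclass
class PipelineConfig:
    """Settings for a full reconstruction run.

    ``confidence=None`` skips the permutation filtering of Step 2 (edge
    probabilities and signs are still computed); supply a
    :class:`ConfidenceConfig` to enable it.
    """

    latent: bool = True
    complexity: str = "nml"
    confidence: ConfidenceConfig | None = None
    orient: bool = True
    propagate: bool = True
    n_eff: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(data: DataTable, cfg: PipelineConfig | None = None
                 ) -> tuple[MixedGraph, dict[tuple[str, str], EdgeState], dict]:
    """Run Steps 1-3 and return (graph, edge states, run report)."""
    cfg = cfg or PipelineConfig()
    logging.getLogger("causalmi").setLevel(cfg.log_level)
    t0 = time.time()
    if cfg.n_eff is not None:
        data = data.with_n_eff(cfg.n_eff)

    graph, states = learn_skeleton(data, latent=cfg.latent, mode=cfg.complexity)
    n_edges_skeleton = graph.n_edges

    for pair in graph.edges():
        st = states[pair]
        st.log_p_xy = log_edge_probability(st)
        st.p_xy = float(np.exp(st.log_p_xy))
    if cfg.confidence is not None:
        assess_confidence(data, graph, states, cfg.confidence, cfg.complexity)
        graph = filter_edges(graph, states, cfg.confidence.threshold)
    for pair in graph.edges():
        st = states[pair]
        st.sign = edge_sign(data, st)

    if cfg.orient:
        triples = unshielded_triples(data, graph, states, cfg.complexity)
        graph = orient(graph, triples, propagate=cfg.propagate)
    violations = ancestral_violations(graph)

    n_a = [st.n_used for st in states.values()]
    report = {
        "config": cfg.as_dict(),
        "n_samples": data.n_samples,
        "n_vars": data.n_vars,
        "n_eff": data.n_eff,
        "n_available_min": int(min(n_a)) if n_a else 0,
        "n_available_max": int(max(n_a)) if n_a else 0,
        "level_coding": {c: list(l) for c, l in zip(data.columns, data.levels)},
        "edges_skeleton": n_edges_skeleton,
        "edges_final": graph.n_edges,
        "ancestral_violations": violations,
        "wall_time_s": time.time() - t0,
    }
    return graph, states, report


_MARK_SYM = {TAIL: "tail", ARROW: "arrow", CIRCLE: "circle"}


def write_edge_summary(states: dict[tuple[str, str], EdgeState],
                       graph: MixedGraph, path,
                       include_removed: bool = False) -> None:
    """TSV edge summary: one row per retained edge, 13 fixed columns.

    With ``include_removed`` the dropped pairs are appended, carrying their
    separating set in the ``ai`` column and category ``removed``/``filtered``.
    """
    rows = []
    for (u, v) in graph.edges():
        st = states[(u, v)]
        rows.append({
            "x": st.x, "y": st.y,
            "ai": ",".join(st.contributors),
            "n_xy_ai": st.n_used,
            "info": f"{st.info_cond:.6f}",
            "cplx": f"{st.complexity:.6f}",
            "info_shifted": f"{st.shifted:.6f}",
            "p_xy": f"{st.p_xy:.6g}",
            "confidence": "" if st.confidence is None else f"{st.confidence:.6g}",
            "sign": st.sign,
            "endpoint_x": graph.get_mark(st.x, st.y, st.x),
            "endpoint_y": graph.get_mark(st.x, st.y, st.y),
            "category": graph.category(st.x, st.y),
        })
    if include_removed:
        for pair, st in sorted(states.items()):
            if st.status in ("removed", "filtered"):
                rows.append({
                    "x": st.x, "y": st.y,
                    "ai": ",".join(st.sep_set if st.sep_set is not None
                                   else st.contributors),
                    "n_xy_ai": st.n_used,
                    "info": f"{st.info_cond:.6f}",
                    "cplx": f"{st.complexity:.6f}",
                    "info_shifted": f"{st.shifted:.6f}",
                    "p_xy": f"{st.p_xy:.6g}",
                    "confidence": ("" if st.confidence is None
                                   else f"{st.confidence:.6g}"),
                    "sign": st.sign,
                    "endpoint_x": "", "endpoint_y": "",
                    "category": st.status,
                })
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edge_summary(path) -> MixedGraph:
    """Rebuild the mixed graph from a written edge summary."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    nodes = sorted(set(df["x"]) | set(df["y"]))
    g = MixedGraph(nodes)
    for _, row in df.iterrows():
        if row["category"] in ("removed", "filtered"):
            continue
        g.add_edge(row["x"], row["y"], row["endpoint_x"], row["endpoint_y"])
    return g
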