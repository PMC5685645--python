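"""Skeleton and endpoint-aware precision/recall/F-score against a reference.

Skeleton mode compares unordered adjacencies.  Endpoint mode additionally
reclassifies every true-positive adjacency whose arrowhead pattern differs
from the reference (arrowhead vs tail-or-circle at either end) as
misoriented: TP' = TP - TP_misorient and FP' = FP + TP_misorient, so
misorientation can only lower the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import ARROW, MixedGraph

__all__ = ["MetricsReport", "skeleton_metrics", "endpoint_metrics"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tp_misorient: int
    precision: float
    recall: float
    fscore: float
    mode: str

    def as_dict(self) -> dict:
        return dict(tp=self.tp, fp=self.fp, fn=self.fn,
                    tp_misorient=self.tp_misorient, precision=self.precision,
                    recall=self.recall, fscore=self.fscore, mode=self.mode)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp + fn == 0:       # both graphs empty: perfect agreement
        return 1.0, 1.0, 1.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f


def _check_nodes(pred: MixedGraph, ref: MixedGraph) -> None:
    if set(pred.nodes) != set(ref.nodes):
        raise ValueError("prediction and reference node sets differ")


def skeleton_metrics(pred: MixedGraph, ref: MixedGraph) -> MetricsReport:
    """Unordered-adjacency precision/recall/F."""
    _check_nodes(pred, ref)
    p, r = pred.skeleton_edges(), ref.skeleton_edges()
    tp, fp, fn = len(p & r), len(p - r), len(r - p)
    prec, rec, f = _prf(tp, fp, fn)
    return MetricsReport(tp, fp, fn, 0, prec, rec, f, "skeleton")


def _misoriented(pred: MixedGraph, ref: MixedGraph, u, v) -> bool:
    for end in (u, v):
        if (pred.get_mark(u, v, end) == ARROW) != (ref.get_mark(u, v, end) == ARROW):
            return True
    return False


def endpoint_metrics(pred: MixedGraph, ref: MixedGraph) -> MetricsReport:
    """Precision/recall/F on TP' = TP - TP_misorient, FP' = FP + TP_misorient."""
    _check_nodes(pred, ref)
    p, r = pred.skeleton_edges(), ref.skeleton_edges()
    tp, fp, fn = len(p & r), len(p - r), len(r - p)
    mis = sum(1 for (u, v) in p & r if _misoriented(pred, ref, u, v))
    prec, rec, f = _prf(tp - mis, fp + mis, fn + mis)
    # recall denominator stays the reference edge count: TP' + (FN + mis)
    return MetricsReport(tp, fp, fn, mis, prec, rec, f, "endpoint")
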