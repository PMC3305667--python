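"""Scoring an estimated graph against a known truth.

All counts are taken over the ``p(p-1)/2`` unordered node pairs.  The
structural Hamming distance (SHD) is the number of edge insertions plus
deletions transforming one graph into the other, which equals the number of
false-positive plus false-negative edges.  Sensitivity is TP/(TP+FN),
specificity TN/(TN+FP), and the Youden index ``J = sensitivity +
specificity - 1`` summarises both in one number (1 for perfect recovery, 0
for an empty estimate against a nonempty, non-complete truth).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NodeSetMismatchError
from .estimate import EstimatedGraph
from .mrf import TrueGraph

__all__ = ["ConfusionCounts", "PerformanceMetrics", "confusion", "shd", "metrics"]

Graph = EstimatedGraph | TrueGraph


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-wise confusion counts over all unordered node pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    shd: int
    sensitivity: float
    specificity: float
    youden: float


def _check_nodes(est: Graph, truth: Graph) -> None:
    a, b = set(est.nodes), set(truth.nodes)
    if a != b:
        raise NodeSetMismatchError(
            f"node sets differ; only in estimate: {sorted(a - b)}, "
            f"only in truth: {sorted(b - a)}"
        )


def confusion(est: Graph, truth: Graph) -> ConfusionCounts:
    """Count TP/FP/TN/FN edges over all unordered node pairs."""
    _check_nodes(est, truth)
    p = len(truth.nodes)
    pairs = p * (p - 1) // 2
    tp = len(est.edges & truth.edges)
    fp = len(est.edges - truth.edges)
    fn = len(truth.edges - est.edges)
    return ConfusionCounts(tp=tp, fp=fp, tn=pairs - tp - fp - fn, fn=fn)


def shd(est: Graph, truth: Graph) -> int:
    """Structural Hamming distance: size of the edge-set symmetric difference."""
    _check_nodes(est, truth)
    return len(est.edges ^ truth.edges)


def metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    """SHD, sensitivity, specificity and Youden index from confusion counts.

    Degenerate denominators use the vacuous-truth convention: sensitivity is
    1 when the truth has no edges, specificity is 1 when the truth is
    complete, keeping ``J`` defined everywhere.
    """
    q = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 1.0
    p_spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else 1.0
    return PerformanceMetrics(
        shd=counts.fp + counts.fn,
        sensitivity=q,
        specificity=p_spec,
        youden=q + p_spec - 1.0,
    )
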