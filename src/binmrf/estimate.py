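"""Graph estimation from binary data by node-wise penalized regression.

Each variable is regressed on all others with an L1 penalty; the nonzero
coefficients define that node's neighborhood.  Neighborhoods are turned into
an undirected edge set with the conservative AND-rule (both nodes select
each other) or the liberal OR-rule (at least one does).

The Bolasso variant stabilises selection by bootstrap aggregation: the
node-wise lasso is refitted on ``B`` bootstrap resamples and a candidate
neighbor is kept only if it is selected in at least a fraction ``π_cut`` of
the resamples.  Two penalty protocols are supported.  With a
cross-validated rule the penalty is fixed once on the original data and
reused in every resample.  With a size rule the penalty is re-selected
within each resample as the largest grid value whose active set reaches the
target neighborhood size ``l``, so every bootstrap fit contributes an
active set of (at least) ``l`` candidates; a penalty tuned to an active-set
size transfers as a size, not as a fixed λ, and keeping it fixed instead
makes every selection frequency hover near the entry boundary.  Selection
frequencies are retained so several thresholds can be applied without
refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, DegenerateOutcomeError, DegeneratePredictorError
from .lasso import (
    LogisticFit,
    PenaltyGrid,
    fit_l1_logistic,
    penalty_for_size,
    penalty_grid,
    regularization_path,
    select_penalty_cv,
    select_penalty_ic,
    standardize,
)
from .mrf import BinaryDataset, TrueGraph, _canonical_edge

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodSet",
    "EstimatedGraph",
    "lasso_neighborhoods",
    "bolasso_neighborhoods",
    "apply_cut",
    "combine_edges",
    "estimate_graph",
    "METHODS",
]

METHODS = ("lasso-cv", "lasso-aic", "lasso-bic", "bolasso", "bolasso-cv")


@dataclass(frozen=True)
class NeighborhoodSet:
    """Per-node selected predictor sets, with Bolasso selection frequencies.

    ``frequencies`` maps node ``a`` to a map ``b → μ_ba``, the fraction of
    bootstrap refits in which ``b`` entered the neighborhood of ``a``; it is
    ``None`` for single-lasso fits.
    """

    nodes: tuple[str, ...]
    selected: Mapping[str, frozenset[str]]
    penalty_used: Mapping[str, float]
    frequencies: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        for a, sel in self.selected.items():
            if a in sel:
                raise ValueError(f"node {a!r} appears in its own neighborhood")


@dataclass(frozen=True)
class EstimatedGraph:
    """An undirected estimate with its full method record."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    method: str | None = None
    rule: str | None = None
    params: Mapping[str, object] = field(default_factory=dict)
    frequencies: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge endpoint outside node set: ({a!r}, {b!r})")
            canon.add(_canonical_edge(a, b))
        object.__setattr__(self, "edges", frozenset(canon))
        object.__setattr__(self, "params", dict(self.params))


@dataclass
class _NodeProblem:
    """One node-wise regression: outcome column and raw predictor matrix."""

    node: str
    y: np.ndarray
    X_raw: np.ndarray
    labels: list[str]


def _parse_rule(penalty_rule: str) -> tuple[str, int | None]:
    rule = penalty_rule.lower()
    if rule in ("cv", "aic", "bic"):
        return rule, None
    if rule.startswith("size:"):
        l = int(rule.split(":", 1)[1])
        return "size", l
    raise ConfigurationError(
        f"unknown penalty rule {penalty_rule!r}; use 'cv', 'aic', 'bic' or 'size:<l>'"
    )


def _split_columns(data: BinaryDataset) -> tuple[list[_NodeProblem], list[str]]:
    """Build the per-node regression problems, sidelining constant columns.

    Constant columns cannot act as outcome or predictor; they are reported
    with a warning and kept only as isolated nodes.
    """
    X = data.data.astype(float)
    usable = [j for j in range(data.p) if X[:, j].std() > 0.0]
    dropped = [data.names[j] for j in range(data.p) if j not in set(usable)]
    if dropped:
        logger.warning(
            "constant columns excluded from estimation (kept as isolated nodes): %s",
            ", ".join(dropped),
        )
    if len(usable) < 3:
        raise ConfigurationError(
            "need at least 3 non-constant variables for node-wise estimation"
        )
    problems = []
    for j in usable:
        others = [k for k in usable if k != j]
        problems.append(
            _NodeProblem(
                node=data.names[j],
                y=X[:, j],
                X_raw=X[:, others],
                labels=[data.names[k] for k in others],
            )
        )
    return problems, dropped


def _select_node_penalty(
    prob: _NodeProblem,
    rule: str,
    l: int | None,
    folds: int,
    seed: int,
) -> tuple[float, LogisticFit]:
    """Fix the penalty for one node on the original data and fit at it."""
    Xs, _, _ = standardize(prob.X_raw)
    grid = penalty_grid(prob.y, Xs)
    if rule == "cv":
        lam = select_penalty_cv(prob.y, Xs, grid, folds=folds, seed=seed)
    elif rule in ("aic", "bic"):
        path = regularization_path(prob.y, Xs, grid, labels=prob.labels)
        lam = select_penalty_ic(prob.y, Xs, grid, rule, path=path)
    elif rule == "size":
        l_eff = min(l, Xs.shape[1])
        path = regularization_path(prob.y, Xs, grid, labels=prob.labels)
        lam = penalty_for_size(prob.y, Xs, grid, l_eff, path=path)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown rule {rule!r}")
    fit = fit_l1_logistic(prob.y, Xs, lam, labels=prob.labels)
    return lam, fit


def lasso_neighborhoods(
    data: BinaryDataset,
    penalty_rule: str,
    folds: int = 10,
    seed: int = 0,
) -> NeighborhoodSet:
    """Node-wise lasso neighborhoods with a per-node penalty rule.

    ``penalty_rule`` is one of ``'cv'``, ``'aic'``, ``'bic'`` or
    ``'size:<l>'``.
    """
    rule, l = _parse_rule(penalty_rule)
    problems, dropped = _split_columns(data)
    selected: dict[str, frozenset[str]] = {name: frozenset() for name in dropped}
    penalties: dict[str, float] = {}
    for prob in problems:
        lam, fit = _select_node_penalty(prob, rule, l, folds, seed)
        selected[prob.node] = fit.active_set
        penalties[prob.node] = lam
    return NeighborhoodSet(
        nodes=data.names, selected=selected, penalty_used=penalties
    )


@dataclass
class _NodeBootContext:
    """Per-node state reused across bootstrap refits."""

    prob: _NodeProblem
    grid_values: np.ndarray
    lam: float  # penalty selected on the original data
    k0: int  # grid index of lam (size rule); -1 for fixed-penalty rules
    warm: LogisticFit | None
    rule: str  # 'fixed' or 'size'
    l: int | None


def _make_boot_contexts(
    problems: list[_NodeProblem],
    rule: str,
    l: int | None,
    folds: int,
    seed: int,
    paths: Mapping[str, tuple] | None = None,
) -> dict[str, _NodeBootContext]:
    """Select per-node penalties on the original data and cache warm starts.

    ``paths`` optionally supplies precomputed ``(Xs, grid, path)`` triples
    per node to avoid refitting regularization paths.
    """
    contexts: dict[str, _NodeBootContext] = {}
    for prob in problems:
        if paths is not None and prob.node in paths:
            Xs, grid, path = paths[prob.node]
        else:
            Xs, _, _ = standardize(prob.X_raw)
            grid = penalty_grid(prob.y, Xs)
            path = None
        if rule == "cv":
            lam = select_penalty_cv(prob.y, Xs, grid, folds=folds, seed=seed)
            warm = fit_l1_logistic(prob.y, Xs, lam, labels=prob.labels)
            contexts[prob.node] = _NodeBootContext(
                prob, grid.values, lam, -1, warm, "fixed", None
            )
        elif rule == "size":
            if path is None:
                path = regularization_path(prob.y, Xs, grid, labels=prob.labels)
            l_eff = min(l, Xs.shape[1])
            lam = penalty_for_size(prob.y, Xs, grid, l_eff, path=path)
            k0 = int(np.flatnonzero(grid.values == lam)[0])
            contexts[prob.node] = _NodeBootContext(
                prob, grid.values, lam, k0, path[k0], "size", l_eff
            )
        else:
            raise ConfigurationError(
                f"bolasso penalty rule must be 'cv' or 'size:<l>', got {rule!r}"
            )
    return contexts


def _bootstrap_active(ctx: _NodeBootContext, idx: np.ndarray) -> frozenset[str]:
    """Refit one node on a bootstrap resample.

    With the fixed rule the original-data penalty is reused; with the size
    rule the largest grid penalty whose active set reaches the target size
    is re-located within the resample by a warm-started walk on the grid
    starting from the original-data index.  A resample with a one-class
    outcome contributes an empty active set; predictors constant within the
    resample are treated as zero coefficients.
    """
    prob = ctx.prob
    yb = prob.y[idx]
    if yb.min() == yb.max():
        return frozenset()
    Xb = prob.X_raw[idx]
    sd = Xb.std(axis=0)
    keep = np.flatnonzero(sd > 0.0)
    if keep.size == 0:
        return frozenset()
    Xs = (Xb[:, keep] - Xb[:, keep].mean(axis=0)) / sd[keep]
    labels = [prob.labels[j] for j in keep]
    warm = ctx.warm
    if warm is not None and keep.size != warm.coefficients.size:
        warm = None
    grid = ctx.grid_values
    if ctx.rule == "fixed":
        fit = fit_l1_logistic(yb, Xs, ctx.lam, labels=labels, warm=warm)
        return fit.active_set
    # size rule: locate the largest grid penalty reaching the target size
    l_eff = min(ctx.l, keep.size)
    k = ctx.k0
    fit = fit_l1_logistic(yb, Xs, grid[k], labels=labels, warm=warm)
    if fit.n_active >= l_eff:
        while k > 0:
            trial = fit_l1_logistic(yb, Xs, grid[k - 1], labels=labels, warm=fit)
            if trial.n_active >= l_eff:
                k -= 1
                fit = trial
            else:
                break
    else:
        while k < grid.size - 1 and fit.n_active < l_eff:
            k += 1
            fit = fit_l1_logistic(yb, Xs, grid[k], labels=labels, warm=fit)
    return fit.active_set


def bolasso_neighborhoods(
    data: BinaryDataset,
    B: int,
    penalty_rule: str,
    pi_cut: float,
    seed: int = 0,
    folds: int = 10,
) -> NeighborhoodSet:
    """Bootstrap-aggregated neighborhoods (Bolasso).

    The node-wise lasso is refitted on ``B`` row resamples (drawn with
    replacement; resample ``b`` is seeded as ``seed + b``) and a neighbor is
    kept if its selection frequency ``μ`` reaches ``pi_cut``.  With
    ``penalty_rule='cv'`` the penalty is fixed per node on the original data
    and reused across resamples; with ``'size:<l>'`` the penalty is
    re-selected within each resample to reach an active set of size ``l``.
    Degenerate resample fits contribute empty active sets while remaining in
    the denominator.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if not 0.0 < pi_cut <= 1.0:
        raise ConfigurationError("pi_cut must be in (0, 1]")
    rule, l = _parse_rule(penalty_rule)
    if rule not in ("cv", "size"):
        raise ConfigurationError(
            f"bolasso penalty rule must be 'cv' or 'size:<l>', got {penalty_rule!r}"
        )
    problems, dropped = _split_columns(data)
    n = data.n
    contexts = _make_boot_contexts(problems, rule, l, folds, seed)
    counts: dict[str, dict[str, int]] = {
        prob.node: {b: 0 for b in prob.labels} for prob in problems
    }
    for b in range(B):
        idx = np.random.default_rng(seed + b).integers(0, n, size=n)
        for prob in problems:
            for lbl in _bootstrap_active(contexts[prob.node], idx):
                counts[prob.node][lbl] += 1
    frequencies = {
        a: {b: c / B for b, c in row.items()} for a, row in counts.items()
    }
    for name in dropped:
        frequencies[name] = {}
    selected = {
        a: frozenset(b for b, mu in row.items() if mu >= pi_cut)
        for a, row in frequencies.items()
    }
    return NeighborhoodSet(
        nodes=data.names,
        selected=selected,
        penalty_used={a: ctx.lam for a, ctx in contexts.items()},
        frequencies=frequencies,
    )


def apply_cut(nbhd: NeighborhoodSet, pi_cut: float) -> NeighborhoodSet:
    """Re-threshold retained Bolasso frequencies at a new ``pi_cut``."""
    if nbhd.frequencies is None:
        raise ConfigurationError("neighborhood set carries no selection frequencies")
    if not 0.0 < pi_cut <= 1.0:
        raise ConfigurationError("pi_cut must be in (0, 1]")
    selected = {
        a: frozenset(b for b, mu in row.items() if mu >= pi_cut)
        for a, row in nbhd.frequencies.items()
    }
    return NeighborhoodSet(
        nodes=nbhd.nodes,
        selected=selected,
        penalty_used=nbhd.penalty_used,
        frequencies=nbhd.frequencies,
    )


def combine_edges(nbhd: NeighborhoodSet, rule: str) -> EstimatedGraph:
    """Combine neighborhoods into an undirected edge set.

    AND-rule: edge (a, b) iff ``a ∈ ne_b`` and ``b ∈ ne_a``.
    OR-rule:  edge (a, b) iff ``a ∈ ne_b`` or ``b ∈ ne_a``.
    The AND edge set is always a subset of the OR edge set.
    """
    rule_u = rule.upper()
    if rule_u not in ("AND", "OR"):
        raise ConfigurationError(f"rule must be 'AND' or 'OR', got {rule!r}")
    edges = set()
    nodes = nbhd.nodes
    sel = nbhd.selected
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            in_a = b in sel.get(a, frozenset())
            in_b = a in sel.get(b, frozenset())
            if (in_a and in_b) if rule_u == "AND" else (in_a or in_b):
                edges.add(_canonical_edge(a, b))
    return EstimatedGraph(
        nodes=nodes, edges=frozenset(edges), rule=rule_u,
        frequencies=nbhd.frequencies,
    )


def estimate_graph(
    data: BinaryDataset,
    method: str,
    rule: str = "OR",
    params: Mapping[str, object] | None = None,
) -> EstimatedGraph:
    """Estimate an undirected graph with one of the five named methods.

    ``lasso-cv`` / ``lasso-aic`` / ``lasso-bic``
        single node-wise lasso with the corresponding penalty rule;
    ``bolasso``
        Bolasso with a size-targeted penalty (requires ``B``, ``pi_cut``,
        ``l``);
    ``bolasso-cv``
        Bolasso with a cross-validated penalty (requires ``B``, ``pi_cut``).
    """
    params = dict(params or {})
    method_l = method.lower()
    if method_l not in METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; choose from {', '.join(METHODS)}"
        )
    seed = int(params.get("seed", 0))
    folds = int(params.get("folds", 10))

    def _require(key: str) -> object:
        if key not in params or params[key] is None:
            raise ConfigurationError(f"method {method!r} requires parameter {key!r}")
        return params[key]

    if method_l.startswith("lasso-"):
        nbhd = lasso_neighborhoods(
            data, method_l.split("-", 1)[1], folds=folds, seed=seed
        )
    elif method_l == "bolasso":
        B = int(_require("B"))
        pi_cut = float(_require("pi_cut"))
        l = int(_require("l"))
        nbhd = bolasso_neighborhoods(
            data, B=B, penalty_rule=f"size:{l}", pi_cut=pi_cut, seed=seed, folds=folds
        )
    else:  # bolasso-cv
        B = int(_require("B"))
        pi_cut = float(_require("pi_cut"))
        nbhd = bolasso_neighborhoods(
            data, B=B, penalty_rule="cv", pi_cut=pi_cut, seed=seed, folds=folds
        )
    graph = combine_edges(nbhd, rule)
    return EstimatedGraph(
        nodes=graph.nodes,
        edges=graph.edges,
        method=method_l,
        rule=graph.rule,
        params=params,
        frequencies=graph.frequencies,
    )
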