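"""Simulation-study driver: grid sweeps, summaries, optimal configurations.

For each replicate and sample size a dataset is drawn from the chosen true
structure by Gibbs sampling; every requested method is then run on the same
dataset and scored against the truth.  For the Bolasso the expensive part —
the per-resample node-wise lasso refits — is computed once at the largest
requested bootstrap count; smaller counts reuse the leading resamples and
all inclusion thresholds are applied to the stored selection frequencies
without refitting.  Both the AND- and OR-rule are evaluated from the same
neighborhoods.

Everything is reproducible from ``base_seed``: per-cell seeds are derived
with a CRC32 hash of the cell coordinates, so adding grid values does not
shift the seeds of existing cells.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import ConfigurationError
from .estimate import (
    METHODS,
    NeighborhoodSet,
    _bootstrap_active,
    _make_boot_contexts,
    _select_node_penalty,
    _split_columns,
    combine_edges,
)
from .evaluate import confusion, metrics
from .lasso import (
    penalty_grid,
    regularization_path,
    select_penalty_ic,
    standardize,
)
from .mrf import (
    DEFAULT_BURN_IN,
    DEFAULT_SPACING,
    BinaryDataset,
    InteractionMatrix,
    gibbs_sample,
    preset_structure,
    true_graph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "OptimalConfiguration",
    "run_study",
    "summarize",
    "optimal_configuration",
]

_SEED_MOD = 2**31 - 1


def _derive_seed(base_seed: int, *parts: object) -> int:
    key = "|".join(str(p) for p in parts).encode()
    return (int(base_seed) + zlib.crc32(key)) % _SEED_MOD


@dataclass(frozen=True)
class StudyConfig:
    """Grid definition for one simulation study."""

    structure: str = "paper19"
    n_grid: tuple[int, ...] = (50, 100, 200, 500, 1000)
    B_grid: tuple[int, ...] = (40, 80, 120, 160, 200)
    pi_cut_grid: tuple[float, ...] = (0.90, 0.95, 0.99, 1.00)
    l_grid: tuple[int, ...] = (1, 2, 5, 10, 18)
    methods: tuple[str, ...] = METHODS
    rules: tuple[str, ...] = ("AND", "OR")
    replicates: int = 10
    base_seed: int = 0
    burn_in: int = DEFAULT_BURN_IN
    spacing: int = DEFAULT_SPACING
    folds: int = 10

    def __post_init__(self) -> None:
        for name in ("n_grid", "B_grid", "pi_cut_grid", "l_grid", "methods", "rules"):
            value = tuple(getattr(self, name))
            object.__setattr__(self, name, value)
            if not value:
                raise ConfigurationError(f"{name} must be non-empty")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        unknown = set(m.lower() for m in self.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
        object.__setattr__(
            self, "methods", tuple(m.lower() for m in self.methods)
        )
        object.__setattr__(self, "rules", tuple(r.upper() for r in self.rules))
        if set(self.rules) - {"AND", "OR"}:
            raise ConfigurationError("rules must be a subset of {AND, OR}")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})


_ROW_COLUMNS = [
    "method", "rule", "n", "B", "pi_cut", "l", "replicate", "seed",
    "tp", "fp", "tn", "fn", "shd", "sensitivity", "specificity", "youden",
]


def _score_rows(
    nbhd: NeighborhoodSet,
    truth,
    rules: Sequence[str],
    base: dict,
) -> list[dict]:
    rows = []
    for rule in rules:
        graph = combine_edges(nbhd, rule)
        counts = confusion(graph, truth)
        perf = metrics(counts)
        rows.append(
            {
                **base,
                "rule": rule,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
                "shd": perf.shd,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "youden": perf.youden,
            }
        )
    return rows


def _neighborhoods_from_counts(
    problems, dropped, nodes, counts: np.ndarray, B: int, pi_cut: float, lambdas
) -> NeighborhoodSet:
    """Threshold prefix counts (resamples 0..B-1) at pi_cut."""
    frequencies: dict[str, dict[str, float]] = {}
    for a_idx, prob in enumerate(problems):
        frequencies[prob.node] = {
            lbl: counts[a_idx, j] / B for j, lbl in enumerate(prob.labels)
        }
    for name in dropped:
        frequencies[name] = {}
    selected = {
        a: frozenset(b for b, mu in row.items() if mu >= pi_cut)
        for a, row in frequencies.items()
    }
    return NeighborhoodSet(
        nodes=nodes, selected=selected, penalty_used=lambdas, frequencies=frequencies
    )


def _run_bolasso_cells(
    data: BinaryDataset,
    truth,
    config: StudyConfig,
    method: str,
    contexts: dict,
    l_value,
    boot_seed: int,
    base_row: dict,
) -> list[dict]:
    """Bootstrap once at max(B_grid); score every (B, pi_cut, rule) cell.

    Smaller bootstrap counts reuse the leading resamples (prefix counts), so
    the expensive refits run exactly once per (replicate, n, l).
    """
    problems, dropped = _split_columns(data)
    max_B = max(config.B_grid)
    n = data.n
    counts = np.zeros((len(problems), max(len(p.labels) for p in problems)), dtype=int)
    prefix: dict[int, np.ndarray] = {}
    sorted_B = sorted(set(config.B_grid))
    next_B = 0
    lambdas = {a: ctx.lam for a, ctx in contexts.items()}
    for b in range(max_B):
        idx = np.random.default_rng(boot_seed + b).integers(0, n, size=n)
        for a_idx, prob in enumerate(problems):
            active = _bootstrap_active(contexts[prob.node], idx)
            if active:
                for j, lbl in enumerate(prob.labels):
                    if lbl in active:
                        counts[a_idx, j] += 1
        if next_B < len(sorted_B) and b + 1 == sorted_B[next_B]:
            prefix[b + 1] = counts.copy()
            next_B += 1
    rows = []
    for B in config.B_grid:
        for pi_cut in config.pi_cut_grid:
            nbhd = _neighborhoods_from_counts(
                problems, dropped, data.names, prefix[B], B, pi_cut, lambdas
            )
            base = {**base_row, "method": method, "B": B, "pi_cut": pi_cut, "l": l_value}
            rows.extend(_score_rows(nbhd, truth, config.rules, base))
    return rows


def run_study(
    config: StudyConfig, structure: InteractionMatrix | None = None
) -> pd.DataFrame:
    """Run the full grid and return one row per evaluated cell replicate.

    Parameters not applicable to a method (for example ``B`` for a single
    lasso) are recorded as nulls.  Target neighborhood sizes at or above the
    number of variables are skipped with a log entry.
    """
    if structure is None:
        structure = preset_structure(config.structure)
    truth = true_graph(structure)
    p = structure.p
    rows: list[dict] = []
    for r in range(config.replicates):
        for n in config.n_grid:
            ds_seed = _derive_seed(config.base_seed, "data", r, n)
            data = gibbs_sample(
                structure, n, burn_in=config.burn_in,
                spacing=config.spacing, seed=ds_seed,
            )
            base_row = {"n": n, "replicate": r, "seed": ds_seed}
            problems, dropped = _split_columns(data)
            # per-node paths on the original data, shared by bic/aic/size rules
            path_cache: dict[str, tuple] = {}

            def node_path(prob):
                if prob.node not in path_cache:
                    Xs, _, _ = standardize(prob.X_raw)
                    grid = penalty_grid(prob.y, Xs)
                    path = regularization_path(prob.y, Xs, grid, labels=prob.labels)
                    path_cache[prob.node] = (Xs, grid, path)
                return path_cache[prob.node]

            boot_seed = _derive_seed(config.base_seed, "boot", r, n)
            for method in config.methods:
                if method.startswith("lasso-"):
                    crit = method.split("-", 1)[1]
                    selected = {name: frozenset() for name in dropped}
                    lambdas = {}
                    for prob in problems:
                        if crit == "cv":
                            lam, fit = _select_node_penalty(
                                prob, "cv", None, config.folds, ds_seed
                            )
                        else:
                            Xs, grid, path = node_path(prob)
                            lam = select_penalty_ic(
                                prob.y, Xs, grid, crit, path=path
                            )
                            fit = path[
                                int(np.flatnonzero(grid.values == lam)[0])
                            ]
                        selected[prob.node] = fit.active_set
                        lambdas[prob.node] = lam
                    nbhd = NeighborhoodSet(
                        nodes=data.names, selected=selected, penalty_used=lambdas
                    )
                    base = {
                        **base_row, "method": method,
                        "B": None, "pi_cut": None, "l": None,
                    }
                    rows.extend(_score_rows(nbhd, truth, config.rules, base))
                elif method == "bolasso":
                    for l in config.l_grid:
                        if l >= p:
                            logger.info(
                                "skipping infeasible neighborhood size l=%d (p=%d)",
                                l, p,
                            )
                            continue
                        paths = {prob.node: node_path(prob) for prob in problems}
                        contexts = _make_boot_contexts(
                            problems, "size", l, config.folds, ds_seed, paths=paths
                        )
                        rows.extend(
                            _run_bolasso_cells(
                                data, truth, config, method,
                                contexts, l, boot_seed, base_row,
                            )
                        )
                else:  # bolasso-cv
                    contexts = _make_boot_contexts(
                        problems, "cv", None, config.folds, ds_seed
                    )
                    rows.extend(
                        _run_bolasso_cells(
                            data, truth, config, method,
                            contexts, None, boot_seed, base_row,
                        )
                    )
    return pd.DataFrame(rows, columns=_ROW_COLUMNS)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, median, sd, min and max of SHD and Youden index per grid cell.

    The sd of a single-replicate cell is reported as null.
    """
    if results.empty:
        raise ValueError("results table is empty")
    grouped = results.groupby(
        ["method", "rule", "n", "B", "pi_cut", "l"], dropna=False
    )
    agg = grouped.agg(
        shd_mean=("shd", "mean"),
        shd_median=("shd", "median"),
        shd_sd=("shd", "std"),
        shd_min=("shd", "min"),
        shd_max=("shd", "max"),
        youden_mean=("youden", "mean"),
        youden_median=("youden", "median"),
        youden_sd=("youden", "std"),
        youden_min=("youden", "min"),
        youden_max=("youden", "max"),
        replicates=("shd", "size"),
    )
    return agg.reset_index()


@dataclass(frozen=True)
class OptimalConfiguration:
    """Grid cell selected by the additive model, with the raw cell-mean
    optimum reported alongside as a robustness check."""

    pi_cut: float
    B: int
    l: int
    fitted_value: float
    cell_mean_optimum: tuple[float, int, int]
    outcome: str


def optimal_configuration(
    results: pd.DataFrame, outcome: str = "shd"
) -> OptimalConfiguration:
    """Pick (pi_cut, B, l) optimising fitted performance for the Bolasso.

    An ordinary least-squares model with factor-coded ``pi_cut``, ``B`` and
    ``l`` plus the ``pi_cut × l`` interaction is fitted to the Bolasso rows;
    the grid cell minimising the fitted SHD (or maximising the fitted Youden
    index) is returned.  ``B`` enters the model only when it varies.
    """
    if outcome not in ("shd", "youden"):
        raise ValueError("outcome must be 'shd' or 'youden'")
    df = results[results["method"] == "bolasso"].dropna(subset=["pi_cut", "B", "l"])
    if df.empty:
        raise ConfigurationError("no bolasso rows in results")
    df = df.copy()
    for col, minimum in (("pi_cut", 2), ("l", 2)):
        if df[col].nunique() < minimum:
            raise ConfigurationError(
                f"need at least 2 levels of {col} to fit the factor model"
            )
    terms = ["C(pi_cut)", "C(l)", "C(pi_cut):C(l)"]
    if df["B"].nunique() >= 2:
        terms.insert(2, "C(B)")
    model = smf.ols(f"{outcome} ~ " + " + ".join(terms), data=df).fit()
    cells = df[["pi_cut", "B", "l"]].drop_duplicates().reset_index(drop=True)
    fitted = model.predict(cells)
    idx = int(fitted.idxmin() if outcome == "shd" else fitted.idxmax())
    cell_means = df.groupby(["pi_cut", "B", "l"])[outcome].mean()
    best_cell = cell_means.idxmin() if outcome == "shd" else cell_means.idxmax()
    return OptimalConfiguration(
        pi_cut=float(cells.loc[idx, "pi_cut"]),
        B=int(cells.loc[idx, "B"]),
        l=int(cells.loc[idx, "l"]),
        fitted_value=float(fitted[idx]),
        cell_mean_optimum=(
            float(best_cell[0]), int(best_cell[1]), int(best_cell[2])
        ),
        outcome=outcome,
    )
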