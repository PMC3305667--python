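"""L1-penalized logistic regression with exact-zero coefficient paths.

Fits are computed by iteratively reweighted least squares with cyclic
coordinate descent on the working quadratic (the glmnet strategy), which
yields hard zeros via soft-thresholding.  The objective minimised is the
unscaled penalized negative log-likelihood

    -l(b0, β) + λ Σ_j |β_j|,

with an unpenalized intercept and predictors standardized to mean zero and
variance one (population divisor).  Convergence is certified through the
Karush-Kuhn-Tucker conditions: writing ``s_j = x_j'(y - π)`` for the score,
a solution satisfies ``|s_j| ≤ λ`` for zero coefficients and
``s_j = λ sign(β_j)`` for nonzero ones, both within ``KKT_TOL``.

Penalty selection supports stratified cross-validation (out-of-fold
log-likelihood), AIC/BIC with degrees of freedom equal to the number of
nonzero slopes, and a target neighborhood size (the largest penalty whose
active set reaches the requested size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateOutcomeError, DegeneratePredictorError

__all__ = [
    "LogisticFit",
    "PenaltyGrid",
    "standardize",
    "penalty_grid",
    "fit_l1_logistic",
    "regularization_path",
    "select_penalty_cv",
    "select_penalty_ic",
    "penalty_for_size",
    "information_criterion",
    "kkt_violation",
    "KKT_TOL",
    "GRID_SIZE",
    "GRID_MIN_RATIO",
]

#: Absolute tolerance on the KKT stationarity conditions at a solution.
KKT_TOL = 1e-6
#: Number of penalty values on the default grid.
GRID_SIZE = 100
#: Ratio of the smallest to the largest grid penalty.
GRID_MIN_RATIO = 1e-3

_W_FLOOR = 1e-6
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class LogisticFit:
    """A single penalized fit on standardized predictors."""

    intercept: float
    coefficients: np.ndarray
    penalty: float
    loglik: float
    active_set: frozenset[str]

    @property
    def n_active(self) -> int:
        return len(self.active_set)


@dataclass(frozen=True)
class PenaltyGrid:
    """Strictly decreasing penalty sequence from ``λ_max`` down to
    ``λ_max × GRID_MIN_RATIO``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("grid must be a non-empty 1-d sequence")
        if np.any(values <= 0):
            raise ValueError("grid values must be positive")
        if np.any(np.diff(values) >= 0):
            raise ValueError("grid must be strictly decreasing")

    @property
    def size(self) -> int:
        return self.values.size


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean zero and scale to unit variance (divisor n).

    Returns ``(X_std, center, scale)``; raises
    :class:`~binmrf.errors.DegeneratePredictorError` naming the first
    constant column.
    """
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        raise DegeneratePredictorError(
            f"column {zero[0]} is constant and cannot be standardized"
        )
    return (X - center) / scale, center, scale


def _check_outcome(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome takes a single value")
    return y


def penalty_grid(
    y: np.ndarray,
    X: np.ndarray,
    size: int = GRID_SIZE,
    min_ratio: float = GRID_MIN_RATIO,
) -> PenaltyGrid:
    """Log-spaced grid anchored at ``λ_max = max_j |x_j'(y - ȳ)|``.

    ``λ_max`` is the smallest penalty at which the active set is empty
    (the score at the intercept-only fit).
    """
    y = _check_outcome(y)
    X = np.asarray(X, dtype=float)
    lam_max = float(np.abs(X.T @ (y - y.mean())).max())
    if lam_max <= 0.0:
        lam_max = 1e-3  # orthogonal predictors; any positive anchor works
    return PenaltyGrid(
        values=np.geomspace(lam_max, lam_max * min_ratio, num=size)
    )


def _unpenalized_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log-likelihood Σ y η - log(1 + exp(η)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def kkt_violation(
    y: np.ndarray, X: np.ndarray, lam: float, intercept: float, beta: np.ndarray
) -> float:
    """Largest absolute violation of the KKT stationarity conditions."""
    eta = intercept + X @ beta
    p = expit(eta)
    score = X.T @ (y - p)
    viol = abs(float(np.sum(y - p)))  # intercept score must vanish
    for j in range(beta.size):
        if beta[j] == 0.0:
            viol = max(viol, abs(score[j]) - lam)
        else:
            viol = max(viol, abs(score[j] - lam * math.copysign(1.0, beta[j])))
    return viol


@njit(cache=True)
def _cd_core(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta: np.ndarray,
    b0: float,
    target: float,
    max_outer: int,
) -> float:  # pragma: no cover - exercised via fit_l1_logistic
    n, m = X.shape
    for _outer in range(max_outer):
        eta = np.dot(X, beta)
        resid_sum = 0.0
        w = np.empty(n)
        z = np.empty(n)
        resid = np.empty(n)
        for i in range(n):
            e = eta[i] + b0
            if e > _ETA_CLIP:
                e = _ETA_CLIP
            elif e < -_ETA_CLIP:
                e = -_ETA_CLIP
            prob = 1.0 / (1.0 + math.exp(-e))
            r = y[i] - prob
            resid[i] = r
            resid_sum += r
            wi = prob * (1.0 - prob)
            if wi < _W_FLOOR:
                wi = _W_FLOOR
            w[i] = wi
            z[i] = e + r / wi
            eta[i] = e
        # stationarity of the true (non-quadratic) objective
        ok = abs(resid_sum) <= target
        if ok:
            score = np.dot(resid, X)
            for j in range(m):
                if beta[j] == 0.0:
                    if abs(score[j]) > lam + target:
                        ok = False
                        break
                else:
                    sgn = 1.0 if beta[j] > 0 else -1.0
                    if abs(score[j] - lam * sgn) > target:
                        ok = False
                        break
        if ok:
            break
        wz_vec = w * z
        A = np.dot(X.T * w, X)
        u = np.dot(wz_vec, X)
        s = np.dot(w, X)
        W = w.sum()
        wz = wz_vec.sum()
        diag = np.empty(m)
        for j in range(m):
            diag[j] = A[j, j]
        Ab = np.dot(A, beta)
        for _inner in range(1000):
            b0_new = (wz - np.dot(s, beta)) / W
            delta = abs(b0_new - b0)
            b0 = b0_new
            for j in range(m):
                g = u[j] - s[j] * b0 - Ab[j] + diag[j] * beta[j]
                if g > lam:
                    bj = (g - lam) / diag[j]
                elif g < -lam:
                    bj = (g + lam) / diag[j]
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    if abs(d) > delta:
                        delta = abs(d)
                    beta[j] = bj
                    for k in range(m):
                        Ab[k] += A[j, k] * d
            if delta < 1e-11:
                break
    return b0


def _cd_solve(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    beta: np.ndarray,
    b0: float,
    max_outer: int = 200,
    kkt_tol: float = KKT_TOL,
) -> tuple[float, np.ndarray]:
    """IRLS + cyclic coordinate descent; stops when KKT holds at kkt_tol/5."""
    X = np.ascontiguousarray(X)
    y = np.ascontiguousarray(y)
    b0 = _cd_core(X, y, float(lam), beta, float(b0), kkt_tol / 5.0, max_outer)
    return b0, beta


def fit_l1_logistic(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    labels: Sequence[str] | None = None,
    warm: LogisticFit | None = None,
) -> LogisticFit:
    """Minimise ``-loglik + λ Σ|β_j|`` with an unpenalized intercept.

    ``X`` is expected standardized; coefficients are reported on that scale.
    ``warm`` optionally seeds the optimiser with a previous solution (the
    result does not depend on it beyond numerical tolerance).
    """
    y = _check_outcome(y)
    X = np.asarray(X, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    n, m = X.shape
    if labels is None:
        labels = [f"x{j}" for j in range(m)]
    if warm is not None and warm.coefficients.size == m:
        beta = warm.coefficients.copy()
        b0 = warm.intercept
    else:
        beta = np.zeros(m)
        ybar = y.mean()
        b0 = math.log(ybar / (1.0 - ybar))
    b0, beta = _cd_solve(y, X, lam, beta, b0)
    eta = b0 + X @ beta
    return LogisticFit(
        intercept=b0,
        coefficients=beta,
        penalty=float(lam),
        loglik=_unpenalized_loglik(y, eta),
        active_set=frozenset(
            labels[j] for j in range(m) if beta[j] != 0.0
        ),
    )


def regularization_path(
    y: np.ndarray,
    X: np.ndarray,
    grid: PenaltyGrid,
    labels: Sequence[str] | None = None,
) -> list[LogisticFit]:
    """One fit per grid value, warm-started in decreasing penalty order."""
    fits: list[LogisticFit] = []
    warm: LogisticFit | None = None
    for lam in grid.values:
        warm = fit_l1_logistic(y, X, lam, labels=labels, warm=warm)
        fits.append(warm)
    return fits


def information_criterion(loglik: float, k: int, n: int, criterion: str) -> float:
    """AIC = -2 loglik + 2k; BIC = -2 loglik + k ln n.

    ``k`` is the number of nonzero slope coefficients (intercept excluded).
    """
    crit = criterion.lower()
    if crit == "aic":
        return -2.0 * loglik + 2.0 * k
    if crit == "bic":
        return -2.0 * loglik + k * math.log(n)
    raise ValueError(f"unknown criterion {criterion!r}; use 'aic' or 'bic'")


def select_penalty_ic(
    y: np.ndarray,
    X: np.ndarray,
    grid: PenaltyGrid,
    criterion: str,
    path: Sequence[LogisticFit] | None = None,
) -> float:
    """Grid penalty minimising AIC or BIC; ties resolved to the larger λ."""
    y = _check_outcome(y)
    n = y.size
    if path is None:
        path = regularization_path(y, X, grid)
    best_lam = grid.values[0]
    best_val = math.inf
    for lam, fit in zip(grid.values, path):
        val = information_criterion(fit.loglik, fit.n_active, n, criterion)
        if val < best_val:  # strict: first (largest) λ wins ties
            best_val = val
            best_lam = lam
    return float(best_lam)


def select_penalty_cv(
    y: np.ndarray,
    X: np.ndarray,
    grid: PenaltyGrid,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Grid penalty maximising mean out-of-fold log-likelihood.

    Folds are stratified by the outcome and seeded.  If a split leaves a
    training fold with a single outcome class, the data are refolded with a
    new seed (at most 10 attempts).
    """
    y = _check_outcome(y)
    X = np.asarray(X, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if y.size < folds:
        raise ValueError("need at least as many observations as folds")
    splits = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        try:
            candidate = list(skf.split(X, y))
        except ValueError as exc:
            raise DegenerateOutcomeError(str(exc)) from exc
        if all(0.0 < y[tr].mean() < 1.0 for tr, _ in candidate):
            splits = candidate
            break
    if splits is None:
        raise DegenerateOutcomeError(
            "could not build folds with both outcome classes in every training set"
        )
    oof = np.zeros((folds, grid.size))
    for k, (tr, te) in enumerate(splits):
        warm: LogisticFit | None = None
        for g, lam in enumerate(grid.values):
            warm = fit_l1_logistic(y[tr], X[tr], lam, warm=warm)
            eta = warm.intercept + X[te] @ warm.coefficients
            oof[k, g] = _unpenalized_loglik(y[te], eta)
    mean_ll = oof.mean(axis=0)
    # ties go to the larger penalty: first index attaining the maximum
    best = int(np.flatnonzero(mean_ll == mean_ll.max())[0])
    return float(grid.values[best])


def penalty_for_size(
    y: np.ndarray,
    X: np.ndarray,
    grid: PenaltyGrid,
    l: int,
    path: Sequence[LogisticFit] | None = None,
) -> float:
    """Largest grid penalty whose active set has at least ``l`` members.

    If no grid value reaches size ``l`` the smallest penalty is returned.
    The realized active set may exceed ``l`` when several coefficients enter
    together; it is used as-is.
    """
    m = np.asarray(X).shape[1]
    if not 1 <= l <= m:
        raise ValueError(f"target size must be in [1, {m}], got {l}")
    if path is None:
        path = regularization_path(y, X, grid)
    for lam, fit in zip(grid.values, path):
        if fit.n_active >= l:
            return float(lam)
    return float(grid.values[-1])
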