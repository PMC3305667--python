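"""Odds-ratio-parameterised binary Markov random fields.

The joint law of a binary vector ``X = (X1, ..., Xp) ∈ {0,1}^p`` is specified
through a symmetric positive ``p × p`` matrix ``M``: diagonal entries are the
baseline odds of each variable, off-diagonal entries are pairwise conditional
odds ratios.  On the log scale this is the classical pairwise binary Markov
random field (an Ising model in 0/1 coding)::

    P(x) ∝ exp( Σ_i h_i x_i + Σ_{i<j} J_ij x_i x_j ),
    h_i = ln M_ii,   J_ij = ln M_ij  (i ≠ j).

The full conditional of variable ``i`` given the rest is logistic,

    logit P(X_i = 1 | x_-i) = h_i + Σ_{j≠i} J_ij x_j,

so ``exp(J_ij) = M_ij`` is exactly the conditional odds ratio between
``X_i`` and ``X_j`` given all other variables, and ``M_ij = 1`` means
conditional independence.  The support of ``J`` is therefore the
conditional-independence graph of the joint distribution.

This module provides the parameterisation, a seeded single-chain Gibbs
sampler with burn-in and between-draw spacing, an exact enumeration oracle
for small ``p``, and the predefined structures used by the simulation study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import CapacityError, InvalidInteractionMatrixError, PresetLookupError

__all__ = [
    "InteractionMatrix",
    "LogPotentials",
    "BinaryDataset",
    "TrueGraph",
    "log_potentials",
    "conditional_probability",
    "gibbs_sample",
    "exact_joint",
    "ExactJoint",
    "true_graph",
    "preset_structure",
    "PAPER19_EDGES",
    "DEFAULT_BURN_IN",
    "DEFAULT_SPACING",
]

#: Gibbs sweeps discarded before recording any observation.
DEFAULT_BURN_IN = 5000
#: Gibbs sweeps between two recorded observations.
DEFAULT_SPACING = 10

_ENUMERATION_LIMIT = 20


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric positive odds-ratio parameterisation of a binary joint law.

    Parameters
    ----------
    values
        ``p × p`` array; ``values[i, i]`` is the baseline odds of variable
        ``i`` and ``values[i, j]`` the pairwise conditional odds ratio.
    names
        Unique labels for the ``p`` variables.
    """

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InvalidInteractionMatrixError(
                f"interaction matrix must be square, got shape {values.shape}"
            )
        p = values.shape[0]
        if p < 2:
            raise InvalidInteractionMatrixError("at least two variables are required")
        if len(self.names) != p:
            raise InvalidInteractionMatrixError(
                f"{len(self.names)} names for {p} variables"
            )
        if len(set(self.names)) != p:
            raise InvalidInteractionMatrixError("variable names must be unique")
        bad = np.argwhere(~(values > 0))
        if bad.size:
            i, j = bad[0]
            raise InvalidInteractionMatrixError(
                f"entry ({self.names[i]}, {self.names[j]}) = {values[i, j]} "
                "is not strictly positive"
            )
        if not np.array_equal(values, values.T):
            i, j = np.argwhere(values != values.T)[0]
            raise InvalidInteractionMatrixError(
                f"matrix is not symmetric at ({self.names[i]}, {self.names[j]})"
            )

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LogPotentials:
    """Log-scale canonical parameters ``(h, J)`` of the pairwise model."""

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        J = np.asarray(self.J, dtype=float)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "J", J)
        if J.shape != (h.size, h.size):
            raise ValueError("J must be p x p with p = len(h)")
        if not np.array_equal(J, J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(J) != 0.0):
            raise ValueError("J must have an exactly zero diagonal")

    @property
    def p(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class BinaryDataset:
    """An ``n × p`` matrix of 0/1 observations with named columns."""

    data: np.ndarray
    names: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("data must be a 2-d array")
        if data.shape[0] < 1:
            raise ValueError("at least one observation is required")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("data entries must be 0 or 1")
        object.__setattr__(self, "data", data.astype(np.int8))
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if len(self.names) != data.shape[1]:
            raise ValueError(
                f"{len(self.names)} names for {data.shape[1]} columns"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TrueGraph:
    """An undirected graph over named nodes; edges in canonical sorted order."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        nodes = tuple(str(n) for n in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        node_set = set(nodes)
        if len(node_set) != len(nodes):
            raise ValueError("node labels must be unique")
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) has an endpoint outside nodes")
            canon.add(_canonical_edge(a, b))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def p(self) -> int:
        return len(self.nodes)


def log_potentials(M: InteractionMatrix) -> LogPotentials:
    """Convert an odds-ratio matrix to log-scale potentials ``(h, J)``.

    ``h_i = ln M_ii`` and ``J_ij = ln M_ij`` for ``i ≠ j``; ``J_ii = 0``.
    """
    J = np.log(M.values)
    h = np.diag(J).copy()
    np.fill_diagonal(J, 0.0)
    return LogPotentials(h=h, J=J)


def conditional_probability(
    pot: LogPotentials, state: Sequence[int], i: int
) -> float:
    """Full-conditional ``P(X_i = 1 | x_-i)`` under the pairwise model.

    The logit is ``h_i + Σ_{j≠i} J_ij x_j``; the diagonal of ``J`` is zero so
    the sum may run over all ``j``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (pot.p,):
        raise ValueError(f"state must have length {pot.p}")
    if not 0 <= i < pot.p:
        raise ValueError(f"node index {i} out of range")
    z = pot.h[i] + float(pot.J[i] @ state)
    return 1.0 / (1.0 + math.exp(-z))


def gibbs_sample(
    M: InteractionMatrix,
    n: int,
    burn_in: int = DEFAULT_BURN_IN,
    spacing: int = DEFAULT_SPACING,
    seed: int = 0,
) -> BinaryDataset:
    """Draw ``n`` observations from the joint law of ``M`` by Gibbs sampling.

    A single chain of full sequential sweeps is run (each sweep updates every
    variable ``i = 1..p`` in order from its full conditional).  The starting
    state draws each variable independently from its baseline odds
    ``M_ii / (1 + M_ii)``.  The first ``burn_in`` sweeps are discarded; one
    observation is then recorded every ``spacing`` sweeps until ``n`` rows are
    collected.  Identical arguments produce bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    pot = log_potentials(M)
    p = pot.p
    h = pot.h.tolist()
    # Sparse neighbour lists: only nonzero couplings enter the conditionals.
    neighbours: list[list[tuple[int, float]]] = [
        [(j, float(pot.J[i, j])) for j in np.flatnonzero(pot.J[i])] for i in range(p)
    ]
    rng = np.random.default_rng(seed)
    x = [1.0 if u < q else 0.0 for u, q in zip(rng.random(p), 1.0 / (1.0 + np.exp(-pot.h)))]

    rows = np.empty((n, p), dtype=np.int8)
    collected = 0
    sweep = 0
    block = 4096
    exp = math.exp
    while collected < n:
        U = rng.random((block, p))
        for t in range(block):
            u = U[t]
            for i in range(p):
                z = h[i]
                for j, w in neighbours[i]:
                    z += w * x[j]
                x[i] = 1.0 if u[i] < 1.0 / (1.0 + exp(-z)) else 0.0
            sweep += 1
            if sweep > burn_in and (sweep - burn_in) % spacing == 0:
                rows[collected] = x
                collected += 1
                if collected == n:
                    break
    provenance = (
        f"gibbs_sample(p={p}, n={n}, burn_in={burn_in}, spacing={spacing}, seed={seed})"
    )
    return BinaryDataset(data=rows, names=M.names, provenance=provenance)


class ExactJoint(NamedTuple):
    """Exhaustive joint table: ``states[s]`` is the bit pattern, ``probs[s]``
    its probability.  ``states[s, i] = (s >> i) & 1``."""

    states: np.ndarray
    probs: np.ndarray


def exact_joint(M: InteractionMatrix) -> ExactJoint:
    """Enumerate all ``2^p`` states and their exact probabilities.

    Serves as a brute-force oracle for the Gibbs sampler; limited to
    ``p ≤ 20``.
    """
    p = M.p
    if p > _ENUMERATION_LIMIT:
        raise CapacityError(
            f"exact enumeration requires p <= {_ENUMERATION_LIMIT}, got {p}"
        )
    pot = log_potentials(M)
    idx = np.arange(2**p, dtype=np.int64)
    states = ((idx[:, None] >> np.arange(p)) & 1).astype(np.int8)
    xf = states.astype(float)
    energy = xf @ pot.h + 0.5 * np.einsum("si,ij,sj->s", xf, pot.J, xf)
    energy -= energy.max()
    w = np.exp(energy)
    return ExactJoint(states=states, probs=w / w.sum())


def true_graph(M: InteractionMatrix) -> TrueGraph:
    """The conditional-independence graph of ``M``: edge iff ``M_ij ≠ 1``."""
    edges = set()
    p = M.p
    for i in range(p):
        for j in range(i + 1, p):
            if M.values[i, j] != 1.0:
                edges.add(_canonical_edge(M.names[i], M.names[j]))
    return TrueGraph(nodes=M.names, edges=frozenset(edges))


def _matrix_from_edges(
    names: Sequence[str], edges: Iterable[tuple[str, str]], odds_ratio: float = 2.0
) -> InteractionMatrix:
    index = {n: i for i, n in enumerate(names)}
    values = np.ones((len(names), len(names)))
    for a, b in edges:
        i, j = index[a], index[b]
        values[i, j] = values[j, i] = odds_ratio
    return InteractionMatrix(values=values, names=tuple(names))


#: Six-variable benchmark: a 4-cycle X1-X2-X4-X3-X1 (all odds ratios 2,
#: baseline odds 1) plus two isolated noise variables X5, X6.
_M6_ROWS = np.array(
    [
        [1, 2, 2, 1, 1, 1],
        [2, 1, 1, 2, 1, 1],
        [2, 1, 1, 2, 1, 1],
        [1, 2, 2, 1, 1, 1],
        [1, 1, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1],
    ],
    dtype=float,
)

#: Frozen 19-edge benchmark topology on 20 nodes: a 12-cycle with one chord,
#: six pendant/branch nodes keeping V01..V18 connected, and two isolated
#: noise variables V19, V20.  All present edges carry odds ratio 2, all
#: baseline odds are 1.  An empty estimate scored against this truth has a
#: structural Hamming distance of 19.
PAPER19_EDGES: tuple[tuple[str, str], ...] = (
    ("V01", "V02"),
    ("V02", "V03"),
    ("V03", "V04"),
    ("V04", "V05"),
    ("V05", "V06"),
    ("V06", "V07"),
    ("V07", "V08"),
    ("V08", "V09"),
    ("V09", "V10"),
    ("V10", "V11"),
    ("V11", "V12"),
    ("V01", "V12"),
    ("V01", "V07"),
    ("V03", "V13"),
    ("V06", "V14"),
    ("V14", "V17"),
    ("V09", "V15"),
    ("V12", "V16"),
    ("V16", "V18"),
)


def preset_structure(name: str) -> InteractionMatrix:
    """Return a predefined odds-ratio matrix.

    ``"m6"``
        The six-variable benchmark (4-cycle plus two isolated variables).
    ``"paper19"``
        The 20-variable benchmark: 19 edges connecting 18 nodes plus two
        isolated noise variables (see :data:`PAPER19_EDGES`).
    """
    key = name.lower()
    if key == "m6":
        return InteractionMatrix(
            values=_M6_ROWS.copy(), names=tuple(f"X{i}" for i in range(1, 7))
        )
    if key == "paper19":
        names = tuple(f"V{i:02d}" for i in range(1, 21))
        return _matrix_from_edges(names, PAPER19_EDGES, odds_ratio=2.0)
    raise PresetLookupError(
        f"unknown preset {name!r}; available presets: 'm6', 'paper19'"
    )
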