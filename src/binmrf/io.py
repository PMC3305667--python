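"""File readers and writers.

All writers are deterministic: fixed orderings, floats with six significant
digits, so identical inputs yield byte-identical files.  Edge lists are
two-column TSV with the lexicographically smaller label first; because an
edge list cannot carry isolated nodes, a ``<path>.nodes`` sidecar lists the
full node set and is consulted on read when present.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataValidationError
from .estimate import EstimatedGraph
from .mrf import BinaryDataset, InteractionMatrix, TrueGraph, _canonical_edge

logger = logging.getLogger(__name__)

__all__ = [
    "read_binary_dataset",
    "write_binary_dataset",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_graph",
    "write_graph",
    "write_metrics",
    "write_frequencies",
    "write_provenance",
]

_SYMMETRY_TOL = 1e-9


def _delimiter(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_binary_dataset(path: str | Path) -> BinaryDataset:
    """Read an n × p matrix of 0/1 cells with a header row of variable names."""
    df = pd.read_csv(path, sep=_delimiter(path))
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected at least two columns")
    names = [str(c) for c in df.columns]
    if len(set(names)) != len(names):
        raise DataValidationError(f"{path}: duplicate column names")
    if any(n.strip() in ("0", "1") or n.startswith("Unnamed:") for n in names):
        raise DataValidationError(
            f"{path}: header row looks like data; a header of variable names is required"
        )
    values = df.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)) | pd.isna(values))
    if bad.size:
        i, j = bad[0]
        raise DataValidationError(
            f"{path}: cell at data row {i + 1}, column {names[j]!r} is "
            f"{df.iat[i, j]!r}; entries must be 0 or 1"
        )
    return BinaryDataset(
        data=values.astype(np.int8), names=tuple(names), provenance=f"file:{path}"
    )


def write_binary_dataset(data: BinaryDataset, path: str | Path) -> None:
    df = pd.DataFrame(data.data, columns=list(data.names))
    df.to_csv(path, sep=_delimiter(path), index=False)


def read_interaction_matrix(path: str | Path) -> InteractionMatrix:
    """Read a square odds-ratio matrix CSV with matching row/column labels.

    Asymmetries within 1e-9 are symmetrized by averaging (with a warning for
    any discrepancy beyond exact equality); larger asymmetries are errors.
    """
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise DataValidationError(f"{path}: matrix is not square: {df.shape}")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise DataValidationError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if np.any(~(values > 0)):
        i, j = np.argwhere(~(values > 0))[0]
        raise DataValidationError(
            f"{path}: entry ({rows[i]}, {cols[j]}) = {values[i, j]} must be positive"
        )
    asym = np.abs(values - values.T).max()
    if asym > _SYMMETRY_TOL:
        raise DataValidationError(
            f"{path}: matrix asymmetric beyond tolerance ({asym:.3g} > {_SYMMETRY_TOL})"
        )
    if asym > 0:
        warnings.warn(
            f"{path}: asymmetry of {asym:.3g} symmetrized by averaging",
            stacklevel=2,
        )
        values = (values + values.T) / 2.0
    return InteractionMatrix(values=values, names=tuple(rows))


def write_interaction_matrix(M: InteractionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(M.values, index=list(M.names), columns=list(M.names))
    df.to_csv(path, sep=_delimiter(path), float_format="%.6g")


def _sorted_edges(graph) -> list[tuple[str, str]]:
    return sorted(_canonical_edge(a, b) for a, b in graph.edges)


def write_graph(
    graph: EstimatedGraph | TrueGraph,
    path: str | Path,
    format: str = "edgelist",
) -> None:
    """Write a graph as a TSV edge list (plus a ``.nodes`` sidecar) or GraphML.

    GraphML output preserves isolated nodes directly and attaches Bolasso
    selection frequencies as an edge attribute ``frequency`` when available.
    """
    fmt = format.lower()
    frequencies = getattr(graph, "frequencies", None)
    if fmt == "edgelist":
        path = Path(path)
        with open(path, "w") as fh:
            for a, b in _sorted_edges(graph):
                fh.write(f"{a}\t{b}\n")
        with open(f"{path}.nodes", "w") as fh:
            for node in graph.nodes:
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        for a, b in _sorted_edges(graph):
            attrs = {}
            if frequencies is not None:
                mu = max(
                    frequencies.get(a, {}).get(b, 0.0),
                    frequencies.get(b, {}).get(a, 0.0),
                )
                attrs["frequency"] = round(mu, 6)
            g.add_edge(a, b, **attrs)
        nx.write_graphml(g, str(path))
    else:
        raise DataValidationError(f"unknown graph format {format!r}")


def read_graph(path: str | Path) -> TrueGraph:
    """Read a TSV edge list; node set from the ``.nodes`` sidecar if present,
    otherwise the union of edge endpoints."""
    path = Path(path)
    edges = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataValidationError(
                    f"{path}:{line_no}: expected two tab-separated labels"
                )
            edges.add(_canonical_edge(parts[0], parts[1]))
    sidecar = Path(f"{path}.nodes")
    if sidecar.exists():
        nodes = tuple(
            line.strip() for line in sidecar.read_text().splitlines() if line.strip()
        )
    else:
        nodes = tuple(sorted({n for e in edges for n in e}))
    return TrueGraph(nodes=nodes, edges=frozenset(edges))


def write_frequencies(graph_or_freq, names, path: str | Path) -> None:
    """Write the p × p Bolasso selection-frequency matrix μ as CSV.

    ``μ[b, a]`` is the frequency with which ``b`` entered the neighborhood
    of ``a``.
    """
    freq = getattr(graph_or_freq, "frequencies", graph_or_freq)
    if freq is None:
        raise DataValidationError("no selection frequencies available")
    names = list(names)
    mat = np.zeros((len(names), len(names)))
    for a_i, a in enumerate(names):
        for b_i, b in enumerate(names):
            mat[b_i, a_i] = freq.get(a, {}).get(b, 0.0)
    df = pd.DataFrame(mat, index=names, columns=names)
    df.to_csv(path, float_format="%.6g")


def write_metrics(payload: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in payload.items()},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def write_provenance(path: str | Path, params: Mapping[str, object]) -> None:
    """Sidecar JSON recording package version, seed and parameters of a run."""
    from . import __version__

    record = {"package": "binmrf", "version": __version__, **params}
    with open(f"{path}.provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
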