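"""Sufficient statistics and change statistics on co-occurrence networks."""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np

from ..transect import BenthicNetwork
from . import _kernels
from .model import ExpandedModel, ModelSpec

__all__ = [
    "network_arrays",
    "adjacency_matrix",
    "compute_statistics",
    "gwesp_statistic",
    "change_statistics",
]


def _as_graph(network: BenthicNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, BenthicNetwork) else network


def adjacency_matrix(network: BenthicNetwork | nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    """Dense 0/1 adjacency matrix of the simple graph in ``nodes`` order."""
    graph = _as_graph(network)
    index = {node: k for k, node in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
    for u, v in graph.edges():
        i, j = index[u], index[v]
        A[i, j] = 1
        A[j, i] = 1
    return A


def network_arrays(
    network: BenthicNetwork | nx.Graph, spec: ModelSpec
) -> tuple[ExpandedModel, np.ndarray]:
    """Expand a spec on a network and return (expanded model, adjacency)."""
    graph = _as_graph(network)
    nodes = sorted(graph.nodes, key=str)
    expanded = spec.expand(nodes, dict(graph.nodes(data=True)))
    return expanded, adjacency_matrix(graph, nodes)


def compute_statistics(
    network: BenthicNetwork | nx.Graph, spec: ModelSpec | ExpandedModel
) -> np.ndarray:
    """Sufficient-statistic vector g(y), one value per expanded term."""
    if isinstance(spec, ExpandedModel):
        expanded = spec
        A = adjacency_matrix(network, expanded.nodes)
    else:
        expanded, A = network_arrays(network, spec)
    return _kernels.stats_from_adj(A, expanded.kinds, expanded.vectors, expanded.decay)


def gwesp_statistic(network: BenthicNetwork | nx.Graph, decay: float) -> float:
    """Geometrically weighted edgewise shared partners of the simple graph."""
    if decay < 0:
        raise ValueError(f"gwesp decay must be >= 0, got {decay}")
    graph = _as_graph(network)
    nodes = sorted(graph.nodes, key=str)
    A = adjacency_matrix(graph, nodes)
    return float(_kernels.gwesp_from_adj(A, decay))


def change_statistics(
    network: BenthicNetwork | nx.Graph,
    spec: ModelSpec | ExpandedModel,
    dyad: tuple[str, str],
) -> np.ndarray:
    """Delta g for toggling a dyad on: g(y + ij) - g(y - ij).

    The delta is evaluated conditionally on the rest of the graph, so it is
    the same whether the edge is currently present or absent.
    """
    u, v = dyad
    if u == v:
        raise ValueError(f"dyad endpoints must differ, got {dyad}")
    if isinstance(spec, ExpandedModel):
        expanded = spec
        A = adjacency_matrix(network, expanded.nodes)
    else:
        expanded, A = network_arrays(network, spec)
    index = {node: k for k, node in enumerate(expanded.nodes)}
    i, j = index[str(u)], index[str(v)]
    present = A[i, j] == 1
    if present:
        A[i, j] = 0
        A[j, i] = 0
    out = np.zeros(expanded.n_params)
    _kernels.change_stats_absent(A, i, j, expanded.kinds, expanded.vectors, expanded.decay, out)
    return out


def dyad_design_matrix(expanded: ExpandedModel, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dyad change statistics and edge indicators in the observed graph.

    Rows follow (i, j), i < j, row-major order — the same dyad indexing the
    enumeration kernel uses.  This is the design matrix of the logistic
    pseudolikelihood.
    """
    n = expanded.n_vertices
    D = n * (n - 1) // 2
    X = np.zeros((D, expanded.n_params))
    y = np.zeros(D)
    A = A.copy()
    d = 0
    row = np.zeros(expanded.n_params)
    for i in range(n):
        for j in range(i + 1, n):
            present = A[i, j] == 1
            if present:
                A[i, j] = 0
                A[j, i] = 0
            _kernels.change_stats_absent(
                A, i, j, expanded.kinds, expanded.vectors, expanded.decay, row
            )
            X[d] = row
            y[d] = 1.0 if present else 0.0
            if present:
                A[i, j] = 1
                A[j, i] = 1
            d += 1
    return X, y
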