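"""Nodal and network topological metrics of binary graphs.

For a binary undirected graph G on N nodes with neighbour subgraph G_i of
node i (the subgraph induced by i's direct neighbours, excluding i):

* degree        K_i = |G_i|;  network degree K_net = mean_i K_i
* cost          K_cost = K_net / (N - 1) = 2E / (N (N - 1))
* clustering    C_i = E_i / (K_i (K_i - 1) / 2), the fraction of neighbour
                pairs that are themselves connected; C_net = mean_i C_i
* path length   L_i = mean_{j != i} d(i, j) with d the BFS shortest-path
                length; characteristic path length L_net = mean_i L_i
* global eff.   E_global = mean over ordered pairs of 1 / d(i, j)
* local eff.    E_local(i) = E_global of G_i (fault tolerance of i);
                E_local = mean_i E_local(i)

Conventions for degenerate cases (standard in the field): nodes with
degree < 2 have C_i = 0 and E_local(i) = 0; disconnected pairs have
d = inf, contributing 0 to efficiencies and making L infinite (the
small-world regime is chosen so this does not occur in practice; a
warning is emitted when it does).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graphs import BinaryGraph, CostGrid, threshold_to_edges

__all__ = [
    "NodalMetrics",
    "NetworkMetrics",
    "nodal_metrics",
    "network_metrics",
    "metric_curves",
    "NETWORK_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

NETWORK_METRIC_NAMES = ("k_net", "k_cost", "c_net", "l_net", "e_global", "e_local")
NODAL_METRIC_NAMES = ("k_node", "c_node", "l_node", "e_node_global", "e_node_local")


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    clustering: np.ndarray
    mean_shortest_path: np.ndarray
    nodal_global_efficiency: np.ndarray
    local_efficiency: np.ndarray


@dataclass(frozen=True)
class NetworkMetrics:
    k_net: float
    k_cost: float
    c_net: float
    l_net: float
    e_global: float
    e_local: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in NETWORK_METRIC_NAMES}


def _bfs_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by per-node BFS; inf if unreachable."""
    if A.shape[0] == 1:
        return np.zeros((1, 1))
    return shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)


def _global_efficiency(A: np.ndarray) -> float:
    """Mean reciprocal shortest-path length over distinct pairs (0 if N < 2)."""
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = _bfs_distances(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _clustering(A: np.ndarray, degrees: np.ndarray) -> np.ndarray:
    Af = A.astype(float)
    triangles = np.diag(Af @ Af @ Af) / 2.0  # closed 2-paths per node
    possible = degrees * (degrees - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c


def nodal_metrics(g: BinaryGraph) -> NodalMetrics:
    """Degree, clustering, mean shortest path, and efficiencies per node."""
    A = g.adjacency
    n = g.n_nodes
    degrees = g.degrees.astype(float)
    clustering = _clustering(A, degrees)

    D = _bfs_distances(A)
    off = ~np.eye(n, dtype=bool)
    if n > 1:
        mean_sp = np.array([D[i, off[i]].mean() for i in range(n)])
        with np.errstate(divide="ignore"):
            invD = 1.0 / D
        np.fill_diagonal(invD, 0.0)
        nodal_geff = invD.sum(axis=1) / (n - 1)
    else:
        mean_sp = np.array([0.0])
        nodal_geff = np.array([0.0])

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size >= 2:
            local_eff[i] = _global_efficiency(A[np.ix_(nbrs, nbrs)])
    return NodalMetrics(
        degree=g.degrees,
        clustering=clustering,
        mean_shortest_path=mean_sp,
        nodal_global_efficiency=nodal_geff,
        local_efficiency=local_eff,
    )


def network_metrics(g: BinaryGraph) -> NetworkMetrics:
    """Network-level aggregation of the nodal metrics."""
    nm = nodal_metrics(g)
    n = g.n_nodes
    k_net = float(nm.degree.mean())
    l_net = float(nm.mean_shortest_path.mean())
    if not np.isfinite(l_net):
        warnings.warn(
            "graph is disconnected: characteristic path length is infinite "
            "(the small-world regime is meant to exclude this)",
            RuntimeWarning,
            stacklevel=2,
        )
    return NetworkMetrics(
        k_net=k_net,
        k_cost=k_net / (n - 1) if n > 1 else 0.0,
        c_net=float(nm.clustering.mean()),
        l_net=l_net,
        e_global=float(nm.nodal_global_efficiency.mean()),
        e_local=float(nm.local_efficiency.mean()),
    )


def metric_curves(
    Z: np.ndarray,
    grid: CostGrid,
    subject_id: str = "subject",
    group: str = "",
    node_labels: tuple[str, ...] = (),
    include_nodal: bool = True,
) -> pd.DataFrame:
    """Network (and optionally nodal) metrics across the cost grid.

    Returns a long-format table with one row per (metric, node, grid
    point): columns ``subject_id, group, edge_count, k_cost, metric,
    node, value``. Network-level rows carry ``node="network"``.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if grid.n_nodes != n:
        raise ValueError(
            f"grid is for N={grid.n_nodes} nodes but matrix has N={n}"
        )
    labels = tuple(node_labels) or tuple(f"IC{i + 1}" for i in range(n))
    rows: list[dict] = []
    for E, cost in zip(grid.edge_counts, grid.costs):
        g = threshold_to_edges(Z, E, node_labels=labels)
        net = network_metrics(g)
        for name, value in net.as_dict().items():
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "edge_count": E,
                    "k_cost": cost,
                    "metric": name,
                    "node": "network",
                    "value": value,
                }
            )
        if include_nodal:
            nm = nodal_metrics(g)
            nodal_values = {
                "k_node": nm.degree.astype(float),
                "c_node": nm.clustering,
                "l_node": nm.mean_shortest_path,
                "e_node_global": nm.nodal_global_efficiency,
                "e_node_local": nm.local_efficiency,
            }
            for name, vec in nodal_values.items():
                for lbl, value in zip(labels, vec):
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "group": group,
                            "edge_count": E,
                            "k_cost": cost,
                            "metric": name,
                            "node": lbl,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows)
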