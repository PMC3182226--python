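"""Cost-matched binary graph construction from Fisher-z FNC matrices.

An undirected, unweighted graph on the N components is obtained by keeping
an edge wherever |z(i, j)| exceeds a threshold. To keep group comparisons
independent of edge-count differences, thresholds are chosen per subject so
that every subject's graph has exactly the same number of edges E; the
corresponding connection density (cost) is

    K_cost = 2E / (N (N - 1)).

The analysis grid is therefore defined in integer edge counts (e.g. 560 to
665 in steps of 7 for N = 57, i.e. costs 0.351 to 0.417); printed costs are
labels rounded to three decimals. The small-world regime is the cost
interval where (1) every subject's graph is fully connected and (2) graphs
show lower global but higher local efficiency than degree-matched random
references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BinaryGraph",
    "CostGrid",
    "RegimeError",
    "cost_of_edges",
    "edges_for_cost",
    "build_grid",
    "threshold_to_edges",
    "is_connected",
    "find_regime",
]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph on N component-nodes.

    ``adjacency`` is a symmetric boolean matrix with zero diagonal;
    ``threshold_used`` records the smallest |z| among included edges when
    the graph came from thresholding (NaN otherwise).
    """

    adjacency: np.ndarray
    threshold_used: float = float("nan")
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] < 1:
            raise ValueError("graph needs at least one node")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(A)):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", A)
        labels = tuple(self.node_labels) or tuple(
            f"IC{i + 1}" for i in range(A.shape[0])
        )
        if len(labels) != A.shape[0]:
            raise ValueError("node_labels length must match n_nodes")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def cost(self) -> float:
        return cost_of_edges(self.n_edges, self.n_nodes)

    def edge_list(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass(frozen=True)
class CostGrid:
    """Strictly increasing edge counts with their exact cost labels."""

    n_nodes: int
    edge_counts: tuple[int, ...]
    costs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        counts = tuple(int(e) for e in self.edge_counts)
        if not counts:
            raise ValueError("empty cost grid")
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("edge counts must be strictly increasing")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if counts[0] < 1 or counts[-1] > max_edges:
            raise ValueError(
                f"edge counts must lie in [1, {max_edges}] for N={self.n_nodes}"
            )
        costs = tuple(cost_of_edges(e, self.n_nodes) for e in counts)
        object.__setattr__(self, "edge_counts", counts)
        object.__setattr__(self, "costs", costs)

    def __len__(self) -> int:
        return len(self.edge_counts)

    @property
    def cost_labels(self) -> tuple[float, ...]:
        """Costs rounded to 3 decimals, as printed on axes/tables."""
        return tuple(round(c, 3) for c in self.costs)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "edge_counts": list(self.edge_counts),
            "costs": list(self.costs),
        }


class RegimeError(ValueError):
    """No cost interval jointly satisfies the small-world regime criteria."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def cost_of_edges(E: int, N: int) -> float:
    """Connection density 2E / (N(N-1)) of an N-node graph with E edges."""
    if N < 2:
        raise ValueError("need N >= 2")
    max_edges = N * (N - 1) // 2
    if not 0 <= E <= max_edges:
        raise ValueError(f"E={E} out of range [0, {max_edges}] for N={N}")
    return 2.0 * E / (N * (N - 1))


def edges_for_cost(k_cost: float, N: int) -> int:
    """Edge count nearest to a target cost (ties round away from zero).

    Note the asymmetry with printed cost labels: a grid defined by edge
    counts 560..665 on 57 nodes prints costs 0.351..0.417, but
    ``edges_for_cost(0.417, 57)`` is 666 (0.417 * 1596 = 665.532). Grids
    should therefore be defined edge-count-first; this helper converts
    user-supplied costs.
    """
    if not 0 < k_cost <= 1:
        raise ValueError("cost must lie in (0, 1]")
    max_edges = N * (N - 1) // 2
    E = int(math.floor(k_cost * max_edges + 0.5))
    if E < 1:
        raise ValueError(f"cost {k_cost} yields no edges for N={N}")
    return min(E, max_edges)


def build_grid(N: int, e_min: int, e_max: int, e_step: int = 1) -> CostGrid:
    """Edge-count grid {e_min, e_min+step, ...} <= e_max with exact costs."""
    if e_step < 1:
        raise ValueError("step must be >= 1")
    if e_min > e_max:
        raise ValueError("e_min must not exceed e_max")
    return CostGrid(
        n_nodes=N, edge_counts=tuple(range(e_min, e_max + 1, e_step))
    )


def _ranked_pairs(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by |z| descending, ties by (i, j) ascending."""
    ii, jj = np.triu_indices(Z.shape[0], k=1)
    a = np.abs(Z[ii, jj])
    order = np.lexsort((jj, ii, -a))
    return ii[order], jj[order], a[order]


def threshold_to_edges(
    Z: np.ndarray,
    E: int,
    node_labels: tuple[str, ...] = (),
) -> BinaryGraph:
    """Binary graph containing exactly the E pairs with largest |z|.

    ``threshold_used`` is the smallest included |z|. Ties at the boundary
    are broken deterministically: |z| descending, then node pair (i, j)
    lexicographically ascending — seed-free and reproducible.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    max_edges = n * (n - 1) // 2
    if not 0 <= E <= max_edges:
        raise ValueError(f"E={E} exceeds available pairs ({max_edges})")
    ii, jj, a = _ranked_pairs(Z)
    A = np.zeros((n, n), dtype=bool)
    A[ii[:E], jj[:E]] = True
    A |= A.T
    thr = float(a[E - 1]) if E > 0 else float("inf")
    return BinaryGraph(adjacency=A, threshold_used=thr, node_labels=node_labels)


def is_connected(g: BinaryGraph) -> bool:
    """True iff a single component spans all N nodes (BFS on sparse adjacency)."""
    if g.n_nodes == 1:
        return True
    n_comp, _ = connected_components(
        csr_matrix(g.adjacency), directed=False, return_labels=True
    )
    return n_comp == 1


def find_regime(
    z_matrices: list[np.ndarray],
    e_step: int,
    n_random: int = 20,
    seed: int | None = 0,
    mode: str = "group_mean",
    connectivity_mode: str = "per_subject",
    n_swap_attempts: int | None = None,
) -> CostGrid:
    """Select the small-world cost regime for a cohort.

    The candidate edge counts are the multiples of ``e_step``. The regime
    minimum is the smallest candidate at which every subject's graph is
    fully connected (``connectivity_mode="per_subject"``; ``"group_mean"``
    instead tests the graph of the cohort-mean |z| matrix). The regime
    maximum is the largest candidate from the minimum upward at which the
    brain graphs still have lower global efficiency and higher local
    efficiency than degree-matched rewired random references; with
    ``mode="group_mean"`` (default, matching how metric curves are
    aggregated) the criterion compares cohort means, with ``mode="per_subject"``
    it must hold for every subject. The scan stops at the first candidate
    where the efficiency criterion fails, so the returned grid is the
    maximal contiguous regime.

    Raises
    ------
    RegimeError
        If no candidate satisfies both criteria; carries per-criterion
        diagnostics (first connected count, efficiency margins per count).
    """
    from .metrics import network_metrics  # local import to avoid cycle
    from .nulls import random_reference

    if not z_matrices:
        raise ValueError("need at least one subject")
    if mode not in {"group_mean", "per_subject"}:
        raise ValueError(f"unknown mode {mode!r}")
    n = z_matrices[0].shape[0]
    max_edges = n * (n - 1) // 2
    candidates = list(range(e_step, max_edges + 1, e_step))
    diagnostics: dict = {"connected_at": None, "efficiency": {}}

    # ranked pairs are reused across candidate counts (nested thresholds)
    ranked = [_ranked_pairs(Z) for Z in z_matrices]

    def graphs_at(E: int) -> list[BinaryGraph]:
        out = []
        for (ii, jj, a) in ranked:
            A = np.zeros((n, n), dtype=bool)
            A[ii[:E], jj[:E]] = True
            A |= A.T
            out.append(BinaryGraph(adjacency=A, threshold_used=float(a[E - 1])))
        return out

    if connectivity_mode == "group_mean":
        mean_abs = np.mean([np.abs(Z) for Z in z_matrices], axis=0)
        connected_ok = lambda E: is_connected(threshold_to_edges(mean_abs, E))  # noqa: E731
    else:
        connected_ok = lambda E: all(is_connected(g) for g in graphs_at(E))  # noqa: E731

    e_min = next((E for E in candidates if connected_ok(E)), None)
    diagnostics["connected_at"] = e_min
    if e_min is None:
        raise RegimeError(
            "no candidate edge count connects every subject's graph",
            diagnostics,
        )

    rng_seed = seed if seed is not None else 0
    regime: list[int] = []
    for idx, E in enumerate(c for c in candidates if c >= e_min):
        graphs = graphs_at(E)
        margins = []
        for s_idx, g in enumerate(graphs):
            ref = random_reference(
                g,
                n_ensemble=n_random,
                seed=rng_seed + 10_000 * idx + s_idx,
                n_swap_attempts=n_swap_attempts,
            )
            m = network_metrics(g)
            margins.append(
                (m.e_global - ref.e_global_random, m.e_local - ref.e_local_random)
            )
        if mode == "group_mean":
            g_margin = float(np.mean([x[0] for x in margins]))
            l_margin = float(np.mean([x[1] for x in margins]))
            ok = g_margin < 0 and l_margin > 0
            diagnostics["efficiency"][E] = {
                "e_global_margin": g_margin,
                "e_local_margin": l_margin,
            }
        else:
            ok = all(gm < 0 and lm > 0 for gm, lm in margins)
            diagnostics["efficiency"][E] = {
                "per_subject_margins": margins,
            }
        if not ok:
            break
        regime.append(E)
    if not regime:
        raise RegimeError(
            "efficiency criterion (lower global, higher local efficiency than "
            "degree-matched random references) never satisfied at or above the "
            f"connectivity minimum E={e_min}",
            diagnostics,
        )
    return CostGrid(n_nodes=n, edge_counts=tuple(regime))
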