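"""Degree-preserving random references and small-worldness indices.

Small-world organisation is quantified against random graphs with the same
degree sequence: gamma = C_net / C_random > 1 together with
lambda = L_net / L_random ~= 1, summarised as sigma = gamma / lambda > 1.
The random references are generated by Markov-chain double-edge swaps
(Maslov-Sneppen rewiring): repeatedly pick two edges (a, b), (c, d) and
replace them with (a, d), (c, b) when that creates neither self-loops nor
duplicate edges — preserving every node's degree exactly. Ensemble means of
C, L and the efficiencies over (by default) 100 rewired graphs per input
graph give C_random, L_random etc.; the closed-form approximations for
Erdos-Renyi-like graphs, C_random = K/N and L_random ~= ln(N)/ln(K), are
reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .graphs import BinaryGraph
from .metrics import network_metrics

__all__ = [
    "RandomReference",
    "rewire_degree_preserving",
    "random_reference",
    "theoretical_random",
]


@dataclass(frozen=True)
class RandomReference:
    """Ensemble means over degree-matched rewired graphs, plus ratios."""

    c_random: float
    l_random: float
    e_global_random: float
    e_local_random: float
    gamma: float
    lambda_: float
    sigma: float
    n_ensemble: int
    seed: int
    n_disconnected: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def rewire_degree_preserving(
    g: BinaryGraph,
    n_swap_attempts: int | None = None,
    seed: int | None = None,
    preserve_connectedness: bool = False,
) -> BinaryGraph:
    """One Markov-chain rewired graph with the exact input degree sequence.

    Parameters
    ----------
    n_swap_attempts : int, optional
        Number of proposed double-edge swaps; proposals that would create a
        self-loop or duplicate edge are skipped (not retried). Default
        10 x edge count, enough mixing at the sizes used here.
    preserve_connectedness : bool
        If True, a swap that disconnects the graph is reverted. Off by
        default (the classical scheme does not enforce connectedness).
    """
    n = g.n_nodes
    edges = np.array(g.edge_list(), dtype=np.int64)
    n_edges = len(edges)
    if n_edges < 2:
        return BinaryGraph(adjacency=g.adjacency.copy(), node_labels=g.node_labels)
    if n_swap_attempts is None:
        n_swap_attempts = 10 * n_edges
    rng = np.random.default_rng(seed)
    A = g.adjacency.copy()

    pick = rng.integers(0, n_edges, size=(n_swap_attempts, 2))
    flip = rng.random(n_swap_attempts) < 0.5
    for t in range(n_swap_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # proposed replacement: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = False
        A[c, d] = A[d, c] = False
        A[a, d] = A[d, a] = True
        A[c, b] = A[b, c] = True
        if preserve_connectedness:
            from .graphs import is_connected

            if not is_connected(BinaryGraph(adjacency=A)):
                A[a, d] = A[d, a] = False
                A[c, b] = A[b, c] = False
                A[a, b] = A[b, a] = True
                A[c, d] = A[d, c] = True
                continue
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
    return BinaryGraph(adjacency=A, node_labels=g.node_labels)


def random_reference(
    g: BinaryGraph,
    n_ensemble: int = 100,
    seed: int | None = 0,
    n_swap_attempts: int | None = None,
    preserve_connectedness: bool = False,
) -> RandomReference:
    """Ensemble-mean metrics of degree-matched rewired graphs and ratios.

    gamma, lambda and sigma compare the input graph's clustering and path
    length against the ensemble means (not the theoretical formulas):
    degree-matched references are the fairer comparison when the degree
    distribution departs from the Gaussian of theoretical random graphs.
    Disconnected ensemble members (possible, though rare at the densities
    used here) make l_random infinite and are counted in
    ``n_disconnected`` with a warning.
    """
    if n_ensemble < 1:
        raise ValueError("need n_ensemble >= 1")
    base = 0 if seed is None else int(seed)
    ss = np.random.SeedSequence(base).spawn(n_ensemble)
    members = []
    for child in ss:
        member_seed = int(child.generate_state(1)[0] % (2**31))
        members.append(
            rewire_degree_preserving(
                g,
                n_swap_attempts=n_swap_attempts,
                seed=member_seed,
                preserve_connectedness=preserve_connectedness,
            )
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        metrics = [network_metrics(m) for m in members]
    n_disc = sum(1 for m in metrics if not np.isfinite(m.l_net))
    if n_disc:
        warnings.warn(
            f"{n_disc}/{n_ensemble} rewired reference graphs are disconnected; "
            "l_random is infinite (consider preserve_connectedness=True)",
            RuntimeWarning,
            stacklevel=2,
        )
    c_random = float(np.mean([m.c_net for m in metrics]))
    l_random = float(np.mean([m.l_net for m in metrics]))
    eg_random = float(np.mean([m.e_global for m in metrics]))
    el_random = float(np.mean([m.e_local for m in metrics]))
    own = network_metrics(g)
    gamma = own.c_net / c_random if c_random > 0 else float("nan")
    lam = own.l_net / l_random if l_random > 0 else float("nan")
    sigma = gamma / lam if lam and np.isfinite(lam) and lam > 0 else float("nan")
    return RandomReference(
        c_random=c_random,
        l_random=l_random,
        e_global_random=eg_random,
        e_local_random=el_random,
        gamma=gamma,
        lambda_=lam,
        sigma=sigma,
        n_ensemble=n_ensemble,
        seed=base,
        n_disconnected=n_disc,
    )


def theoretical_random(N: int, K: float) -> tuple[float, float]:
    """Closed-form random-graph references C_random = K/N, L_random = ln N / ln K.

    Valid for mean degree K > 1 (the log diverges at K = 1).
    """
    if N <= 1:
        raise ValueError("need N > 1")
    if K <= 1:
        raise ValueError("theoretical L_random requires mean degree K > 1")
    return K / N, float(np.log(N) / np.log(K))
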