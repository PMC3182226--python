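import networkx as nx
import numpy as np
import pytest

from fncnet import BinaryGraph, SubjectTimecourses


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def graph_from_nx(G: nx.Graph) -> BinaryGraph:
    A = nx.to_numpy_array(G, nodelist=sorted(G.nodes), dtype=bool)
    np.fill_diagonal(A, False)
    return BinaryGraph(adjacency=A)


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random SPD covariance: A A^T + n I scaled to unit-ish diagonal."""
    A = rng.standard_normal((n, n))
    S = A @ A.T + n * np.eye(n)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d) * (1 + rng.random())


@pytest.fixture
def triangle() -> BinaryGraph:
    return graph_from_nx(nx.complete_graph(3))


@pytest.fixture
def small_timecourses(rng) -> SubjectTimecourses:
    return SubjectTimecourses(
        data=rng.standard_normal((60, 5)), tr_seconds=1.5, subject_id="s1"
    )
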