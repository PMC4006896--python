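import numpy as np
import pytest

from spherecon import BinaryNetwork
from spherecon.phantom import make_ground_truth_network


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_net():
    """Connected 8-node modular network, deterministic."""
    return make_ground_truth_network(8, 2, 0.9, 0.2, seed=11)


@pytest.fixture
def triangle_pair_net():
    """Two disjoint triangles plus one isolate (N = 7)."""
    A = np.zeros((7, 7), dtype=int)
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[i, j] = A[j, i] = 1
    return BinaryNetwork(adjacency=A)


def union_find_components(adjacency: np.ndarray) -> np.ndarray:
    """Independent union-find oracle for undirected components."""
    n = adjacency.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    relabel = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[i] = relabel[r]
    return out
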