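import numpy as np
import pytest

from nqmod import (
    MultiplexNetwork,
    Partition,
    WeightedNetwork,
    build_multiplex,
)


def two_cliques_adjacency():
    """Two disjoint 3-cliques on 6 nodes, unit weights."""
    A = np.zeros((6, 6))
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                if i != j:
                    A[i, j] = 1.0
    return A


@pytest.fixture
def clique_net():
    return WeightedNetwork(list("abcdef"), two_cliques_adjacency())


@pytest.fixture
def clique_partition():
    return Partition.single_layer([0, 0, 0, 1, 1, 1])


@pytest.fixture
def dual_clique_mux(clique_net):
    """Two identical clique layers, unit replica coupling."""
    return build_multiplex([clique_net, clique_net], 1.0)


@pytest.fixture
def dual_clique_partition():
    # communities = cliques spanning both layers
    return Partition.from_layers([[0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]])


def random_multiplex(rng, n_nodes=None, n_layers=None, density=0.5,
                     coupling=None):
    """Random nonnegative-weight multiplex instance for property tests."""
    n = n_nodes or int(rng.integers(4, 13))
    L = n_layers or int(rng.integers(1, 4))
    layers = []
    names = [f"n{i}" for i in range(n)]
    for _ in range(L):
        A = (rng.random((n, n)) < density) * rng.uniform(0.1, 2.0, (n, n))
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        layers.append(WeightedNetwork(names, A))
    w = coupling if coupling is not None else float(rng.uniform(0, 2))
    return build_multiplex(layers, w)


def random_partition(rng, n_nodes, n_layers, max_k=None):
    k = max_k or max(1, n_nodes // 2)
    labels = rng.integers(0, k, size=n_nodes * n_layers)
    return Partition(labels, n_nodes=n_nodes, n_layers=n_layers)


def brute_force_nq(mux: MultiplexNetwork, partition: Partition,
                   gamma: float = 1.0, mu_convention: str = "coupled"):
    """Direct nested-loop evaluation of the nodal decomposition.

    Independent of the package's matrix implementation: sums the quality
    summand element by element over (j, r) for every node-layer (i, s).
    Returns (values layer-major, total Q).
    """
    n, L = mux.n_nodes, mux.n_layers
    g = partition.labels.reshape(L, n)  # g[s][i]
    k = np.array([layer.weights.sum(axis=1) for layer in mux.layers])  # L x n
    two_m = np.array([layer.weights.sum() for layer in mux.layers])
    two_mu = float(two_m.sum())
    if mu_convention == "coupled":
        two_mu += n * float(mux.coupling.sum())
    values = np.zeros(n * L)
    for s in range(L):
        A = mux.layers[s].weights
        for i in range(n):
            acc = 0.0
            for r in range(L):
                for j in range(n):
                    if g[s][i] != g[r][j]:
                        continue
                    if r == s:
                        acc += A[i, j] - gamma * k[s][i] * k[s][j] / two_m[s]
                    if i == j and r != s:
                        acc += mux.coupling[s, r]
            values[i + s * n] = acc / two_mu
    return values, float(values.sum())
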