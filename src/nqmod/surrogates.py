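"""Null-model surrogate networks: degree-preserving rewiring and a
partition-seeded stochastic block model (SBM).

Rewiring performs Maslov-Sneppen double-edge swaps on the binarized
topology with each weight carried by its edge, so node count, binary degree
sequence and the weight multiset are preserved exactly.  The SBM surrogate
is binary by construction: edge probabilities per block pair are estimated
as mean edge weights (sensible when weights are |rho| in [0, 1]).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .graph import Partition, WeightedNetwork


class SurrogateError(ValueError):
    pass


def rewire_random(net: WeightedNetwork, swaps_per_edge: int = 10, seed=None,
                  max_tries_factor: int = 100) -> WeightedNetwork:
    """Maslov-Sneppen double-edge swap surrogate.

    Picks two edges (a, b), (c, d) and rewires them to (a, d), (c, b) with
    weights following their original edge, rejecting swaps that would
    create self-loops or multi-edges.  Performs ``swaps_per_edge * E``
    accepted swaps.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(net.n_nodes, k=1)
    mask = net.weights[iu] != 0
    edges = [(int(i), int(j), float(w))
             for i, j, w in zip(iu[0][mask], iu[1][mask], net.weights[iu][mask])]
    n_edges = len(edges)
    if n_edges < 2:
        raise SurrogateError("need at least two edges to rewire")
    existing = {(a, b) for a, b, _ in edges}
    target = swaps_per_edge * n_edges
    max_tries = max_tries_factor * target
    done = tries = 0
    while done < target:
        if tries >= max_tries:
            raise SurrogateError(
                f"only {done}/{target} swaps after {tries} attempts; graph too "
                "small or dense to rewire"
            )
        tries += 1
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a, b, w1 = edges[e1]
        c, d, w2 = edges[e2]
        if rng.integers(0, 2):
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in existing or new2 in existing or new1 == new2:
            continue
        existing.discard((a, b) if a < b else (b, a))
        existing.discard((min(c, d), max(c, d)))
        existing.add(new1)
        existing.add(new2)
        edges[e1] = (new1[0], new1[1], w1)
        edges[e2] = (new2[0], new2[1], w2)
        done += 1
    weights = np.zeros_like(net.weights)
    for a, b, w in edges:
        weights[a, b] = weights[b, a] = w
    return WeightedNetwork(net.node_labels, weights)


def block_prob_from_network(net: WeightedNetwork, partition: Partition) -> np.ndarray:
    """K x K block connection probabilities estimated as mean edge weights.

    Entry (a, b) is the mean weight over node pairs (i != j) with groups
    (a, b); mean |rho| is read as a connection probability for the binary
    surrogate.  Empty block pairs get 0 with a warning.
    """
    if partition.labels.size != net.n_nodes:
        raise SurrogateError("partition size does not match network")
    labels = partition.labels
    k = partition.n_communities
    prob = np.zeros((k, k))
    for a in range(k):
        ia = np.flatnonzero(labels == a)
        for b in range(a, k):
            ib = np.flatnonzero(labels == b)
            block = net.weights[np.ix_(ia, ib)]
            if a == b:
                n_pairs = ia.size * (ia.size - 1)
                total = block.sum()  # diagonal is zero
            else:
                n_pairs = ia.size * ib.size
                total = block.sum()
            if n_pairs == 0:
                warnings.warn(
                    f"empty block pair ({a}, {b}); probability set to 0",
                    stacklevel=2,
                )
                p = 0.0
            else:
                p = float(total) / n_pairs
            prob[a, b] = prob[b, a] = p
    return prob


def sbm_generate(partition: Partition, block_prob: np.ndarray, n_samples: int = 1,
                 seed=None, node_labels=None) -> list:
    """Sample binary undirected SBM graphs given a node partition.

    Edge (i, j), i != j, is present independently with probability
    ``block_prob[g_i, g_j]``.
    """
    block_prob = np.asarray(block_prob, dtype=float)
    if np.any(block_prob < 0) or np.any(block_prob > 1):
        raise SurrogateError("block probabilities must lie in [0, 1]")
    if np.abs(block_prob - block_prob.T).max(initial=0.0) > 1e-12:
        raise SurrogateError("block probability matrix must be symmetric")
    labels = partition.labels
    n = labels.size
    p_pair = block_prob[np.ix_(labels, labels)]
    rng = np.random.default_rng(seed)
    if node_labels is None:
        node_labels = list(range(n))
    out = []
    iu = np.triu_indices(n, k=1)
    for _ in range(n_samples):
        u = rng.random(iu[0].size)
        adj = np.zeros((n, n))
        present = u < p_pair[iu]
        adj[iu[0][present], iu[1][present]] = 1.0
        adj = adj + adj.T
        out.append(WeightedNetwork(node_labels, adj))
    return out


def surrogate_comparison(nets, n_surrogates: int = 50, seed=None,
                         n_runs: int = 10, swaps_per_edge: int = 10) -> pd.DataFrame:
    """Maximized single-layer Q for originals vs rewired and SBM surrogates.

    For each input network: maximize Q (best-of-``n_runs`` iterated
    Louvain), generate ``n_surrogates`` degree-preserving rewires and
    ``n_surrogates`` SBM samples seeded from the recovered partition, and
    maximize Q on each.  SBM modularity is evaluated on the binary samples.
    Returns a long-format table (network, condition, sample, Q).
    """
    from .community import genlouvain_iterated

    rng = np.random.default_rng(seed)
    rows = []
    for ni, net in enumerate(nets):
        res = genlouvain_iterated(net, n_runs=n_runs,
                                  seed=int(rng.integers(2**31)))
        rows.append({"network": ni, "condition": "original", "sample": 0,
                     "Q": res.Q})
        off_diag = ~np.eye(net.n_nodes, dtype=bool)
        if (net.weights[off_diag] > 0).all():
            # complete topology: no double-edge swap can change it
            if n_surrogates > 0:
                warnings.warn(
                    f"network {ni} is complete; rewired surrogates skipped",
                    stacklevel=2,
                )
        else:
            for k in range(n_surrogates):
                rw = rewire_random(net, swaps_per_edge=swaps_per_edge,
                                   seed=int(rng.integers(2**31)))
                q_rw = genlouvain_iterated(rw, n_runs=n_runs,
                                           seed=int(rng.integers(2**31))).Q
                rows.append({"network": ni, "condition": "rewired",
                             "sample": k, "Q": q_rw})
        if n_surrogates > 0:
            prob = block_prob_from_network(net, res.partition)
            prob = np.clip(prob, 0.0, 1.0)
            part = Partition.single_layer(res.partition.labels)
            samples = sbm_generate(part, prob, n_samples=n_surrogates,
                                   seed=int(rng.integers(2**31)),
                                   node_labels=net.node_labels)
            for k, g in enumerate(samples):
                if g.total_weight == 0:
                    q_sbm = 0.0  # empty sample: no structure to score
                else:
                    q_sbm = genlouvain_iterated(g, n_runs=n_runs,
                                                seed=int(rng.integers(2**31))).Q
                rows.append({"network": ni, "condition": "sbm", "sample": k,
                             "Q": q_sbm})
    return pd.DataFrame(rows, columns=["network", "condition", "sample", "Q"])
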