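"""Multislice modularity and its maximization by iterated generalized Louvain.

The quality function is

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma_s k_is k_js / (2 m_s)) d_sr
                               + d_ij C_jsr ] d(g_is, g_jr)

with k_is the intra-layer strength, m_s the layer's total edge weight and
C the replica-coupling matrix.  For a single layer this is classical
Newman-Girvan modularity.  The maximizer is a Louvain procedure on the
supra-modularity matrix with either greedy moves or ``moverandw`` (a move is
sampled with probability proportional to its positive modularity gain),
iterated by restarting from its own output until the partition is stable,
and repeated over independent runs keeping the best Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import (
    GraphError,
    MultiplexNetwork,
    Partition,
    QualityParams,
    WeightedNetwork,
    build_multiplex,
    canonical_labels,
)


class CommunityError(ValueError):
    pass


@dataclass
class QualityResult:
    Q: float
    partition: Partition
    params: QualityParams
    n_communities: int


def _as_multiplex(net) -> MultiplexNetwork:
    if isinstance(net, WeightedNetwork):
        return build_multiplex([net], 0.0)
    return net


def modularity_matrix(mux: MultiplexNetwork, params: QualityParams | None = None):
    """Unnormalized supra-modularity matrix B and the 2*mu normalization.

    Q(partition) = sum of B over same-community node-layer pairs / two_mu.
    """
    mux = _as_multiplex(mux)
    if params is None:
        params = QualityParams()
    n, L = mux.n_nodes, mux.n_layers
    gamma = params.gamma_per_layer(L)
    B = np.zeros((n * L, n * L))
    intra_total = 0.0
    for s, layer in enumerate(mux.layers):
        A = layer.weights
        if np.any(A < 0):
            raise CommunityError(
                f"layer {s} has negative weights; take absolute values upstream"
            )
        k = layer.strengths
        two_m = float(k.sum())
        if two_m <= 0:
            raise CommunityError(
                f"layer {s} is empty (m_s = 0): the null model is undefined"
            )
        intra_total += two_m
        sl = slice(s * n, (s + 1) * n)
        B[sl, sl] = A - gamma[s] * np.outer(k, k) / two_m
    eye = np.eye(n)
    for s in range(L):
        for r in range(L):
            if r != s and mux.coupling[s, r] != 0:
                B[s * n:(s + 1) * n, r * n:(r + 1) * n] += mux.coupling[s, r] * eye
    coup_total = float(mux.n_nodes * (mux.coupling.sum()))
    if params.mu_convention == "coupled":
        two_mu = intra_total + coup_total
    else:
        two_mu = intra_total
    return B, two_mu


def _partition_score(B: np.ndarray, labels: np.ndarray) -> float:
    """sum_{ij: g_i = g_j} B_ij (ordered pairs, diagonal included)."""
    k = int(labels.max()) + 1
    s = 0.0
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        s += float(B[np.ix_(idx, idx)].sum())
    return s


def multislice_quality(
    mux, partition: Partition, params: QualityParams | None = None
) -> QualityResult:
    """Evaluate multislice modularity of a given partition."""
    mux = _as_multiplex(mux)
    if params is None:
        params = QualityParams()
    expected = mux.n_nodes * mux.n_layers
    if partition.labels.size != expected:
        raise CommunityError(
            f"partition covers {partition.labels.size} node-layers, network has {expected}"
        )
    B, two_mu = modularity_matrix(mux, params)
    q = _partition_score(B, partition.labels) / two_mu
    return QualityResult(
        Q=float(q),
        partition=partition,
        params=params,
        n_communities=partition.n_communities,
    )


# ---------------------------------------------------------------------------
# Louvain machinery (dense supra-modularity matrix)
# ---------------------------------------------------------------------------

def _sweep(B, labels, rng, move_rule, tol):
    """One Louvain phase: move nodes between communities until local optimum.

    Moving node v from community c to d changes the partition score by
    2 * (link[d] - link[c \\ v]) since B is symmetric and the diagonal term
    follows the node.  A fresh (empty) community is always a candidate so
    nodes can split off when their within-community weight is negative.
    Returns True if any node moved.
    """
    n = B.shape[0]
    moved_any = False
    next_free = int(labels.max()) + 1
    while True:
        moved_this_pass = False
        for v in rng.permutation(n):
            c = labels[v]
            row = B[v]
            link = np.bincount(labels, weights=row, minlength=next_free + 1)
            link[c] -= B[v, v]
            gains = 2.0 * (link - link[c])
            gains[c] = 0.0
            # candidate "split off" community is next_free (link = 0 there)
            if move_rule == "moverandw":
                pos = np.flatnonzero(gains > tol)
                if pos.size == 0:
                    continue
                p = gains[pos]
                target = int(rng.choice(pos, p=p / p.sum()))
            else:  # greedy, ties to the lowest community index
                target = int(np.argmax(gains))
                if gains[target] <= tol:
                    continue
            labels[v] = target
            if target == next_free:
                next_free += 1
            moved_this_pass = moved_any = True
        if not moved_this_pass:
            break
    return moved_any


def _louvain_once(B, init, rng, move_rule, tol):
    """Full multi-level Louvain from an initial labelling; returns labels."""
    full = np.arange(B.shape[0])
    level_B = B
    level_labels = canonical_labels(np.asarray(init, dtype=int))
    while True:
        _sweep(level_B, level_labels, rng, move_rule, tol)
        level_labels = canonical_labels(level_labels)
        k = int(level_labels.max()) + 1
        full = level_labels[full]
        if k == level_B.shape[0]:
            # every super-node is its own community: no coarsening possible
            break
        S = np.zeros((level_B.shape[0], k))
        S[np.arange(level_B.shape[0]), level_labels] = 1.0
        level_B = S.T @ level_B @ S
        level_labels = np.arange(k)
    return canonical_labels(full)


def genlouvain_iterated(
    mux,
    params: QualityParams | None = None,
    n_runs: int = 100,
    seed=None,
    move_rule: str = "moverandw",
    max_iterate: int = 100,
) -> QualityResult:
    """Best-of-``n_runs`` iterated generalized Louvain maximization.

    Each run starts from singletons, runs multi-level Louvain, then restarts
    the whole procedure from its own output partition until stable
    ("iterated").  The best run by Q is returned (exact Q ties broken by the
    lexicographically smallest canonical label vector).  Deterministic given
    ``seed``.
    """
    if move_rule not in ("moverandw", "greedy"):
        raise CommunityError(f"unknown move_rule {move_rule!r}")
    if n_runs < 1:
        raise CommunityError("n_runs must be >= 1")
    mux = _as_multiplex(mux)
    if params is None:
        params = QualityParams()
    B, two_mu = modularity_matrix(mux, params)
    tol = 1e-12 * max(1.0, float(np.abs(B).max()))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_runs):
        labels = np.arange(B.shape[0])
        labels = _louvain_once(B, labels, rng, move_rule, tol)
        for _ in range(max_iterate):
            new = _louvain_once(B, labels.copy(), rng, move_rule, tol)
            if np.array_equal(new, labels):
                break
            labels = new
        score = _partition_score(B, labels)
        key = (-score, tuple(labels))
        if best is None or key < best[0]:
            best = (key, labels)
    labels = best[1]
    part = Partition(labels, n_nodes=mux.n_nodes, n_layers=mux.n_layers)
    return QualityResult(
        Q=float(_partition_score(B, part.labels) / two_mu),
        partition=part,
        params=params,
        n_communities=part.n_communities,
    )


def exhaustive_max_quality(mux, params: QualityParams | None = None) -> QualityResult:
    """Exact maximum-modularity partition by enumerating all set partitions.

    Only feasible for very small networks (<= ~12 node-layers); used as the
    ground-truth oracle when validating the Louvain maximizer.
    """
    mux = _as_multiplex(mux)
    if params is None:
        params = QualityParams()
    B, two_mu = modularity_matrix(mux, params)
    M = B.shape[0]
    if M > 13:
        raise CommunityError("exhaustive enumeration limited to <= 13 node-layers")
    best_labels = None
    best_score = -np.inf
    labels = np.zeros(M, dtype=int)

    def recurse(v: int, k: int, score: float):
        # score = partition score of nodes < v under current labels
        nonlocal best_labels, best_score
        if v == M:
            if score > best_score:
                best_score = score
                best_labels = labels[:].copy()
            return
        row = B[v, :v]
        for c in range(k + 1):
            labels[v] = c
            delta = 2.0 * float(row[labels[:v] == c].sum()) + B[v, v]
            recurse(v + 1, max(k, c + 1), score + delta)

    recurse(0, 0, 0.0)
    part = Partition(best_labels, n_nodes=mux.n_nodes, n_layers=mux.n_layers)
    return QualityResult(
        Q=float(best_score / two_mu),
        partition=part,
        params=params,
        n_communities=part.n_communities,
    )
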