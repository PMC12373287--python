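"""Weighted single-layer and multiplex network containers.

A multiplex network here is a set of L node-aligned weighted layers plus an
L x L matrix of replica-coupling weights: inter-layer edges connect a node
only to its own replica in another layer.  Node-layer quantities are stored
in *layer-major* order throughout the package: the node-layer (i, s) maps to
the linear index ``i + s * N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SYMMETRY_TOL = 1e-12


class GraphError(ValueError):
    """Invalid network construction or incompatible inputs."""


def _as_matrix(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise GraphError(f"weights must be a square matrix, got shape {w.shape}")
    return w


@dataclass
class WeightedNetwork:
    """Undirected weighted graph on an ordered node set.

    ``weights`` is the symmetric N x N adjacency matrix with an exactly zero
    diagonal (self-loops are rejected: the configuration-model null term
    assumes none).
    """

    node_labels: list
    weights: np.ndarray

    def __post_init__(self):
        self.node_labels = list(self.node_labels)
        self.weights = _as_matrix(self.weights)
        n = self.weights.shape[0]
        if n < 1:
            raise GraphError("network needs at least one node")
        if len(self.node_labels) != n:
            raise GraphError(
                f"{len(self.node_labels)} labels for {n}-node weight matrix"
            )
        if len(set(self.node_labels)) != n:
            raise GraphError("node labels must be unique")
        if np.isnan(self.weights).any():
            raise GraphError("weights contain NaN")
        asym = np.abs(self.weights - self.weights.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.argmax(np.abs(self.weights - self.weights.T)), self.weights.shape
            )
            raise GraphError(
                f"weights not symmetric: |W[{i},{j}] - W[{j},{i}]| = {asym:.3g}"
            )
        # exact symmetry downstream
        self.weights = (self.weights + self.weights.T) / 2.0
        diag = np.abs(np.diag(self.weights)).max(initial=0.0)
        if diag > 0:
            i = int(np.argmax(np.abs(np.diag(self.weights))))
            raise GraphError(
                f"self-loop on node {self.node_labels[i]!r} (diagonal must be zero)"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Weighted degree k_i = sum_j A_ij."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """m = half the sum of all entries (total edge weight)."""
        return float(self.weights.sum()) / 2.0

    def binarized(self, threshold: float = 0.0) -> "WeightedNetwork":
        """Copy with weights replaced by 1 where weight > threshold."""
        return WeightedNetwork(self.node_labels, (self.weights > threshold).astype(float))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        idx = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(*idx):
            w = self.weights[i, j]
            if w != 0:
                g.add_edge(self.node_labels[i], self.node_labels[j], weight=float(w))
        return g


@dataclass
class MultiplexNetwork:
    """L node-aligned weighted layers plus replica-coupling weights.

    ``coupling[s, r]`` is the weight of the inter-layer edge joining each
    node's replicas in layers s and r (symmetric, zero diagonal).
    """

    node_labels: list
    layers: list
    coupling: np.ndarray

    def __post_init__(self):
        self.node_labels = list(self.node_labels)
        if not self.layers:
            raise GraphError("at least one layer required")
        for li, layer in enumerate(self.layers):
            if layer.node_labels != self.node_labels:
                bad = next(
                    (a for a, b in zip(layer.node_labels, self.node_labels) if a != b),
                    "<missing>",
                )
                raise GraphError(
                    f"layer {li} node labels disagree with multiplex order "
                    f"(first offending node: {bad!r})"
                )
        L = len(self.layers)
        self.coupling = _as_matrix(self.coupling)
        if self.coupling.shape != (L, L):
            raise GraphError(
                f"coupling must be {L}x{L}, got {self.coupling.shape}"
            )
        if np.any(self.coupling < 0):
            raise GraphError("coupling weights must be nonnegative")
        if np.abs(self.coupling - self.coupling.T).max(initial=0.0) > SYMMETRY_TOL:
            raise GraphError("coupling matrix must be symmetric")
        if np.abs(np.diag(self.coupling)).max(initial=0.0) > 0:
            raise GraphError("coupling diagonal must be zero")
        self.coupling = (self.coupling + self.coupling.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def node_layer_index(self, i: int, s: int) -> int:
        """Layer-major linear index of node i in layer s."""
        return i + s * self.n_nodes


def build_multiplex(layers: Sequence[WeightedNetwork], coupling_weight: float = 1.0) -> MultiplexNetwork:
    """Assemble a multiplex network with uniform replica coupling.

    Every node is linked to each of its replicas with weight
    ``coupling_weight`` (for two layers: one replica edge per node, the
    standard unit inter-layer edge of multiplex brain networks).
    """
    layers = list(layers)
    if not layers:
        raise GraphError("at least one layer required")
    if coupling_weight < 0:
        raise GraphError("coupling_weight must be nonnegative")
    L = len(layers)
    coupling = np.full((L, L), float(coupling_weight))
    np.fill_diagonal(coupling, 0.0)
    return MultiplexNetwork(layers[0].node_labels, layers, coupling)


def node_layer_strengths(mux: MultiplexNetwork):
    """Intra-layer and coupling strengths, each as an N x L matrix.

    intra[i, s] = sum_j A_ijs; coup[i, s] = sum_{r != s} C[s, r] (the same
    for every node of the layer, since only replicas are coupled).
    """
    intra = np.column_stack([layer.strengths for layer in mux.layers])
    per_layer = mux.coupling.sum(axis=1)
    coup = np.tile(per_layer, (mux.n_nodes, 1))
    return intra, coup


def supra_adjacency(mux: MultiplexNetwork) -> np.ndarray:
    """(NL) x (NL) supra-adjacency in layer-major order.

    Diagonal blocks are the layer matrices, off-diagonal blocks are
    ``coupling[s, r] * I``.
    """
    n, L = mux.n_nodes, mux.n_layers
    supra = np.zeros((n * L, n * L))
    eye = np.eye(n)
    for s in range(L):
        supra[s * n:(s + 1) * n, s * n:(s + 1) * n] = mux.layers[s].weights
        for r in range(L):
            if r != s and mux.coupling[s, r] != 0:
                supra[s * n:(s + 1) * n, r * n:(r + 1) * n] = mux.coupling[s, r] * eye
    return supra


@dataclass
class Partition:
    """Community assignment per node-layer, layer-major, canonical ids 0..K-1."""

    labels: np.ndarray
    n_nodes: int
    n_layers: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size != self.n_nodes * self.n_layers:
            raise GraphError(
                f"partition needs {self.n_nodes * self.n_layers} labels, "
                f"got {self.labels.size}"
            )
        if np.any(self.labels < 0):
            raise GraphError("community ids must be nonnegative")
        self.labels = canonical_labels(self.labels)

    @classmethod
    def single_layer(cls, labels) -> "Partition":
        labels = np.asarray(labels, dtype=int)
        return cls(labels, n_nodes=labels.size, n_layers=1)

    @classmethod
    def from_layers(cls, per_layer: Sequence[Sequence[int]]) -> "Partition":
        arrays = [np.asarray(a, dtype=int) for a in per_layer]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise GraphError("all layers must assign the same number of nodes")
        return cls(np.concatenate(arrays), n_nodes=n, n_layers=len(arrays))

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def layer_labels(self, s: int) -> np.ndarray:
        n = self.n_nodes
        return self.labels[s * n:(s + 1) * n]


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities to 0..K-1 in order of first appearance."""
    labels = np.asarray(labels, dtype=int)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {int(c): k for k, c in enumerate(order)}
    return np.array([remap[int(c)] for c in labels], dtype=int)


@dataclass
class QualityParams:
    """Parameters of the multislice modularity quality function.

    gamma
        Per-layer resolution (scalar broadcast to all layers); 1 by default.
    mu_convention
        How the 2*mu normalization is formed: ``"coupled"`` sums intra-layer
        strengths plus coupling strengths (the multislice steady-state
        normalization, under which the sum of nodal contributions equals the
        optimizer's Q); ``"intra_only"`` sums intra-layer strengths alone.
        Conservation of nQ holds under either.
    """

    gamma: float | Sequence[float] = 1.0
    mu_convention: str = "coupled"

    def __post_init__(self):
        if self.mu_convention not in ("coupled", "intra_only"):
            raise GraphError(
                f"unknown mu_convention {self.mu_convention!r}"
            )
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if np.any(g <= 0):
            raise GraphError("gamma must be positive")

    def gamma_per_layer(self, n_layers: int) -> np.ndarray:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            return np.full(n_layers, float(g[0]))
        if g.size != n_layers:
            raise GraphError(f"gamma has {g.size} entries for {n_layers} layers")
        return g
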