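"""Comparison node metrics: degree, clustering coefficient and PageRank in
single-layer and multiplex flavours, plus the metric-vs-nQ correlation.

Multiplex degree adds the replica-coupling strength to the intra-layer
strength.  The multiplex clustering coefficient is the two-triangle ratio:
paths of two edges in one layer closed by an edge in the other, divided by
open one-triads, aggregated over both ordered layer pairs.  Multiplex
PageRank follows the "combined" recursion, where centrality on one layer
multiplicatively biases both the link weights and the teleportation
distribution on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import MultiplexNetwork, WeightedNetwork, node_layer_strengths


class MetricError(ValueError):
    pass


@dataclass
class MetricVector:
    name: str
    values: np.ndarray
    node_labels: list
    layer_index: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise MetricError(f"metric {self.name!r} has non-finite values")


def degree_multiplex(mux: MultiplexNetwork) -> MetricVector:
    """Node-layer strength including inter-layer (replica) edges."""
    intra, coup = node_layer_strengths(mux)
    values = (intra + coup).T.ravel()  # layer-major
    return MetricVector(
        name="multiplex_degree",
        values=values,
        node_labels=list(mux.node_labels),
        layer_index=np.repeat(np.arange(mux.n_layers), mux.n_nodes),
    )


def degree_single(net: WeightedNetwork) -> MetricVector:
    return MetricVector("degree", net.strengths, list(net.node_labels))


def clustering_multiplex(mux: MultiplexNetwork, weighted: bool = False) -> MetricVector:
    """Two-triangle clustering coefficient for dual-layer networks.

    For node i: (number of two-triangles centred at i) / (number of
    one-triads centred at i), summed over both ordered layer pairs; 0/0 is
    defined as 0.  Counting is on the binarized (> 0) graphs, which is
    invariant to positive rescaling of weights.  For complete weighted
    layers (where binary counting is degenerate) ``weighted=True`` uses
    geometric-mean edge weights for triangles and sqrt products for triads.
    """
    if mux.n_layers != 2:
        raise MetricError(
            f"two-triangle clustering is defined for 2 layers, got {mux.n_layers}"
        )
    if weighted:
        A1 = np.cbrt(mux.layers[0].weights)
        A2 = np.cbrt(mux.layers[1].weights)
        T1 = np.sqrt(mux.layers[0].weights)
        T2 = np.sqrt(mux.layers[1].weights)
    else:
        A1 = (mux.layers[0].weights > 0).astype(float)
        A2 = (mux.layers[1].weights > 0).astype(float)
        T1, T2 = A1, A2
    # two-triangles centred at i with wings in layer s, base in layer r
    tri = np.diag(A1 @ A2 @ A1) + np.diag(A2 @ A1 @ A2)
    k1 = T1.sum(axis=1)
    k2 = T2.sum(axis=1)
    if weighted:
        triads = (k1 ** 2 - (T1 ** 2).sum(axis=1)) + (k2 ** 2 - (T2 ** 2).sum(axis=1))
    else:
        triads = k1 * (k1 - 1) + k2 * (k2 - 1)
    values = np.divide(tri, triads, out=np.zeros_like(tri), where=triads > 0)
    return MetricVector(
        name="multiplex_clustering",
        values=values,
        node_labels=list(mux.node_labels),
        params={"weighted": weighted},
    )


def clustering_single(net: WeightedNetwork) -> MetricVector:
    """Classical (binary) clustering coefficient per node."""
    import networkx as nx

    g = net.binarized().to_networkx()
    cc = nx.clustering(g)
    values = np.array([cc[label] for label in net.node_labels])
    return MetricVector("clustering", values, list(net.node_labels))


def _pagerank_power(A: np.ndarray, damping: float, tol: float, max_iter: int,
                    weights_bias: np.ndarray | None = None,
                    teleport: np.ndarray | None = None) -> np.ndarray:
    """Power iteration for (biased) PageRank on a symmetric weight matrix.

    Column j distributes to i proportionally to A_ij * weights_bias_i;
    dangling columns teleport.  Returns the stationary probability vector.
    """
    n = A.shape[0]
    bias = np.ones(n) if weights_bias is None else weights_bias
    v = np.full(n, 1.0 / n) if teleport is None else teleport / teleport.sum()
    W = A * bias[:, None]
    col = W.sum(axis=0)
    dangling = col <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(col > 0, W / col, 0.0)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (M @ x + x[dangling].sum() * v) + (1 - damping) * v
        x_new = x_new / x_new.sum()
        if np.abs(x_new - x).sum() < tol:
            return x_new
        x = x_new
    raise MetricError(
        f"PageRank did not converge in {max_iter} iterations "
        f"(residual {np.abs(x_new - x).sum():.3g})"
    )


def pagerank_single(net: WeightedNetwork, damping: float = 0.85,
                    tol: float = 1e-10, max_iter: int = 1000) -> MetricVector:
    """Standard weighted PageRank (transition weights proportional to edge
    weight, row-normalized by strength)."""
    x = _pagerank_power(net.weights, damping, tol, max_iter)
    return MetricVector("pagerank", x, list(net.node_labels),
                        params={"damping": damping})


def pagerank_multiplex_combined(
    mux: MultiplexNetwork,
    bias_layer: int = 0,
    target_layer: int = 1,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> MetricVector:
    """Combined multiplex PageRank across a pair of layers.

    First the standard PageRank x is computed on ``bias_layer``.  On
    ``target_layer`` the recursion is then biased by x twice (both
    "strategies"): node i's incoming link weights are multiplied by x_i and
    the teleportation distribution is proportional to x.  The returned
    node-layer vector carries the plain PageRank on the bias layer and the
    combined centrality on the target layer, each summing to 1 per layer.
    """
    if bias_layer == target_layer:
        raise MetricError("bias_layer and target_layer must differ")
    if np.any(mux.layers[target_layer].weights < 0) or np.any(
        mux.layers[bias_layer].weights < 0
    ):
        raise MetricError("combined PageRank requires nonnegative weights")
    x = _pagerank_power(mux.layers[bias_layer].weights, damping, tol, max_iter)
    combined = _pagerank_power(
        mux.layers[target_layer].weights, damping, tol, max_iter,
        weights_bias=x, teleport=x,
    )
    n, L = mux.n_nodes, mux.n_layers
    values = np.zeros(n * L)
    values[bias_layer * n:(bias_layer + 1) * n] = x
    values[target_layer * n:(target_layer + 1) * n] = combined
    return MetricVector(
        name="multiplex_pagerank_combined",
        values=values,
        node_labels=list(mux.node_labels),
        layer_index=np.repeat(np.arange(L), n),
        params={"damping": damping, "bias_layer": bias_layer,
                "target_layer": target_layer},
    )


def metric_vs_nq(metric: MetricVector, nq) -> dict:
    """Pearson correlation between a node metric and nQ.

    When the metric is per node (no layer axis) and nQ is per node-layer,
    nQ values are pooled by broadcasting the metric across layers.
    Returns r, the p-value and the aligned value pairs for plotting.
    """
    from scipy import stats as _stats

    nq_values = np.asarray(nq.values, dtype=float)
    m = np.asarray(metric.values, dtype=float)
    if m.size != nq_values.size:
        n_layers = nq_values.size // m.size
        if m.size * n_layers != nq_values.size:
            raise MetricError(
                f"cannot align metric ({m.size}) with nQ ({nq_values.size})"
            )
        m = np.tile(m, n_layers)
    if np.ptp(m) == 0 or np.ptp(nq_values) == 0:
        raise MetricError("Pearson r undefined: zero variance in one vector")
    r, p = _stats.pearsonr(m, nq_values)
    return {"metric": metric.name, "r": float(r), "p_value": float(p),
            "pairs": np.column_stack([m, nq_values])}
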