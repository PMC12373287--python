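"""Per-node(-layer) modularity contributions (nQ).

The global multislice modularity is decomposed over node-layers:

    Q_i(s) = (1/2mu) * sum_{jr} [ (A_ijs - gamma_s k_is k_js / (2 m_s)) d_sr
                                  + d_ij C_jsr ] d(g_is, g_jr)

so that sum over all node-layers of Q_i(s) equals Q exactly.  The sum is
unrestricted: the self term j = i, r = s (which contributes
-gamma_s k_is^2 / (2 m_s 2mu), since A_iis = 0) is included whenever the
node's community matches itself, i.e. always; dropping it silently breaks
conservation.  Each coupling weight C[s, r] is credited once per ordered
layer pair to the node in layer s, mirroring the symmetric double count in
the quality function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import CommunityError, modularity_matrix, multislice_quality
from .graph import (
    MultiplexNetwork,
    Partition,
    QualityParams,
    WeightedNetwork,
    build_multiplex,
)


@dataclass
class NodalModularityResult:
    """Per-node-layer modularity contributions in layer-major order."""

    values: np.ndarray
    node_labels: list
    layer_index: np.ndarray
    total_Q: float
    partition: Partition
    params: QualityParams

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.layer_index = np.asarray(self.layer_index, dtype=int)

    @property
    def n_layers(self) -> int:
        return int(self.layer_index.max()) + 1

    def per_node(self) -> np.ndarray:
        """Convenience reducer: nQ summed over layers, one value per node."""
        n = len(self.node_labels)
        out = np.zeros(n)
        for s in range(self.n_layers):
            out += self.values[s * n:(s + 1) * n]
        return out

    def layer_values(self, s: int) -> np.ndarray:
        n = len(self.node_labels)
        return self.values[s * n:(s + 1) * n]

    def to_frame(self):
        import pandas as pd

        n = len(self.node_labels)
        return pd.DataFrame(
            {
                "node_label": [self.node_labels[i % n] for i in range(self.values.size)],
                "layer": self.layer_index,
                "community": self.partition.labels,
                "nQ": self.values,
            }
        )


def nodal_modularity_multiplex(
    mux: MultiplexNetwork, partition: Partition, params: QualityParams | None = None
) -> NodalModularityResult:
    """nQ per node-layer of a multiplex network under a given partition."""
    if params is None:
        params = QualityParams()
    expected = mux.n_nodes * mux.n_layers
    if partition.labels.size != expected:
        raise CommunityError(
            f"partition covers {partition.labels.size} node-layers, network has {expected}"
        )
    B, two_mu = modularity_matrix(mux, params)
    same = partition.labels[:, None] == partition.labels[None, :]
    values = (B * same).sum(axis=1) / two_mu
    layer_index = np.repeat(np.arange(mux.n_layers), mux.n_nodes)
    return NodalModularityResult(
        values=values,
        node_labels=list(mux.node_labels),
        layer_index=layer_index,
        total_Q=float(values.sum()),
        partition=partition,
        params=params,
    )


def nodal_modularity_single(
    net: WeightedNetwork, partition: Partition, params: QualityParams | None = None
) -> NodalModularityResult:
    """Single-layer nQ: Q_i = (1/2m) sum_j [A_ij - k_i k_j / 2m] d(g_i, g_j)."""
    if partition.n_layers != 1:
        raise CommunityError("single-layer nQ requires a single-layer partition")
    mux = build_multiplex([net], 0.0)
    return nodal_modularity_multiplex(mux, partition, params)


def maximize_and_decompose(
    net, params: QualityParams | None = None, n_runs: int = 100, seed=None,
    move_rule: str = "moverandw",
) -> NodalModularityResult:
    """Maximize multislice modularity, then decompose the best partition."""
    from .community import genlouvain_iterated

    res = genlouvain_iterated(net, params=params, n_runs=n_runs, seed=seed,
                              move_rule=move_rule)
    if isinstance(net, WeightedNetwork):
        net = build_multiplex([net], 0.0)
    return nodal_modularity_multiplex(net, res.partition, res.params)


def nq_group_table(per_subject, labels):
    """Assemble subjects x node-layers nQ matrix plus group labels.

    ``per_subject`` is a list of NodalModularityResult sharing node labels
    and layer structure; ``labels`` gives one group label per subject.
    Returns a ``GroupStudy`` ready for the statistics stage.
    """
    from .stats import GroupStudy, StatsError

    if len(per_subject) != len(labels):
        raise StatsError(
            f"{len(per_subject)} subjects but {len(labels)} group labels"
        )
    first = per_subject[0]
    for k, res in enumerate(per_subject):
        if res.node_labels != first.node_labels or not np.array_equal(
            res.layer_index, first.layer_index
        ):
            raise StatsError(f"subject {k} node/layer annotations mismatch")
    values = np.vstack([res.values for res in per_subject])
    return GroupStudy(
        values=values,
        groups=list(labels),
        node_labels=list(first.node_labels),
        layer_index=first.layer_index.copy(),
        metric_name="nQ",
        metadata={"mu_convention": first.params.mu_convention},
    )
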