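"""Synthetic inputs for every pipeline stage: planted-partition multiplex
networks, task-structured ROI time-series, and two-group nQ studies with
planted lesions.

All generators are deterministic given their seed and produce objects that
satisfy the package's graph invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import (
    MultiplexNetwork,
    Partition,
    WeightedNetwork,
    build_multiplex,
)
from .connectivity import RoiTimeSeries


class SyntheticError(ValueError):
    pass


def _roi_names(n: int) -> list:
    return [f"roi{i:03d}" for i in range(n)]


def planted_multiplex(
    n_nodes: int = 60,
    n_layers: int = 2,
    n_communities: int = 3,
    p_in: float = 0.9,
    p_out: float = 0.1,
    w_in: float = 1.0,
    w_out: float = 0.5,
    coupling: float = 1.0,
    persist: float = 1.0,
    jitter: float = 0.05,
    seed=None,
):
    """Planted-partition multiplex network with cross-layer module dynamics.

    Within/between-block edges appear with probabilities ``p_in``/``p_out``
    and weights ``w_in``/``w_out`` plus small uniform jitter.  A fraction
    ``1 - persist`` of nodes is reassigned to a random community in each
    layer after the first, creating modules that change across layers.
    Returns (MultiplexNetwork, ground-truth Partition).
    """
    if not (0 <= p_out <= p_in <= 1):
        raise SyntheticError("need 0 <= p_out <= p_in <= 1")
    if not 0 <= persist <= 1:
        raise SyntheticError("persist must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels0 = np.arange(n_nodes) % n_communities
    layer_labels = [labels0]
    for _ in range(1, n_layers):
        lab = labels0.copy()
        move = rng.random(n_nodes) >= persist
        lab[move] = rng.integers(0, n_communities, size=int(move.sum()))
        layer_labels.append(lab)
    layers = []
    names = _roi_names(n_nodes)
    iu = np.triu_indices(n_nodes, k=1)
    for lab in layer_labels:
        same = lab[iu[0]] == lab[iu[1]]
        p = np.where(same, p_in, p_out)
        w = np.where(same, w_in, w_out)
        present = rng.random(iu[0].size) < p
        w = w * present
        if jitter > 0:
            w = w + present * rng.uniform(-jitter, jitter, size=w.size)
        w = np.clip(w, 0.0, None)
        adj = np.zeros((n_nodes, n_nodes))
        adj[iu] = w
        adj = adj + adj.T
        layers.append(WeightedNetwork(names, adj))
    mux = build_multiplex(layers, coupling)
    truth = Partition.from_layers(layer_labels)
    return mux, truth


# --- task time-series -------------------------------------------------------

# durations (s) of the fixed trial segments preceding encoding
_PRE_ENCODING = 2.5 + 3.0 + 0.25 + 2.0  # warning, fixation, blank, instructions
_ENCODING = 2.0
_PROBE = 4.0
_ITI = 2.0


def make_trial_table(
    n_trials: int = 31,
    maintenance_menu=(2.0, 4.0, 6.0, 8.0),
    start: float = 0.0,
    accuracy: float = 1.0,
    seed=None,
) -> pd.DataFrame:
    """Trial timing table following the task procedure.

    Per trial: 7.75 s of warning/fixation/blank/instruction screens, a 2 s
    encoding display, a maintenance delay drawn from ``maintenance_menu``,
    a 4 s probe display and a 2 s inter-trial interval.  ``correct`` is
    Bernoulli(``accuracy``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = float(start)
    for k in range(n_trials):
        maintenance = float(rng.choice(maintenance_menu))
        enc_onset = t + _PRE_ENCODING
        probe_onset = enc_onset + _ENCODING + maintenance
        rows.append(
            {
                "trial_id": k,
                "encoding_onset": enc_onset,
                "encoding_duration": _ENCODING,
                "maintenance_duration": maintenance,
                "probe_onset": probe_onset,
                "probe_duration": _PROBE,
                "correct": bool(rng.random() < accuracy),
            }
        )
        t = probe_onset + _PROBE + _ITI
    return pd.DataFrame(rows)


def synthetic_task_timeseries(
    n_rois: int = 85,
    communities=None,
    n_trials: int = 31,
    maintenance_menu=(2.0, 4.0, 6.0, 8.0),
    tr: float = 2.0,
    correlation_strength: float = 1.0,
    noise_sd: float = 0.3,
    accuracy: float = 0.9,
    probe_communities=None,
    seed=None,
):
    """ROI time-series with trial structure and planted community signal.

    Each ROI's signal is a shared community latent (fresh white noise per
    volume) scaled by ``correlation_strength`` plus independent noise.
    During probe windows the latents follow ``probe_communities`` (defaults
    to the encmaint map), so the two phase layers can carry different
    community structure.  Returns (RoiTimeSeries, trial table, dict of
    ground-truth community maps).
    """
    rng = np.random.default_rng(seed)
    if communities is None:
        communities = np.arange(n_rois) % 4
    communities = np.asarray(communities, dtype=int)
    if probe_communities is None:
        probe_communities = communities
    probe_communities = np.asarray(probe_communities, dtype=int)
    trials = make_trial_table(
        n_trials=n_trials,
        maintenance_menu=maintenance_menu,
        accuracy=accuracy,
        seed=rng.integers(2**31),
    )
    last = trials.iloc[-1]
    t_end = float(last["probe_onset"] + last["probe_duration"]) + _ITI + 4.0
    n_vol = int(np.ceil(t_end / tr))
    mid = (np.arange(n_vol) + 0.5) * tr

    k = int(max(communities.max(), probe_communities.max())) + 1
    latents_enc = rng.standard_normal((k, n_vol))
    latents_probe = rng.standard_normal((k, n_vol))

    in_probe = np.zeros(n_vol, dtype=bool)
    for _, row in trials.iterrows():
        s = row["probe_onset"] + 2.0
        in_probe |= (mid >= s) & (mid < s + row["probe_duration"])

    data = noise_sd * rng.standard_normal((n_rois, n_vol))
    enc_part = latents_enc[communities]
    probe_part = latents_probe[probe_communities]
    data += correlation_strength * np.where(in_probe[None, :], probe_part, enc_part)

    ts = RoiTimeSeries(_roi_names(n_rois), data, sampling_rate=1.0 / tr)
    truth = {"encmaint": communities, "probe": probe_communities}
    return ts, trials, truth


# --- two-group lesion studies ----------------------------------------------

def _subject_network(base: np.ndarray, names, noise_sd: float, rng) -> WeightedNetwork:
    n = base.shape[0]
    iu = np.triu_indices(n, k=1)
    w = base[iu] + noise_sd * rng.standard_normal(iu[0].size)
    w = np.clip(w, 0.0, 1.0)
    adj = np.zeros_like(base)
    adj[iu] = w
    adj = adj + adj.T
    return WeightedNetwork(names, adj)


def planted_lesion_study(
    n_controls: int = 8,
    n_patients: int = 8,
    n_nodes: int = 85,
    n_communities: int = 5,
    w_in: float = 0.6,
    w_out: float = 0.2,
    subject_noise_sd: float = 0.1,
    lesioned_nodes=None,
    lesion_size: float = 1.5,
    n_runs: int = 10,
    seed=None,
):
    """Two-group nQ study with a planted within-module lesion.

    The base network is complete and weighted (fMRI-like |rho| weights):
    ``w_in`` within planted modules, ``w_out`` between.  Each subject gets
    independent edge noise.  For patients, edges between each lesioned node
    and its own-module partners are scaled by ``lesion_size`` before nQ is
    computed (lesions act on network weights so the ground-truth effect is
    controlled).  Each subject's partition is found with best-of-``n_runs``
    iterated Louvain, nQ is decomposed from it, and the assembled GroupStudy
    is returned with the ground-truth lesion mask.
    """
    from .community import genlouvain_iterated
    from .nodal import nodal_modularity_multiplex, nq_group_table

    if n_controls < 2 or n_patients < 2:
        raise SyntheticError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    names = _roi_names(n_nodes)
    communities = np.arange(n_nodes) % n_communities
    base = np.where(
        communities[:, None] == communities[None, :], w_in, w_out
    ).astype(float)
    np.fill_diagonal(base, 0.0)
    if lesioned_nodes is None:
        # one lesioned node per community, spread across modules
        lesioned_nodes = [int(np.flatnonzero(communities == c)[0])
                          for c in range(min(5, n_communities))]
    lesioned_nodes = sorted(int(v) for v in lesioned_nodes)
    if any(v < 0 or v >= n_nodes for v in lesioned_nodes):
        raise SyntheticError("lesioned_nodes must index into the node set")

    lesion_mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    for v in lesioned_nodes:
        partners = communities == communities[v]
        lesion_mask[v, partners] = True
        lesion_mask[partners, v] = True
    np.fill_diagonal(lesion_mask, False)

    results, labels = [], []
    for group, count, lesioned in (
        ("control", n_controls, False),
        ("patient", n_patients, True),
    ):
        for _ in range(count):
            net = _subject_network(base, names, subject_noise_sd, rng)
            w = net.weights.copy()
            if lesioned and lesion_size != 1.0:
                w[lesion_mask] = np.clip(w[lesion_mask] * lesion_size, 0.0, 1.0)
                net = WeightedNetwork(names, w)
            mux = build_multiplex([net], 0.0)
            res = genlouvain_iterated(mux, n_runs=n_runs,
                                      seed=int(rng.integers(2**31)))
            results.append(nodal_modularity_multiplex(mux, res.partition,
                                                      res.params))
            labels.append(group)
    study = nq_group_table(results, labels)
    truth = {
        "lesioned_nodes": lesioned_nodes,
        "lesion_size": lesion_size,
        "communities": communities,
    }
    return study, truth
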