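"""Readers and writers for the package's TSV interchange formats.

TSV with explicit headers is the lingua franca: the networks involved are
small dense matrices and human-diffable artifacts aid review.  All writers
serialize numeric values to full precision (repr round-trip).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TRIAL_COLUMNS, RoiTimeSeries, validate_trials
from .graph import GraphError, MultiplexNetwork, Partition, WeightedNetwork, build_multiplex
from .stats import GroupStudy


class FormatError(ValueError):
    pass


_FLOAT_FMT = "%.17g"


# --- adjacency matrices -----------------------------------------------------

def write_adjacency(net: WeightedNetwork, path) -> None:
    """Adjacency TSV: header row/column of node labels."""
    df = pd.DataFrame(net.weights, index=net.node_labels, columns=net.node_labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="node")


def read_adjacency(path) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise FormatError(f"{path}: row and column labels disagree")
    w = df.to_numpy(dtype=float)
    asym = np.abs(w - w.T)
    if asym.max(initial=0.0) > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"{path}: adjacency not symmetric; worst cell ({labels[i]}, "
            f"{labels[j]}) differs by {asym[i, j]:.3g}"
        )
    w = (w + w.T) / 2.0
    try:
        return WeightedNetwork(labels, w)
    except GraphError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# --- edge lists -------------------------------------------------------------

def write_edgelist(net: WeightedNetwork, path) -> None:
    """3-column undirected edge list TSV (node_a, node_b, weight)."""
    iu = np.triu_indices(net.n_nodes, k=1)
    mask = net.weights[iu] != 0
    df = pd.DataFrame(
        {
            "node_a": [net.node_labels[i] for i in iu[0][mask]],
            "node_b": [net.node_labels[j] for j in iu[1][mask]],
            "weight": net.weights[iu][mask],
        }
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=False)


def read_edgelist(path, node_labels=None) -> WeightedNetwork:
    """Read an undirected weighted edge list; duplicate pairs are rejected.

    ``node_labels`` fixes the node order (and includes isolates); otherwise
    nodes appear in first-encounter order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str},
                     float_precision="round_trip")
    for col in ("node_a", "node_b", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if node_labels is None:
        node_labels = []
        for _, row in df.iterrows():
            for v in (row["node_a"], row["node_b"]):
                if v not in node_labels:
                    node_labels.append(v)
    index = {v: i for i, v in enumerate(node_labels)}
    n = len(node_labels)
    w = np.zeros((n, n))
    seen = set()
    for line, row in df.iterrows():
        a, b = row["node_a"], row["node_b"]
        if a not in index or b not in index:
            raise FormatError(f"{path} line {line + 2}: unknown node label")
        i, j = index[a], index[b]
        key = (min(i, j), max(i, j))
        if key in seen:
            raise FormatError(
                f"{path} line {line + 2}: duplicate undirected pair ({a}, {b})"
            )
        seen.add(key)
        w[i, j] = w[j, i] = float(row["weight"])
    try:
        return WeightedNetwork(node_labels, w)
    except GraphError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# --- multiplex bundles ------------------------------------------------------

def write_multiplex(mux: MultiplexNetwork, directory, layer_names=None) -> None:
    """One adjacency TSV per layer plus a JSON manifest (order, coupling)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if layer_names is None:
        layer_names = [f"layer{s}" for s in range(mux.n_layers)]
    for name, layer in zip(layer_names, mux.layers):
        write_adjacency(layer, directory / f"{name}.tsv")
    manifest = {
        "layers": [f"{name}.tsv" for name in layer_names],
        "coupling": mux.coupling.tolist(),
    }
    (directory / "multiplex.json").write_text(json.dumps(manifest, indent=2))


def read_multiplex(directory) -> MultiplexNetwork:
    directory = Path(directory)
    manifest = json.loads((directory / "multiplex.json").read_text())
    layers = [read_adjacency(directory / f) for f in manifest["layers"]]
    coupling = np.asarray(manifest["coupling"], dtype=float)
    return MultiplexNetwork(layers[0].node_labels, layers, coupling)


# --- partitions -------------------------------------------------------------

def write_partition(partition: Partition, node_labels, path) -> None:
    """Partition TSV: (node_label, layer_index, community_id)."""
    n = len(node_labels)
    rows = {
        "node_label": [node_labels[i % n] for i in range(partition.labels.size)],
        "layer_index": np.repeat(np.arange(partition.n_layers), n),
        "community_id": partition.labels,
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition(path, node_labels=None) -> Partition:
    df = pd.read_csv(path, sep="\t")
    for col in ("node_label", "layer_index", "community_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    n_layers = int(df["layer_index"].max()) + 1
    n = len(df) // n_layers
    if n * n_layers != len(df):
        raise FormatError(f"{path}: ragged node-layer table")
    df = df.sort_values(["layer_index"], kind="stable")
    return Partition(df["community_id"].to_numpy(), n_nodes=n, n_layers=n_layers)


# --- time-series ------------------------------------------------------------

def write_timeseries(ts: RoiTimeSeries, path) -> None:
    """Time-series TSV: '# sampling_rate_hz=' header line, then one row per
    ROI (first column the label)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={ts.sampling_rate!r}\n")
        df = pd.DataFrame(ts.data, index=ts.roi_labels)
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, header=False)


def read_timeseries(path) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# sampling_rate_hz="):
            raise FormatError(
                f"{path} line 1: expected '# sampling_rate_hz=' header"
            )
        rate = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0,
                         float_precision="round_trip")
    return RoiTimeSeries([str(i) for i in df.index], df.to_numpy(dtype=float), rate)


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path, sep="\t"))


# --- group studies and reports ---------------------------------------------

def write_study(study: GroupStudy, path) -> None:
    """GroupStudy TSV: one row per subject; group column then node-layer
    columns named '<node>@<layer>'."""
    cols = [f"{study.node_labels[j % len(study.node_labels)]}@{study.layer_index[j]}"
            for j in range(study.values.shape[1])]
    df = pd.DataFrame(study.values, columns=cols)
    df.insert(0, "group", study.groups)
    df.insert(0, "subject", study.subject_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=False)


def read_study(path, metric_name: str = "nQ") -> GroupStudy:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "group" not in df.columns or "subject" not in df.columns:
        raise FormatError(f"{path}: missing 'subject'/'group' columns")
    value_cols = [c for c in df.columns if c not in ("subject", "group")]
    node_labels, layer_index = [], []
    for c in value_cols:
        if "@" not in c:
            raise FormatError(f"{path}: column {c!r} not in node@layer form")
        node, layer = c.rsplit("@", 1)
        layer_index.append(int(layer))
        if int(layer) == 0:
            node_labels.append(node)
    return GroupStudy(
        values=df[value_cols].to_numpy(dtype=float),
        groups=list(df["group"]),
        node_labels=node_labels,
        layer_index=np.asarray(layer_index),
        metric_name=metric_name,
        subject_ids=list(df["subject"]),
    )


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
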