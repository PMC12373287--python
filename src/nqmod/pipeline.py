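"""One-shot pipeline runner: time-series -> phase networks -> multiplex ->
communities -> nQ -> optional metrics / surrogates / group statistics.

Every stage writes its artifact into the results directory and records its
parameters (gamma, mu convention, run counts, permutation counts, seeds) in
a machine-readable manifest, so a rerun with the same config and seed
reproduces identical numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as nio
from .community import genlouvain_iterated
from .connectivity import PhaseSpec, phase_networks
from .graph import QualityParams, build_multiplex
from .metrics import (
    clustering_multiplex,
    degree_multiplex,
    metric_vs_nq,
    pagerank_multiplex_combined,
)
from .nodal import nodal_modularity_multiplex
from .surrogates import surrogate_comparison

log = logging.getLogger("nqmod")


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "coupling": 1.0,
    "gamma": 1.0,
    "mu_convention": "coupled",
    "n_runs": 100,
    "move_rule": "moverandw",
    "highpass_hz": 0.06,
    "probe_shift_s": 2.0,
    "correct_only": True,
    "seed": 0,
    "metrics": False,
    "surrogates": 0,
}


def _validate(config: dict) -> dict:
    cfg = dict(DEFAULTS)
    cfg.update(config)
    has_ts = "timeseries" in cfg and "trials" in cfg
    has_layers = "layers" in cfg
    if not has_ts and not has_layers:
        raise ConfigError(
            "config must provide either 'timeseries' + 'trials' or 'layers' "
            "(list of adjacency TSVs)"
        )
    return cfg


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    ``config`` keys: ``timeseries``/``trials`` (paths) or ``layers``
    (list of adjacency paths), plus the parameters in ``DEFAULTS``.
    """
    cfg = _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"parameters": {k: v for k, v in cfg.items()
                               if not isinstance(v, (list, dict))},
                "stages": [], "artifacts": {}}

    if "timeseries" in cfg:
        log.info("stage connectivity: highpass=%s Hz, probe shift=%s s",
                 cfg["highpass_hz"], cfg["probe_shift_s"])
        ts = nio.read_timeseries(cfg["timeseries"])
        trials = nio.read_trials(cfg["trials"])
        specs = [PhaseSpec.encmaint(), PhaseSpec.probe(cfg["probe_shift_s"])]
        nets = phase_networks(ts, trials, specs=specs,
                              cutoff=cfg["highpass_hz"],
                              correct_only=cfg["correct_only"])
        layers = [nets[s.name] for s in specs]
        layer_names = [s.name for s in specs]
        for name, net in nets.items():
            nio.write_adjacency(net, out / f"network_{name}.tsv")
            manifest["artifacts"][f"network_{name}"] = f"network_{name}.tsv"
        manifest["stages"].append("connectivity")
    else:
        layers = [nio.read_adjacency(p) for p in cfg["layers"]]
        layer_names = [f"layer{i}" for i in range(len(layers))]

    mux = build_multiplex(layers, cfg["coupling"])
    nio.write_multiplex(mux, out / "multiplex", layer_names=layer_names)
    manifest["artifacts"]["multiplex"] = "multiplex/"
    manifest["stages"].append("multiplex")

    params = QualityParams(gamma=cfg["gamma"], mu_convention=cfg["mu_convention"])
    log.info("stage communities: %d runs, move_rule=%s, seed=%d",
             cfg["n_runs"], cfg["move_rule"], seed)
    res = genlouvain_iterated(mux, params=params, n_runs=int(cfg["n_runs"]),
                              seed=seed, move_rule=cfg["move_rule"])
    nio.write_partition(res.partition, mux.node_labels, out / "partition.tsv")
    manifest["artifacts"]["partition"] = "partition.tsv"
    manifest["stages"].append("communities")
    manifest["Q"] = res.Q
    manifest["n_communities"] = res.n_communities

    nq = nodal_modularity_multiplex(mux, res.partition, params)
    nq.to_frame().to_csv(out / "nq.tsv", sep="\t", index=False,
                         float_format="%.17g")
    manifest["artifacts"]["nq"] = "nq.tsv"
    manifest["stages"].append("nq")

    if cfg["metrics"] and mux.n_layers == 2:
        from .metrics import MetricError

        rows = {}
        # binary clustering is degenerate on complete layers: use weights
        complete = all((l.weights[~np.eye(mux.n_nodes, dtype=bool)] > 0).all()
                       for l in mux.layers)
        for mv in (degree_multiplex(mux),
                   clustering_multiplex(mux, weighted=complete),
                   pagerank_multiplex_combined(mux)):
            try:
                rows[mv.name] = metric_vs_nq(mv, nq)["r"]
            except MetricError as exc:
                log.warning("metric %s skipped: %s", mv.name, exc)
                rows[mv.name] = None
        manifest["metric_correlations"] = rows
        manifest["stages"].append("metrics")

    n_surr = int(cfg["surrogates"])
    if n_surr > 0:
        table = surrogate_comparison(layers, n_surrogates=n_surr,
                                     seed=seed + 1)
        table.to_csv(out / "surrogate_q.tsv", sep="\t", index=False)
        manifest["artifacts"]["surrogate_q"] = "surrogate_q.tsv"
        manifest["stages"].append("surrogates")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
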