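"""Per-node group-difference statistics.

For each node(-layer) the two groups' metric values (typically nQ) are
compared with a two-sided permutation test of the difference of means,
Cohen's d effect size and the (folded) ROC AUC; Benjamini-Hochberg FDR is
applied jointly across all node-layers of one model.  The permutation
p-value is the plain proportion of permutations whose |mean difference|
reaches the observed one (no add-one correction by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

_ABS_TOL = 1e-12


class StatsError(ValueError):
    pass


@dataclass
class GroupStudy:
    """Subjects x node-layers metric matrix with two-group labels."""

    values: np.ndarray
    groups: list
    node_labels: list
    layer_index: np.ndarray
    metric_name: str = "nQ"
    subject_ids: list | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatsError("values must be subjects x node-layers")
        if np.isnan(self.values).any():
            raise StatsError("study values contain NaN")
        if len(self.groups) != self.values.shape[0]:
            raise StatsError("one group label per subject required")
        self.layer_index = np.asarray(self.layer_index, dtype=int)
        n_nl = self.values.shape[1]
        if self.layer_index.size != n_nl:
            raise StatsError("layer_index must cover all node-layers")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{k:03d}" for k in range(self.values.shape[0])]

    @property
    def group_names(self) -> list:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_values(self, name) -> np.ndarray:
        mask = np.array([g == name for g in self.groups])
        return self.values[mask]


def _n_splits(n: int, k: int) -> int:
    return math.comb(n, k)


def permutation_test(
    x, y, n_perm: int = 10000, seed=None, exhaustive_if_small: bool = False,
    alternative: str = "two-sided", add_one: bool = False,
):
    """Permutation test of the difference of means between two samples.

    The statistic is mean(x) - mean(y).  Two-sided by default: the p-value
    is the proportion of label permutations with |d_perm| >= |d_obs|
    ("greater" compares d_perm >= d_obs one-sidedly).  When the number of
    distinct splits is <= n_perm and ``exhaustive_if_small`` is set, all
    splits are enumerated; otherwise splits are Monte-Carlo sampled with
    the given seed.  Returns (p_value, observed_difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater"):
        raise StatsError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    obs = float(x.mean() - y.mean())
    total = _n_splits(n, nx)
    grand = pooled.sum()
    if exhaustive_if_small and total <= n_perm:
        diffs = np.empty(total)
        for idx, comb in enumerate(combinations(range(n), nx)):
            sx = pooled[list(comb)].sum()
            diffs[idx] = sx / nx - (grand - sx) / (n - nx)
    else:
        rng = np.random.default_rng(seed)
        mask = _mc_split_matrix(n, nx, n_perm, rng)
        sx = mask @ pooled
        diffs = sx / nx - (grand - sx) / (n - nx)
    tol = _ABS_TOL * max(1.0, abs(obs))
    if alternative == "two-sided":
        hits = np.abs(diffs) >= abs(obs) - tol
    else:
        hits = diffs >= obs - tol
    count = int(hits.sum())
    denom = diffs.size
    if add_one:
        return (count + 1) / (denom + 1), obs
    return count / denom, obs


def effect_size(x, y) -> float:
    """Cohen's d with pooled standard deviation; sign = mean(x) - mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("each group needs at least 2 subjects for Cohen's d")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        raise StatsError("zero pooled standard deviation: effect size undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def roc_auc(x, y, fold: bool = True) -> float:
    """Mann-Whitney AUC of y (e.g. disease) vs x (e.g. control) values.

    AUC = (#{pairs with y > x} + 0.5 #ties) / (|x| |y|).  With ``fold``
    (default) the result is max(AUC, 1 - AUC), mapping separability onto
    [0.5, 1] regardless of direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be nonempty")
    greater = (y[:, None] > x[None, :]).sum()
    ties = (y[:, None] == x[None, :]).sum()
    auc = (greater + 0.5 * ties) / (x.size * y.size)
    if fold:
        auc = max(auc, 1.0 - auc)
    return float(auc)


def bh_fdr(p_values, alpha: float = 0.2):
    """Benjamini-Hochberg step-up FDR control.

    Returns (pass_flags, adjusted_p): the standard largest-k step-up rule
    and monotone adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise StatsError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def _mc_split_matrix(n: int, nx: int, n_perm: int, rng) -> np.ndarray:
    """n_perm x n boolean matrix; each row marks a random size-nx group."""
    keys = rng.random((n_perm, n))
    order = np.argsort(keys, axis=1)
    mask = np.zeros((n_perm, n), dtype=bool)
    rows = np.repeat(np.arange(n_perm), nx)
    mask[rows, order[:, :nx].ravel()] = True
    return mask


def node_group_report(
    study: GroupStudy,
    alpha: float = 0.2,
    p_thresh: float = 0.05,
    n_perm: int = 10000,
    seed=None,
    exhaustive_if_small: bool = False,
) -> pd.DataFrame:
    """Per-node-layer permutation p, effect size and folded AUC, with BH-FDR
    applied jointly across all node-layers of the model.

    Rows are flagged significant iff p <= p_thresh AND the BH flag passes.
    The same label permutations are shared across node-layers (vectorized),
    which is the standard practice and leaves each marginal test exact.
    """
    names = study.group_names
    if len(names) != 2:
        raise StatsError(f"exactly two groups required, got {names}")
    gx = study.group_values(names[0])
    gy = study.group_values(names[1])
    if gx.shape[0] < 2 or gy.shape[0] < 2:
        raise StatsError("need at least 2 subjects per group")
    V = np.vstack([gx, gy])
    n, nx = V.shape[0], gx.shape[0]
    obs = gx.mean(axis=0) - gy.mean(axis=0)

    total = _n_splits(n, nx)
    if exhaustive_if_small and total <= n_perm:
        mask = np.zeros((total, n), dtype=bool)
        for idx, comb in enumerate(combinations(range(n), nx)):
            mask[idx, list(comb)] = True
    else:
        rng = np.random.default_rng(seed)
        mask = _mc_split_matrix(n, nx, n_perm, rng)
    diffs = (mask @ V) / nx - (~mask @ V) / (n - nx)
    tol = _ABS_TOL * np.maximum(1.0, np.abs(obs))
    p = (np.abs(diffs) >= np.abs(obs)[None, :] - tol[None, :]).mean(axis=0)

    d = np.array([effect_size(gx[:, j], gy[:, j]) for j in range(V.shape[1])])
    auc = np.array([roc_auc(gx[:, j], gy[:, j]) for j in range(V.shape[1])])
    fdr_pass, p_adj = bh_fdr(p, alpha=alpha)

    n_nodes = len(study.node_labels)
    report = pd.DataFrame(
        {
            "node_label": [study.node_labels[j % n_nodes]
                           for j in range(V.shape[1])],
            "layer": study.layer_index,
            "p_value": p,
            "p_adjusted": p_adj,
            "effect_size": d,
            "roc_auc": auc,
            "mean_diff": obs,
            "fdr_pass": fdr_pass,
        }
    )
    report["significant"] = (report["p_value"] <= p_thresh) & report["fdr_pass"]
    report.attrs["groups"] = names
    report.attrs["alpha"] = alpha
    report.attrs["p_thresh"] = p_thresh
    report.attrs["n_perm"] = int(diffs.shape[0])
    report.attrs["metric"] = study.metric_name
    return report
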