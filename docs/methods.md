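# Methods

## The measure

Multislice (multiplex) modularity scores a partition of node-layers by

    Q = (1/2μ) Σ_{ijsr} [ (A_ijs − γ_s k_is k_js / 2m_s) δ_sr + δ_ij C_jsr ] δ(g_is, g_jr)

where `A_ijs` are the intra-layer weights, `k_is` the intra-layer strengths,
`2m_s` the layer's total strength, `C[s,r]` the replica-coupling weight, and
`γ_s` a per-layer resolution parameter (1 throughout by default).  Nodal
modularity decomposes this sum over the first index: `nQ_i(s)` collects every
summand in which node-layer `(i, s)` is the first argument, so that the sum
of `nQ` over all node-layers equals `Q` *exactly* — conservation is an
algebraic identity of the implementation (both quantities are computed from
the same supra-modularity matrix `B`, with `Q = Σ_{g_i=g_j} B_ij / 2μ` and
`nQ = rowsum(B ⊙ same-community) / 2μ`), and the test suite additionally
verifies it against an independent nested-loop evaluation of the defining
formula.

Two conventions for the normalization `2μ` are implemented:

- `coupled` (default): `2μ = Σ_is (k_is + c_is)` where `c_is` is the
  coupling strength — the steady-state normalization of the multislice null
  model, under which `Σ nQ` equals the Q reported by the generalized-Louvain
  maximizer;
- `intra_only`: `2μ = Σ_is k_is`, intra-layer strengths alone.

Conservation holds under either; the flag is carried in result metadata.
Two easy-to-drop details the implementation deliberately keeps: the self
term `j=i, r=s` (which contributes `−γ_s k_is²/(2 m_s 2μ)`, forced by the
unrestricted sum), and the crediting of each coupling weight `C[s,r]` once
per *ordered* layer pair to the node in layer `s`, mirroring the symmetric
double count in the quality function.  Dropping either breaks conservation.

## Maximization

Communities are found by a generalized Louvain procedure on the dense
supra-modularity matrix: node sweeps move node-layers between communities
(including a split-off option, relevant because `B` has negative entries),
followed by aggregation into super-nodes, until no gain.  Two move rules:

- `moverandw` (default): a move is sampled among the strictly
  positive-gain candidates with probability proportional to its gain;
- `greedy`: the maximum-gain move, ties broken toward the lowest community
  index (seed-independent).

The whole procedure is *iterated* — restarted from its own output partition
until the partition is stable — and repeated over `n_runs` independent runs
(default 100), keeping the best Q.  Exact Q ties between runs are broken by
the lexicographically smallest canonical label vector, which makes the
result a pure function of (network, parameters, seed).  Community labels
are canonicalized to 0..K−1 in first-appearance order.  The optimizer
rejects negative weights: the intended handling of signed connectivity is
to take absolute values upstream (the `spearman_network` default), treating
negative correlations as equal to positive ones.

Numerical choices: move gains are compared against a tolerance of
`1e-12 × max(1, |B|_max)` to prevent cycling on ties; the optimizer's
internal score is discarded and the returned Q is recomputed by the
standalone evaluator, which the tests require to agree to 1e-10.  Empty
layers (`m_s = 0`) are rejected: the configuration-model null is undefined.
Exact maxima for validation come from `exhaustive_max_quality`, a pruned
recursive enumeration of all set partitions, feasible to ~13 node-layers.

## Network construction

ROI × time signals are high-pass filtered with a zero-phase (forward-
backward) Butterworth filter, order 4, default cutoff 0.06 Hz at a 0.5 Hz
sampling rate (the lowest task-trial frequency; no low-pass, since the
shortest task windows approach Nyquist).  Zero-phase filtering is chosen so
short task windows are not phase-shifted; the paper-style cutoff is the
only externally fixed quantity.

Task windows are defined by `PhaseSpec` rows over the trial table:
`encmaint` spans encoding (2 s) plus the variable maintenance delay
(2/4/6/8 s); `probe` spans the 4 s probe display shifted +2 s to reduce
overlap with the preceding window and better catch the hemodynamic peak.
A volume belongs to a window when its acquisition midpoint lies in the
half-open interval `[onset + shift, onset + shift + duration)`; volumes are
0-based, seconds are the external unit.  Incorrect trials are dropped by
default.  Window phases are concatenated across trials in trial order and
correlated with Spearman's rank correlation (average ranks on ties);
absolute values are taken by default for downstream community detection.
Constant ROI series fail loudly (correlation undefined) rather than being
zeroed.  Outlier-volume repair is assumed done upstream.

## Comparison metrics

- multiplex degree: intra-layer strength plus replica-coupling strength per
  node-layer;
- multiplex clustering (two layers): two-triangles (two edges in one layer
  closed in the other) over one-triads, both ordered layer pairs, counted
  on the binarized (>0) graphs with 0/0 := 0.  Binary counting is
  degenerate on complete layers, so a weighted variant (geometric-mean
  triangle weights, sqrt-product triads) is available behind a flag;
- combined multiplex PageRank: standard PageRank `x` on a bias layer, then
  a recursion on the target layer in which `x_i` multiplies both node i's
  incoming link weights and its teleportation probability (damping 0.85,
  L1 tolerance 1e-8, per-layer normalization to 1).  For the task networks
  the default direction is bias = encmaint, target = probe (temporal
  order); configurable.
- `metric_vs_nq` reports Pearson r over node-layer pairs, pooling both
  layers by default (per-layer available); per-node metrics are broadcast
  across layers.

## Surrogates

Degree-preserving randomization is Maslov–Sneppen double-edge swapping on
the binarized topology with each weight carried by its edge (node count,
binary degree sequence and weight multiset preserved exactly; 10 accepted
swaps per edge by default).  The SBM surrogate is binary: block connection
probabilities are estimated as mean edge weights per block pair (sensible
for |ρ|-weighted networks; the estimator is a documented stand-in, as no
canonical mapping from weighted networks to SBM probabilities exists), and
samples are drawn edge-independently given the recovered partition.

## Statistics

Per node-layer: two-sided permutation test of the difference of group
means (default 10 000 permutations; the p-value is the plain proportion of
permutations with `|Δ_perm| ≥ |Δ_obs|`, no add-one term — an add-one flag
exists), Cohen's d with pooled SD (the effect-size formula is this
package's choice, recorded in output metadata), and the Mann–Whitney ROC
AUC folded onto [0.5, 1] by default (raw orientation retained).
Benjamini–Hochberg FDR (via statsmodels) is applied jointly across all
node-layers of one model (170 for a dual-layer model, 85 per single-layer
model — never pooled across models), default α = 0.2; rows are flagged
significant iff `p ≤ 0.05` *and* the BH flag passes.  The same label
permutations are shared across node-layers (vectorized), which is standard
and leaves each marginal test exact.  Exhaustive enumeration replaces
Monte-Carlo sampling when the number of distinct splits is within budget
and the flag is set.

## Synthetic data

The generators define the conditions every test runs under:

- `planted_multiplex`: per-layer planted-partition graphs (edge
  probabilities `p_in`/`p_out`, weights `w_in`/`w_out` with ±0.05 uniform
  jitter), uniform replica coupling, and a `persist` fraction of nodes
  keeping their community across layers (reassignment may re-draw the same
  community, so the expected switch rate is `(1−persist)(K−1)/K`).
- `synthetic_task_timeseries`: trial tables with the task's fixed screen
  sequence (7.75 s pre-encoding, 2 s encoding, maintenance drawn from
  {2, 4, 6, 8} s, 4 s probe, 2 s inter-trial interval; 31 trials and TR 2 s
  by default; trial correctness Bernoulli with accuracy 0.9), and ROI
  signals built as shared per-community white-noise latents scaled by a
  correlation strength plus independent noise, with separate latents inside
  probe windows so the two phase layers can carry different community
  structure.  The latent-factor construction (rather than covariance
  sampling) keeps Spearman's monotone invariance testable and the
  generative story auditable.  It does not emulate hemodynamics,
  autocorrelated noise, motion or scanner drift beyond what the high-pass
  test needs — passing tests demonstrate pipeline correctness on planted
  correlation structure, not robustness to real fMRI artifacts.
- `planted_lesion_study`: complete weighted |ρ|-like base networks (0.6
  within / 0.2 between planted modules, 85 nodes, 5 modules by default),
  independent per-subject edge noise (sd 0.1, clipped to [0, 1]), and, for
  patients, within-module edges of the lesioned nodes (one per module by
  default) scaled by `lesion_size` before nQ is computed.  Lesions act on
  network weights, not time-series, so the ground-truth direction of the
  nQ effect is controlled; each subject's partition is re-estimated with
  best-of-`n_runs` (default 10) iterated Louvain, mirroring the per-subject
  analysis at a tractable run count.

## Problem sizes and design choices in the validation suite

The acceptance checks run at sizes chosen to be decisive yet desk-scale:
conservation on 200 random instances up to 60 nodes × 3 layers; optimizer
exactness against full partition enumeration on 20 random graphs of 5–10
nodes with best-of-100 runs; the 34-node Karate Club benchmark with
best-of-100 runs; surrogate ordering on five 50-node planted fixtures with
10 rewires each (sparse fixtures for rewiring, since a complete graph
admits no degree-preserving swap) and five complete weighted fixtures with
10 SBM samples each (moderate contrast, 0.5 within / 0.3 between: there
the binary sampling variance of the SBM dominates the small weight jitter
of the originals, which is the regime in which binary surrogates sharpen
apparent structure); type-I calibration over 500 null 16-subject × 85-node
replicates at 2 000 permutations; and lesion recovery over 20 seeds of the
default 8-vs-8 study.

## Known limitations

- The optimizer operates on dense matrices; intended for networks up to a
  few hundred nodes per layer, not large sparse graphs.
- Multiplex clustering is defined for exactly two layers; PageRank biasing
  for one ordered layer pair.
- Only uniform replica coupling is offered by the builder (general
  inter-layer topologies are out of scope); arbitrary coupling matrices can
  still be supplied directly.
- Group statistics assume two groups, no covariates, and exchangeable
  subjects under the null; FDR assumes independent or positively dependent
  tests.
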