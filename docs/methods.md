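# Methods

This note documents the modelling choices behind `dynhypernet`: what each
stage assumes, which parameters matter, what the synthetic cohorts do and do
not emulate, and where the design was genuinely open.

## Dynamic connectivity

Windows are rectangular, anchored at rows `0, s, 2s, …`; a trailing partial
window is discarded, so `W = ⌊(T−l)/s⌋ + 1`. Correlations are raw Pearson
values — no Fisher z-transform and no taper — and the connection order is the
fixed lexicographic enumeration of pairs `(i, j), i < j`; every downstream
node id refers to this order. A component with zero variance inside a window
is an error by default; a `zero` policy substitutes `r = 0` for the affected
pairs and is intended for synthetic edge cases only.

Defaults `l = 60` samples, `s = 1` at a 2 s sampling interval follow the
reference resting-state protocol (the package's parameter sweeps showed these
to be the accuracy optimum there). With `l = T` the matrix degenerates to a
single row of full-series correlations — the static-hypernetwork special
case, which `run_pipeline` flags in its report.

An important statistical consequence of `s = 1` and band-limited signals is
that consecutive windows share almost all their samples: a relevant series
of `W = 189` windows carries only a handful of effectively independent
values, so *chance* correlations between two unrelated relevant series are
large (empirically, s.d. ≈ 0.45 at the default dimensions). Every stage
downstream operates against this noise floor; it is intrinsic to the
windowing regime, not an implementation artifact.

## Grouping

k-medoids with k-means++ (D²) seeding, greedy PAM swaps (best improving swap
per iteration, at most 100), 10 restarts, minimal total within-cluster
distance wins; all ties break to the lowest index so a seed fully determines
the result. Distances are Euclidean between relevant-series columns;
correlation distance (1 − r) is available behind a switch.

Grouping is computed **once per cohort** on the row-stacked relevant-series
matrices of all subjects (`grouping_scope="pooled"`), so the group structure
of the regression penalty — and hence the supports it induces — is
comparable across subjects. The per-subject alternative remains available
(`grouping_scope="per-subject"`), but measurements on synthetic cohorts
showed that subject-specific groupings inject subject-idiosyncratic support
noise into every metric column (largest between-group effect size dropped
from d ≈ 1.8 to d ≈ 1.3, and FDR discoveries from 12 to 0, at matched
settings), which is why pooled is the default.

The group count `k` is a preset of the penalty, not an estimate: the
full-scale default is `k = 150` (calibrated by sweep in the reference
protocol at `M = 231` connections and clipped to `M` when the input is
smaller). For the 10-component synthetic regime (`M = 45`),
`PipelineConfig.desk_scale()` sets `k = 5`, chosen by the same
calibration-by-sweep applied at that scale: groups of ≈ 9 connections track
co-varying modules of ≈ 6, whereas large `k` fragments the penalty into
near-singletons and forfeits the group structure.

## Sparse group LASSO and the hypernetwork

The objective is literal — `‖y − Xα‖² + λ₁‖α‖₁ + λ₂ Σ_i ‖α_{G_i}‖₂` with no
½ on the quadratic and, by default, no group-size weighting
(`group_weighting="sqrt-size"` is available). The solver is monotone FISTA
with the exact step `1/L`, `L = 2σ_max(X)²`, the composite proximal operator
(elementwise soft-threshold, then groupwise shrinkage — exact for disjoint
groups), adaptive momentum restarts, and best-iterate tracking, so the
returned objective never exceeds the value at zero. Convergence is declared
when the best objective improves by less than `tol = 1e−5` (relative) over a
20-iteration span; non-convergence warns and returns the best iterate.

Columns of the design matrix and the response are centred and scaled to
**unit ℓ₂ norm** before solving. This makes `2·Xᵀy` a vector of (twice the)
correlations, so the λ₁ ladder 0.1 … 0.9 thresholds partial correlations on
an absolute, subject-independent scale; plain z-scoring would leave column
norms at √W and reduce the entire ladder to effectively zero penalty. Only
the support matters downstream, so the coefficient scale is immaterial.

Per seed, the ladder is swept in ascending order with warm starts; the
hyperedge is `{m} ∪ {j : |α_j| > 1e−6}`. Singleton hyperedges are dropped
(they carry no relational information and make overlap coefficients
undefined), and duplicate node-sets are deduplicated keeping the first
(lowest seed, smallest λ₁) provenance, because the node metrics quantify
over hyperedge existence and `|S(v)|` and duplicates would inflate them
spuriously.

## Hypergraph metrics

`N(v)` is the set of co-members of some hyperedge with `v`; `S(v)` the
hyperedges through `v`. HCC¹ and HCC² count neighbour pairs co-contained in
an edge excluding / including `v`, normalised by `C(|N(v)|, 2)`. For HCC³
the printed source formula carries a leading 2 that pushes the coefficient
above 1 under full overlap; the default variant drops it, giving
`(Σ_{e∈S(v)}(|e|−1) − |N(v)|) / (|N(v)|(|S(v)|−1)) ∈ [0, 1]`, with
`literal2x` available. The pairwise coefficient uses the geometric-mean
denominator `|S(u)∩S(v)| / √(|S(u)||S(v)|)` — the standard compromise
between the max- and min-criterion overlap ratios — with the literal product
behind a flag; HCCPN is its mean over `N(v)`. SP is the mean minimal number
of hyperedges traversed (BFS on the clique-expanded graph) to each
*reachable* peer; unreachable peers are excluded rather than assigned a
penalty constant.

Degenerate denominators (fewer than two neighbours or incident edges,
isolation) return 0 with a per-cell flag; `strict=True` raises instead. A
total function is required because sparse λ configurations legitimately
produce such nodes.

## Feature selection

Local features are the `5·M` metric columns (metric-major order, recorded in
output headers). Each column gets a two-sample KS statistic with a
**permutation** null — exact enumeration of all `C(n, n₁)` splits when that
count is ≤ 10⁴, otherwise `n_perm = 5000` sampled splits with the add-one
estimator — followed by a single Benjamini-Hochberg step-up across all
columns jointly at `q = 0.05`.  The permutation count is sized so the
p-value floor `1/(n_perm+1)` does not exceed the step-up threshold `q/m` at
the column counts in scope; a smaller `n_perm` silently disables low-rank
FDR rejections. The permutation set is shared across columns
(valid, since the null is the same label exchange). The KS statistic is
computed tie-safely (evaluated at the last occurrence of each distinct
pooled value), which matters because degenerate metric cells produce exact
zeros. If the FDR step rejects nothing, no filter is applied and all
non-constant columns feed the vector kernel: an empty rejection set is
absence of evidence, and collapsing to a single near-threshold column proved
actively harmful (it lets one noise column drive the kernel).

Subgraph patterns are hyperedge node-sets; a subject "contains" a pattern
when some hyperedge equals it exactly (subset containment behind a flag).
Scores are `S = |fq_pos − fq_neg|`; each candidate is assigned to its
higher-frequency group (ties to positive), each side is sorted by descending
score (ties: smaller pattern, then lexicographic) and the top `t₁ = t₂ = 36`
are kept.

## Kernels and fusion

Hypernetworks and patterns are clique-expanded with the node's global
connection id as its WL label, so label counts are comparable across
subjects; star expansion was rejected because its artificial hub nodes have
no shared identity. The WL subtree kernel sums label-count inner products
over iterations 0 … h (h = 3). All h rounds are always computed: stopping a
graph early once its own partition stabilises would freeze it in an older
compressed-label space and silently drop cross-graph matches. Label
compression goes through a shared dictionary (`WLCache`), which also lets
subject maps be computed once and reused across folds.

Each subject's graph-kernel embedding is its vector of WL similarities to
the selected patterns, ℓ₂-normalised. The vector kernel is an RBF on the
z-scored selected local features with a **per-feature bandwidth**,
`exp(−γ‖x−z‖²/p)` for `p` features, so the dimensionless γ grid (tuned
jointly with c) spans the useful range whatever the width of the selected
feature space. Both base kernels are trace-normalised to `n`. Fusion
weights come from the closed-form alignment maximiser `μ = F⁻¹b/‖F⁻¹b‖`
(pseudo-inverse if `F` is singular), uncentred, with negative components
permitted. When a base kernel is (near-)constant across subjects, the
closed form assigns it a large negative weight — the optimum effectively
centres the informative kernel through the all-ones matrix. That component
is inert in the SVM dual (the equality constraint annihilates it), so the
fused kernel receives only a tiny `ε·I` (`ε = 1e−8·trace/n`) diagonal nudge
when numerically indefinite; repairing by the full `|λ_min|` would bury the
informative structure under diagonal mass.

## Classification protocol

LOOCV with an SVM on the precomputed fused kernel. `nested` (default): for
each held-out subject, KS/FDR selection, FSFS, standardisation statistics
and μ are fit on the `n−1` training subjects; an inner stratified 5-fold
grid over `(c, γ) ∈ {2⁻⁷ … 2⁷}²` maximises inner accuracy, ties to the
smallest c then γ. `paper-literal` performs selection and standardisation
once on the whole cohort first. AUC is computed from the pooled held-out
decision values. The repetition protocol reruns everything with clustering
seed `base + r` and averages the metrics.

A caveat worth knowing: under exchangeable groups (no real signal), LOOCV
accuracy is pessimistically biased — each held-out subject's class is the
minority of its training fold, so a deterministic classifier drifts toward
the training majority and the null distribution centres below 0.5. The
informative direction of a label-shuffle control is therefore the upper
side: shuffled labels must not yield above-chance accuracy.

## Synthetic cohorts

Each component is unit-variance Gaussian noise band-limited to 0.01–0.10 Hz
(FFT masking) at TR = 2 s, T = 248 — dimensions typical of a resting-state
acquisition. In the positive group the four components spanning the planted
module (the 6 connections among components 0–3) are mixed with a shared
band-limited signal under a variance-preserving rule whose instantaneous
squared mixing coefficient is `β·m(t)`, `m(t)` a 0.005 Hz raised sinusoid:
the instantaneous correlation of two planted components is `β·m(t)`, so `β`
(default 0.8) is the peak pairwise correlation the coupling reaches and the
planted pairs' windowed correlations rise and fall together. The negative
group has no coupling; at `β = 0` the groups are exchangeable by
construction.

The default cohort is 20 + 20 subjects — the closest runtime-feasible
approximation of the 38 + 28 clinical cohort the protocol was designed for.
At markedly smaller n the LOOCV null bias described above dominates any
planted effect, so very small cohorts are suitable for smoke tests only.

What the generator deliberately does **not** emulate: hemodynamics, head
motion, physiological noise, spatially structured component mixing, or
between-subject variability in effect topography. Passing tests on these
cohorts therefore demonstrate that the pipeline recovers and classifies the
statistical structure it targets (co-varying windowed correlations), not
that it would achieve comparable numbers on clinical data.

## Problem sizes used by the validation suite

The end-to-end checks run the default cohort (N = 10 components, M = 45
connections, 40 subjects) with `desk_scale` settings, five repetitions for
the classification average, and a 10 + 10 null cohort; solver oracles and
metric enumerations use instances small enough for exhaustive reference
computation (hypergraphs with ≤ 5 nodes and ≤ 3 edges, regression problems
with ≤ 12 rows). The acceptance script averages three repetitions by
default.

## Known limitations

* Overlapping groups and weighted hypergraph paths are out of scope.
* The graph-kernel channel is nearly uninformative when hypernetworks are
  dense enough that every subject's graph covers all connection nodes — the
  WL iteration-0 term then dominates and the pattern-similarity vectors
  coincide across subjects. The discriminative signal of recurring module
  patterns is still visible in the FSFS scores themselves, and fusion
  weights then shift to the vector kernel.
* The KS permutation p-value floor is `1/(n_perm+1)`; with very many
  columns the BH threshold at small ranks can lie below this floor, making
  rank-1 discoveries impossible by construction. Raising `n_perm` trades
  runtime for resolution.
* The alignment-maximising weights may be negative (by design, following
  the closed form); with strongly collinear base kernels this can produce
  an indefinite fused kernel, which is passed to the SVM with only a
  numerical diagonal nudge (see above).
* At small cohort sizes the nested per-fold KS/FDR selection is unstable:
  the selected column sets can differ almost completely between folds, so
  each held-out subject is classified in a different feature space and
  cross-validated accuracy falls well below what the same features support
  under a stable (cohort-level) selection. The protocol was designed for
  cohorts of ~66 subjects and ~1155 columns, where the surviving set is
  stable; on desk-scale cohorts the selection stage is the accuracy
  bottleneck, not the features.
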