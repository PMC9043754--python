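# dynhypernet

High-order functional hypernetworks from multivariate time series, with
hypergraph topology features and multi-kernel classification.

## The problem

Resting-state functional connectivity is usually summarised one pair of
signals at a time, and statically. Both simplifications lose information:
neural interactions involve more than two regions at once, and the coupling
between regions drifts over the course of a scan. `dynhypernet` implements a
framework that keeps both aspects. It treats each *functional connection*
(an unordered pair of components) as an object in its own right, follows its
strength through time with a sliding window, and then asks which connections'
dynamics co-vary — a question about groups of connections, answered with a
hypergraph.

The intended use is two-group classification of subjects (e.g. patients vs
controls) from per-subject component time series, such as ICA component
signals from resting-state fMRI. Raw-image preprocessing and component
estimation are prerequisites, not part of this package: the pipeline starts
from plain `T x N` signal matrices.

## The model

For a subject with `N` components observed at `T` timepoints:

1. **Dynamic connectivity** — sliding windows of length `l` and step `s`
   give `W = ⌊(T−l)/s⌋ + 1` windowed Pearson correlation networks. The
   trace of one connection across windows,
   `TS_m = [r_ij(1), …, r_ij(W)]`, is its *relevant time series*; stacking
   all `M = N(N−1)/2` of them gives the `W x M` relevant-series matrix
   `CTS`.
2. **Grouping** — the `M` connections are clustered into `k` groups by
   k-medoids (k-means++ seeding, 10 restarts) on distances between their
   relevant series.
3. **Hypernetwork construction** — each connection `m` is regressed on all
   others with the sparse group LASSO

   `min_α ‖TS_m − CTS_m α‖² + λ₁‖α‖₁ + λ₂ Σ_i ‖α_{G_i}‖₂`

   where `CTS_m` has column `m` zeroed. The support of `α`, together with
   the seed `m`, forms a hyperedge; sweeping `λ₁` over the ladder
   0.1, …, 0.9 (with `λ₂ = 0.4`) and all seeds yields the subject's
   high-order hypernetwork on the `M` connection nodes.
4. **Topology features** — five node-level hypergraph metrics (three
   single-node clustering coefficients HCC¹–HCC³, the pair-node coefficient
   HCCPN, and the mean hyperedge-hop shortest path SP) give a `5·M`-column
   local-feature vector per subject; hyperedge node-sets act as subgraph
   patterns scored by their between-group frequency difference (FSFS), with
   the top-36 per group retained.
5. **Kernels and fusion** — an RBF kernel on the KS-permutation/BH-FDR
   selected local features and a linear kernel on Weisfeiler-Lehman subtree
   similarities between each subject's clique-expanded hypernetwork and the
   selected patterns are fused as `K_f = Σ μ_l K_l`, with
   `μ = F⁻¹b / ‖F⁻¹b‖` maximising the kernel-target alignment
   (`b_l = ⟨K_l, yyᵀ⟩_F`, `F_mn = ⟨K_m, K_n⟩_F`).
6. **Classification** — leave-one-out cross-validation with an SVM on the
   fused kernel; `(c, γ)` tuned on inner stratified 5-fold grids over
   `2⁻⁷ … 2⁷`; the whole pipeline repeated over clustering seeds and
   averaged. In the default `nested` mode every label-dependent step is fit
   inside each training fold; a `paper-literal` mode reproduces the common
   whole-cohort-selection protocol.

A synthetic-cohort generator produces band-limited (0.01–0.10 Hz, TR = 2 s)
component signals with a planted module of connections whose coupling is
modulated by a shared slow sinusoid in one group only — ground truth for
recovery and classification tests.

## Worked example

```bash
python examples/02_build_hypernetwork.py
```

prints, for one synthetic positive-group subject:

```
grouped 45 connections into 5 groups (within-cluster cost 92.8)
hypernetwork: 45 nodes, 250 hyperedges
hyperedges per lambda1 level: {0.1: 45, 0.2: 44, 0.3: 37, 0.4: 32, 0.5: 23,
                               0.6: 17, 0.7: 21, 0.8: 16, 0.9: 15}
26 hyperedges seeded at a planted connection contain another planted connection
```

The edge counts fall as `λ₁` grows (stronger within-group sparsity keeps
only the strongest partners), and hyperedges seeded at planted connections
repeatedly pick up the other module members — the co-variation structure the
regression is meant to find. `examples/03_metrics_and_selection.py` then
shows the planted module surfacing as the top discriminative subgraph
(score 1.00: present in every positive subject, absent in every negative),
and `examples/04_classification_pipeline.py` runs the full LOOCV pipeline.

The same stages are available as a thin CLI
(`dynhypernet simulate | connectivity | hypernet | metrics | select |
kernels | classify | run`) over TSV/CSV/JSON files; see
`dynhypernet --help`.

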