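# Methods

`spatialcontrast` implements graph self-supervised contrastive representation
learning for spatial transcriptomics, with three applications sharing one
core: spatial-domain clustering, multi-slice integration with implicit batch
correction, and cell-type deconvolution through a learned cell-to-spot
mapping matrix. This note records the model, its assumptions, the defaults
and why they were chosen, and what the synthetic benchmarks do and do not
demonstrate.

## Preprocessing

Raw counts are library-size normalized to a target sum (default 10^4 per
spot), log1p-transformed, reduced to the top highly variable genes
(Seurat-flavor normalized dispersion, default 3000), and z-scaled per gene.
This is the standard scanpy order (normalize → log → HVG → scale); the
per-gene mean/std are recorded so a single-cell reference can be placed on
the same scale before gene intersection. Zero-count spots are retained —
dropping them would desynchronize the coordinate table — and zero-variance
genes are dropped before scaling. Duplicate gene identifiers are resolved
first-wins with numeric suffixes so the mapping is deterministic and
reversible from logs.

A practical caveat worth knowing: Seurat-flavor HVG selection z-scores
dispersions *within mean bins*. Genes whose elevation pushes them into mean
bins populated only by other elevated genes lose their apparent advantage.
This is a property of the criterion, not of this implementation; on data
where nearly all informative genes are strongly and jointly elevated, the
`n_hvg` cut should be kept generous.

## Spatial graph

Spot coordinates define an undirected neighbor graph: each spot points at
its k nearest other spots by Euclidean distance (default k = 3) and the
adjacency is the symmetric OR of that directed relation. Selection is
**tie-inclusive**: every candidate tied at the k-th smallest distance is
included. This makes the graph deterministic, invariant to spot storage
order, and — crucially for vertical integration — keeps co-located spots
(overlaid serial sections) exactly exchangeable. An index-based tie-break
was considered and rejected: on overlaid slices it systematically routes
all tied choices toward whichever slice happens to be stored first, halving
the in-degree of the other slice and breaking the symmetry that cross-slice
smoothing relies on. On regular grids tie-inclusion means interior spots
get their full 4-neighborhood at k = 3; on generic coordinates (no exact
ties) it reduces to plain k-NN.

Graph convolutions use the symmetrically normalized adjacency
D^(-1/2)(A + I)D^(-1/2); self-loops are on by default so each spot retains
its own signal during aggregation (exposed as a flag). All eigenvalues of
this operator lie in [-1, 1].

## Representation model

One graph-convolution layer encodes the scaled expression X into
Z = ReLU(Ã X W_e + b_e) (latent width 64 by default) and a symmetric
single-layer decoder returns H = Ã Z W_d + b_d in gene space. A single
layer keeps the reconstruction interpretable as smoothed expression and is
the minimal realization of the symmetric encoder/decoder pair; depth is not
a tunable here.

Training jointly minimizes

* reconstruction: `L_recon = ||X − H||_F²`;
* a symmetric local-context contrastive loss. The corruption view shuffles
  expression vectors across spots while keeping the graph fixed. The
  context of spot i is `g_i = sigmoid(mean_{j∈N_i} z_j)` (self excluded); a
  bilinear discriminator `Φ(z, g) = sigmoid(zᵀ W g)` is asked to score
  (z_i, g_i) high and (z′_i, g_i) low, and the mirrored construction on the
  corrupted view's own summaries is added, giving `L_SCL + L_SCL_corrupt`.

Total loss `λ₁ L_recon + λ₂ (L_SCL + L_SCL_corrupt)` with λ₁ = 10, λ₂ = 1,
Adam at learning rate 1e-3, 600 epochs for clustering/integration and 1200
for deconvolution-facing runs. The discriminator weight matrix starts at
zero, so both contrastive terms open at exactly ln 2 (chance level) — a
useful initialization diagnostic. A fresh corruption permutation is drawn
every epoch (stronger negatives than a fixed one, still deterministic from
the seed). BCE terms are computed through softplus, which is the stable,
clamp-free form.

The networks are small enough (one layer each) that forward passes and
analytic gradients are coded directly in numpy with a hand-rolled Adam;
gradient correctness is enforced by finite-difference tests. Runs are
bitwise reproducible on one machine given the config seed. Everything is
full-batch; the implementation targets desk-scale datasets (up to a few
thousand spots — the all-pairs distance matrix in graph construction is the
first thing to replace for larger data).

## Clustering

Domains are assigned from the *reconstructed* expression H (not the
latent): H is reduced to 20 principal components and clustered with a
shared-covariance ("tied", the EEE analogue) Gaussian mixture, seeded and
with 5 initializations; a diagonal-covariance fallback handles singular
fits. When the domain count is unknown, it is chosen by maximal mean
silhouette over a candidate range (ties to the smaller count).

An optional refinement pass reassigns each spot to the most frequent label
among all other spots within radius r — one synchronous pass computed
entirely from pre-pass labels, ties and empty neighborhoods keeping the
current label. r is in input coordinate units: the conventional default of
50 suits Visium pixel coordinates, whereas unit-spaced fixture grids want
r ≈ 1.5 (one ring of 8 neighbors). Refinement is off by default; it helps
on coarse-grained laminar tissue and hurts on fine-grained data.

## Multi-slice integration

Slices already placed in one frame (rigid per-slice transforms are
accepted; alignment itself is an external pre-step) are concatenated,
restricted to their shared genes, preprocessed as one pool (a single HVG
set feeds a single encoder), and a single k-NN graph is built over pooled
coordinates so neighbor sets cross slice boundaries. No batch covariate
enters the model: correction comes from cross-slice feature smoothing plus
the contrastive pull between neighbors in different slices.

Mixing is quantified with iLISI: per spot, Gaussian-kernel weights over its
3×perplexity nearest neighbors (bandwidth binary-searched so the weight
entropy equals log perplexity, default 30), the inverse Simpson index of
the weighted batch frequencies, averaged over spots. Ranges from 1 (no
mixing) to the number of batches; invariant to rigid motions of the
embedding. The construction follows the LISI family; absolute values are
comparable in construction, not bitwise, with other implementations.

## Deconvolution

A single-hidden-layer autoencoder (genes → 64 ReLU → genes, mean squared
error, Adam 1e-3) denoises the reference cells into H_c. The mapping
matrix M (cells × spots) is parametrized as a column-wise softmax of free
logits, so each spot's column is a probability distribution over cells
after every optimizer step by construction. With H′ = Mᵀ H_c, the
objective is

    L = −α Σ_i Σ_{j∈N_i} log softmax_j( cos(h′_i, h_j)/τ )  +  β ||H − H′||_F²

with α = 1, β = 10, τ = 1, Adam 1e-3, 1200 epochs. The softmax denominator
runs over all spots p ≠ i (standard InfoNCE; neighbors included). An
alternative reading — negatives restricted to non-neighbors — is available
as `MappingConfig(negatives="non_neighbors")`; both paths are
gradient-checked. Zero-norm rows get cosine 0 with a warning. Logits start
at zero (uniform columns), which makes the fit exactly equivariant to
permutations of the reference cells. Cell annotations are never consulted
during fitting.

Annotation transfer is linear algebra on M: per spot, keep the
ceil(0.1·N_cell) highest-probability cells (probability ties toward the
smaller cell index), zero the rest without renormalizing, then
P_spot = M̃ᵀ S_cell and P_domain = S_spotᵀ P_spot. For comparison against
mixture proportions, P_spot rows are normalized to sum one.

Benchmark metrics per cell type across spots: Pearson correlation
(constant columns reported as 0 with a warning), global non-windowed SSIM
on min-max-scaled vectors (K1 = 0.01, K2 = 0.03, L = 1), RMSE on min-max-
scaled vectors, and base-2 Jensen–Shannon divergence between the
sum-normalized columns (bounded in [0, 1]; the base is recorded in the
output).

## Synthetic fixtures

The generators produce the statistical structure the method assumes, at
desk scale, so every pipeline stage is testable without downloads.

* **Domain slide** — a 32×32 grid partitioned into 4 contiguous quadrant
  domains (general counts use the nearest-square band product, stripes for
  primes); 500 genes with log-normal baselines (log-mean 1.5, log-sd 0.4);
  each domain elevates 30 disjoint marker genes by `effect_size` (default
  1.0) in log space. Noise is either log-normal ("gaussian", σ = 1 in log
  space, rounded) or negative binomial (gamma–Poisson, dispersion 0.3). One
  log-unit shifts on 30 markers against one log-unit noise is a
  deliberately clear but not trivial signal — roughly the contrast of
  cortical layers against within-layer variability.
* **Replicate slices** — the same layout and programs with independent
  noise and an additive per-slice per-gene log-offset of scale
  `batch_shift`; at `batch_shift = 3` (the integration benchmark) the first
  principal component of pooled data is batch, not biology.
* **Reference + spots** — 5 cell types × 60 cells, 20 disjoint markers per
  type elevated by 2 log-units (cell types are far more distinct than
  spatial domains), per-cell noise σ = 0.5; 100 spots on a 10×10 grid with
  Dirichlet(1) mixture weights blended half-and-half with the mean of
  their grid neighbors (the locality the contrastive loss presumes), each
  spot summing the counts of 10 reference cells drawn per its weights.
  Truth is the realized per-spot type fractions.

All generators are pure functions of spec + seed.

What passing these benchmarks shows: the optimization machinery is correct
(losses match loop-built oracles and finite differences), the pipeline
recovers planted spatial structure under substantial noise, cross-slice
smoothing removes a dominant additive batch effect without a batch
covariate, and the mapping matrix recovers known mixtures. What it does not
show: robustness to real-platform artifacts that the fixtures deliberately
omit — dropout sparsity patterns, hexagonal lattices and tissue-mask
irregularity, cell-type imbalance, reference/spot platform shifts, or
ambient RNA. Real-data performance claims require real data.

## Numerical and design notes

* All computation is float64; determinism is per-machine (BLAS reductions
  may differ across builds).
* PCA uses the full SVD solver (exact, deterministic) — appropriate at
  desk scale.
* The mixture model's tied covariance mirrors the EEE covariance structure
  of model-based clustering; PCA depth (20) and covariance type are
  exposed.
* Workflow runs derive named per-stage seeds from the single global seed
  (CRC32 of the stage name into a SeedSequence), so any stage can be re-run
  in isolation with the same stream; all derived seeds stay below 2^31.
* Degenerate inputs: spots with empty neighbor sets (impossible after
  graph construction) would fall back to their own embedding in the local
  summary; all-zero expression rows survive preprocessing as zero vectors;
  an empty gene intersection between reference and spots is a hard error.
* The CLI (`spatial-contrast {simulate|cluster|integrate|deconvolve}`)
  is a thin layer over the library: one flat YAML config, flags override
  file values, every run writes a manifest with config, seeds and package
  version.
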