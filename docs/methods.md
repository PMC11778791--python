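# Methods

## Problem setting

Two single-cell datasets measure different molecular layers on different
cells: a source matrix `X_S` (n_s cells × m genes, expression, with
cell-type labels) and a target matrix `X_T` (n_t cells × m genes,
chromatin-accessibility-derived gene activity, unlabeled). No cell is
shared between them, so integration must rely on shared *biological*
structure — the same cell types producing correlated gene-level signals in
both layers. The method treats label transfer as domain adaptation: learn a
co-embedding in which the two distributions overlap, then classify target
cells from their source neighbors.

Cells are rows in every matrix in this package. Accessibility peak
matrices can be collapsed to gene activities beforehand: a peak contributes
its counts to every gene whose body plus promoter window (default 2000 bp
upstream of the TSS, strand-aware; BED-style 0-based half-open coordinates,
GTF converted on read) it overlaps. The aggregation is an unweighted sum —
the common convention; no weighting scheme is implied by the underlying
model.

## Preprocessing

Counts/activities are library-size normalized per cell to 10,000 and
log1p-transformed before any projection or training. Both steps are
toggleable (`RunConfig.normalize`, `target_sum`); the defaults are the
standard single-cell practice and the pipeline makes no attempt to infer
them from the data.

## Diagonal CCA and the hybrid graph

Classical CCA needs paired samples, which unpaired datasets lack. We use
the diagonal form (as popularized for cross-dataset single-cell anchoring):
per-gene standardize each matrix within its dataset, take the SVD
`Z_s Z_tᵀ = U S Vᵀ`, and use `U√S` / `V√S` as shared coordinates
(`d_cca = 20` components by default, capped at `min(n_s, n_t, m) − 1`).
The reported canonical correlation of component *i* is the cosine between
the gene-space representatives `Z_sᵀu_i` and `Z_tᵀv_i`; it equals 1 when
the datasets are copies, and components are ordered so correlations are
non-increasing. Signs are fixed deterministically (largest-magnitude entry
of each source vector made positive).

Mutual nearest neighbors are computed in this space with exact Euclidean
k-NN (`k_mnn = 20`; distance ties broken toward the lower index). The
hybrid graph has two blocks: source↔target MNN pairs, and source↔source
MNN pairs computed with self-neighbors excluded. Target↔target edges are
intentionally absent: unlabeled cells receive information only through
anchored paths into the labeled dataset. Edges are binary by default; a
Gaussian proximity weighting `exp(−‖x−y‖²/2σ²)` is available
(`weighted_edges`), with σ defaulting to the median pairwise distance in
CCA space. For graph convolution the adjacency is normalized once as
`Ã = D^{-1/2}(A + I)D^{-1/2}`, whose spectrum lies in [−1, 1].

## Model and losses

**Sub-vector autoencoders (one per modality).** Each cell's m-vector is
split into `n_sub = 8` contiguous sub-vectors (zero-padded tail) passed
through a *shared* linear+ReLU block encoder (width 16), concatenated, and
linearly projected to the `K = 32` latent space; the decoder mirrors this.
Sharing block weights keeps the parameter count independent of m and
regularizes the fit on small datasets.

**MK-MMD.** The squared maximum mean discrepancy between source and target
latent samples under a convex combination of five Gaussian kernels with
bandwidths `{¼, ½, 1, 2, 4} × median pairwise distance` and uniform
weights β = 1/5. The biased estimator (diagonal included, hence
nonnegative) is the default; the unbiased variant is available. The median
heuristic is recomputed per batch from the current embeddings.

**Best-match cosine loss.** `1 − mean_t max_s cos(e_t, e_s)` over a batch:
every target embedding is pulled toward its best-matching source embedding
in angle. Because the "best match" is the current nearest vector, this
objective can lock in wrong matches if it dominates early training; it is
therefore weighted as an auxiliary term (`λ_cos = 0.1`) next to MK-MMD
(`λ_mmd = 1`), which aligns distributions without committing to pairings.

**Training.** Stage 1 minimizes
`recon_src + recon_tgt + λ_mmd·MMD(z_s, z_t) + λ_cos·cosine(z_s, z_t)`
on mini-batches (Adam, lr 1e-3, batch 256, 60 epochs). Stage 2 trains the
two-layer GCN `Ŷ = softmax(Ã ReLU(Ã Z W⁰) W¹)` full-batch on the frozen
concatenated latents, minimizing `λ_ce·CE(source labels)` plus
`λ_mmd·MMD(H¹_src, H¹_tgt)` on the hidden layer (150 epochs). Placing the
stage-2 MMD on the hidden layer (rather than the softmax output) adapts
the representation the k-NN transfer actually uses; applying it to the
output as well is a flag (`mmd_on_output`). A one-conv-layer variant with
a dense softmax head exists as `single_conv` for comparison. Reconstruction
loss is not carried into stage 2. All randomness (weight init, batch
order, simulation) derives from one integer seed, and runs are
bit-reproducible.

Training runs on a small reverse-mode autodiff core over numpy written for
this package (`omicbridge/_autograd.py`); its gradients are verified
against central finite differences in the test suite. Losses with exact
closed-form values at their extremes (cosine, MMD on identical samples,
cross-entropy of uniform predictions) are implemented so those values are
attained to floating-point accuracy, not merely approximately.

## Label transfer

Each target cell collects the plurality vote of its k = 30
Euclidean-nearest source cells in the stage-2 hidden embedding. The
confidence is the vote fraction; cells below 0.60 keep their plurality
label but carry a low-confidence flag — retaining the label keeps accuracy
computation well defined while the flag marks candidates for
novel/ambiguous populations. Vote ties go to the nearest neighbor among
the tied classes; distance ties to the lower source index. The argmax of
the GCN softmax is exposed as an alternative (`transfer_mode="gcn"`); the
k-NN vote is the primary mode because it converges at many fewer epochs
and provides a natural confidence.

## Evaluation metrics

All metrics operate on the co-embedding and are invariant to rigid motion
and label renaming. `k_eval = 30` is the single neighborhood size used by
neighbor consistency and the alignment score.

- **Silhouette** `s(i) = (b−a)/max(a,b)` per cell (singletons 0), computed
  against modality labels (lower = better mixing) or cell-type labels
  (higher = better separation).
- **Silhouette F1** `2(1−s′_mod)s′_ct / ((1−s′_mod)+s′_ct)` with
  `s′ = (s̄+1)/2`: high only when modalities mix *and* types separate.
- **Cell-type ASW** `(s̄_ct+1)/2 ∈ [0,1]`.
- **Omics-layer ASW**: for each cell type containing both modalities, the
  mean of `1−|s_mod(i)|` within that type, averaged over qualifying types;
  types observed in a single modality are skipped (they cannot mix).
- **Neighbor consistency**: mean Jaccard overlap of each cell's k-NN sets
  in a single-omics embedding vs the integrated one.
- **FOSCTTM**: for ground-truth-paired cells, the fraction of cells closer
  than the true match, averaged both ways; 0 = perfect, ≈0.5 = random.
- **Seurat alignment score** `1 − (x̄ − k/D)/(k − k/D)` clipped to [0,1],
  with `x̄` the mean same-modality count among k nearest neighbors after
  subsampling modalities to equal size (seeded); `k/D` is the expected
  count under perfect mixing of D modalities.
- **Transfer accuracy / per-type F1**, restricted to cell types shared by
  both modalities.

## Synthetic data

The generator emulates the statistical skeleton of an unpaired two-modality
experiment: G ≥ 2 cell types as unit-variance Gaussian clusters around
centroids on a Δ-scaled simplex in a d = 10 latent space; each modality
observes cells through its own d × m loading matrix (target loadings = a
distorted copy of the source's, relative distortion 0.2); the target can
additionally carry a constant latent shift (systematic modality effect).
Features pass through additive Gaussian noise (sd 0.5), a softplus
(nonnegativity, in place of count sampling — keeps the pipeline smooth and
exactly reproducible), and Bernoulli dropout. Novel clusters can be
restricted to the target; a paired mode reuses identical latents for
FOSCTTM-style evaluation. Defaults: 300 cells per modality, 100 features,
3 clusters, Δ = 10.

Presets: `easy` (Δ = 10, no shift, no dropout), `noisy` (dropout 0.6),
`shifted` (latent shift 3.0), `novel-type` (one target-only cluster).

What passing on these scenarios does and does not show: linear loadings +
Gaussian clusters capture cluster geometry and systematic modality
offsets, but not count statistics, zero-inflation tied to expression
level, batch structure within a modality, or continuous trajectories.
Results here demonstrate the machinery recovers planted structure under
controlled distortions, not atlas-scale performance.

## Numerical choices and degenerate inputs

- Pairwise squared distances inside kernels are clamped at 0 to absorb
  cancellation error; the biased MMD may still be −1e-9 from rounding.
- Cosine normalization uses `max(‖x‖, 1e-9)`, exact for nonzero rows; the
  public loss rejects zero-norm rows outright.
- Cross-entropy clips probabilities to `[1e-12, 1−1e-12]` and requires
  rows to sum to 1 within 1e-6.
- Isolated graph nodes keep `Ã_ii = 1` through their self-loop; an empty
  graph normalizes to the identity.
- kNN ties everywhere resolve to the lower index (stable argsort), making
  every neighbor computation deterministic.
- Non-finite training losses abort immediately with a stage-tagged
  diagnostic rather than propagating NaNs.
- Problem sizes in the test and acceptance runs follow the generator
  defaults (300 + 300 cells, 100 features); they are desk-scale
  deliberately, since exact k-NN and a dense graph are O(n²).

## Known limitations

- Exact k-NN and dense adjacency bound practical size to ~10⁴ cells;
  approximate-NN backends are out of scope.
- Confidence is a raw vote fraction, not calibrated probability.
- The GCN receives no target-side supervision signal other than MMD; very
  small source datasets can underrepresent rare types, and types absent
  from the source can only be *flagged*, never named.
- CCA is linear; strongly nonlinear modality relationships rely entirely
  on the autoencoders and graph propagation downstream.
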