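# omicbridge

Transfer cell-type labels from annotated scRNA-seq data to unannotated
scATAC-seq data (via gene activity scores), treating unpaired multi-omics
integration as a domain-adaptation problem.

Single-cell chromatin accessibility data is hard to annotate directly:
signals are sparse and cell-type reference atlases are far richer on the
transcriptome side. `omicbridge` co-embeds a *labeled source* dataset
(cells × genes expression) and an *unlabeled target* dataset (cells × genes
activity, optionally aggregated from a peak matrix) and votes labels across
the shared space. It is aimed at computational biologists who have a
well-annotated expression reference and want consistent annotations — plus
confidence scores and candidate-novel-cell flags — for an accessibility
dataset from the same tissue.

## Method

1. **Shared projection.** Both matrices are restricted to common genes,
   library-size normalized and log-transformed, then co-projected by
   diagonal CCA: with per-gene standardized matrices `Z_s (n_s × m)` and
   `Z_t (n_t × m)`, the SVD `Z_s Z_tᵀ = U S Vᵀ` gives canonical coordinates
   `U√S`, `V√S` for source and target cells in one space.
2. **Hybrid graph.** Mutual nearest neighbors (MNN) in CCA space link
   source↔target cells (putative biological anchors) and source↔source
   cells; target↔target edges are deliberately absent, so information flows
   into the target only through the source. The adjacency is symmetrically
   normalized, `Ã = D^{-1/2}(A + I)D^{-1/2}`.
3. **Stage 1 — aligned autoencoders.** One sub-vector autoencoder per
   modality maps profiles to a shared K-dimensional latent space, trained
   with reconstruction loss plus multi-kernel maximum mean discrepancy
   (MK-MMD, Gaussian kernels `k_u(a,b) = exp(−‖a−b‖²/2σ_u²)` with convex
   weights) and a best-match cosine loss
   `1 − mean_t max_s cos(e_t, e_s)` pulling the two latent distributions
   together.
4. **Stage 2 — graph convolutional classifier.** A two-layer GCN
   `Ŷ = softmax(Ã · ReLU(Ã Z W⁰) · W¹)` over the hybrid graph is trained
   with cross-entropy on the labeled source nodes plus MK-MMD between the
   source and target hidden embeddings.
5. **Label transfer.** Each target cell takes the plurality vote of its
   k = 30 Euclidean-nearest source cells in the hidden embedding; the vote
   fraction is its confidence, and cells below 0.60 are flagged.

The package ships the standard integration metrics (silhouette
coefficients and their F1 combination, cell-type ASW, omics-layer ASW,
neighbor consistency, FOSCTTM, Seurat alignment score, transfer
accuracy/F1) and a synthetic two-modality generator, so the whole method is
testable end-to-end without external data. See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
import omicbridge as ob

from omicbridge.simulate import get_preset, simulate

src, src_labels, tgt, tgt_truth, _ = simulate(get_preset("easy", seed=1))
res = ob.run_pipeline(ob.RunConfig(seed=1), src, src_labels, tgt, tgt_truth)
print(f"accuracy {res.metrics['transfer_accuracy']:.3f}  "
      f"celltype_asw {res.metrics['celltype_asw']:.3f}  "
      f"silhouette_f1 {res.metrics['silhouette_f1']:.3f}")
```

prints

```
accuracy 1.000  celltype_asw 0.753  silhouette_f1 0.501
```

i.e. on the well-separated three-cluster scenario every target cell
receives its correct type (accuracy 1.0), cell types are cleanly resolved
in the co-embedding (cell-type ASW 0.75 on a 0–1 scale), and the silhouette
F1 reflects the trade-off between type separation and modality mixing.
The same pipeline is available from the shell:

```sh
omicbridge run --preset easy --seed 1 --outdir out/
omicbridge ablate --preset shifted --components mmd,cosine
```

writing `embedding.tsv`, `transfer.tsv` (cell, label, confidence, flag),
`metrics.json` and a reproducibility manifest; identical config + seed
reproduces all outputs bit for bit.

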