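"""Integration-quality metrics for co-embedded multi-omics data.

Six complementary indicators: silhouette coefficients (and their F1
combination balancing modality mixing against cell-type separation),
cell-type ASW, omics-layer ASW, neighbor consistency, FOSCTTM and the
Seurat alignment score — plus label-transfer accuracy with per-type F1.
All operate on a cells-by-K embedding with modality / cell-type labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import f1_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .io import LabelSet, TransferResult

__all__ = [
    "silhouette",
    "silhouette_f1",
    "celltype_asw",
    "omics_asw",
    "neighbor_consistency",
    "foscttm",
    "seurat_alignment_score",
    "transfer_accuracy",
    "evaluate_all",
]


def _as_labels(labels) -> np.ndarray:
    return np.asarray(labels)


def silhouette(embedding: np.ndarray, labels) -> tuple[np.ndarray, float]:
    """Per-cell silhouette s(i) = (b - a) / max(a, b) and its mean.

    a(i) is the mean intra-cluster distance (self excluded), b(i) the
    smallest mean distance to another cluster; singletons score 0.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = _as_labels(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two label classes")
    s = silhouette_samples(embedding, labels)
    return s, float(s.mean())


def _rescaled_mean_silhouette(embedding, labels) -> float:
    _, mean_s = silhouette(embedding, labels)
    return (mean_s + 1.0) / 2.0


def silhouette_f1(embedding: np.ndarray, modality_labels, celltype_labels) -> float:
    """Harmonic combination of modality mixing and cell-type separation.

    With s' the [0,1]-rescaled mean silhouette, returns
    2 (1 - s'_mod) s'_ct / ((1 - s'_mod) + s'_ct):  1 needs perfectly mixed
    modalities *and* perfectly separated cell types.
    """
    s_mod = _rescaled_mean_silhouette(embedding, modality_labels)
    s_ct = _rescaled_mean_silhouette(embedding, celltype_labels)
    num = 2.0 * (1.0 - s_mod) * s_ct
    den = (1.0 - s_mod) + s_ct
    return float(num / den) if den > 0 else 0.0


def celltype_asw(embedding: np.ndarray, celltype_labels) -> float:
    """Cell-type average silhouette width rescaled to [0, 1]."""
    return float(_rescaled_mean_silhouette(embedding, celltype_labels))


def omics_asw(embedding: np.ndarray, modality_labels, celltype_labels) -> float:
    """Omics-layer mixing score: mean over cell types (containing both
    modalities) of 1 - |modality silhouette| within that type; 1 = modalities
    indistinguishable inside every type."""
    embedding = np.asarray(embedding, dtype=float)
    modality_labels = _as_labels(modality_labels)
    celltype_labels = _as_labels(celltype_labels)
    per_type = []
    for ct in np.unique(celltype_labels):
        mask = celltype_labels == ct
        mods = modality_labels[mask]
        if len(np.unique(mods)) < 2:
            continue  # a type seen in one modality only cannot be mixed
        s = silhouette_samples(embedding[mask], mods)
        per_type.append(float(np.mean(1.0 - np.abs(s))))
    if not per_type:
        raise ValueError("no cell type contains both modalities")
    return float(np.mean(per_type))


def _knn_sets(embedding: np.ndarray, k: int) -> list[set[int]]:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    idx = nn.kneighbors(embedding, return_distance=False)
    out = []
    for i, row in enumerate(idx):
        neigh = [j for j in row if j != i][:k]
        out.append(set(neigh))
    return out


def neighbor_consistency(
    emb_single: np.ndarray, emb_integrated: np.ndarray, k: int = 30
) -> float:
    """Mean Jaccard overlap of k-NN sets before vs after integration."""
    emb_single = np.asarray(emb_single, dtype=float)
    emb_integrated = np.asarray(emb_integrated, dtype=float)
    n = emb_single.shape[0]
    if emb_integrated.shape[0] != n:
        raise ValueError("embeddings must cover the same cells")
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    nn_s = _knn_sets(emb_single, k)
    nn_i = _knn_sets(emb_integrated, k)
    jac = [
        len(a & b) / len(a | b) if a | b else 1.0 for a, b in zip(nn_s, nn_i)
    ]
    return float(np.mean(jac))


def foscttm(src_emb: np.ndarray, tgt_emb: np.ndarray) -> float:
    """Fraction of samples closer than the true match (paired rows).

    For each pair i, counts cells that sit closer to i's partner than the
    partner itself does, averaged both ways; 0 = perfect alignment,
    ~0.5 = random.
    """
    src_emb = np.atleast_2d(np.asarray(src_emb, dtype=float))
    tgt_emb = np.atleast_2d(np.asarray(tgt_emb, dtype=float))
    if src_emb.shape != tgt_emb.shape:
        raise ValueError("paired embeddings must have identical shape")
    n = src_emb.shape[0]
    d = cdist(src_emb, tgt_emb)
    true = np.diag(d)
    n1 = (d < true[None, :]).sum(axis=0)  # over j: d(x_j, y_i) < d(x_i, y_i)
    n2 = (d < true[:, None]).sum(axis=1)  # over j: d(x_i, y_j) < d(x_i, y_i)
    return float((n1.sum() / n + n2.sum() / n) / (2.0 * n))


def seurat_alignment_score(
    embedding: np.ndarray, modality_labels, k: int = 30, seed: int = 0
) -> float:
    """Alignment score: 1 - (xbar - k/D) / (k - k/D), clipped to [0, 1].

    xbar is the mean number of same-modality cells among each cell's k
    nearest neighbors after subsampling every modality to the smallest
    modality size; D is the number of modalities.  1 = ideal mixing,
    0 = fully separated modalities.
    """
    embedding = np.asarray(embedding, dtype=float)
    modality_labels = _as_labels(modality_labels)
    groups = np.unique(modality_labels)
    d_mod = len(groups)
    if d_mod < 2:
        raise ValueError("need at least two modalities")
    rng = np.random.default_rng(seed)
    n_min = min((modality_labels == g).sum() for g in groups)
    keep = np.concatenate(
        [
            rng.choice(np.where(modality_labels == g)[0], size=n_min, replace=False)
            for g in groups
        ]
    )
    emb, mods = embedding[keep], modality_labels[keep]
    if k >= len(keep):
        raise ValueError("k must be below the subsampled cell count")
    nn_sets = _knn_sets(emb, k)
    same = [sum(mods[j] == mods[i] for j in s) for i, s in enumerate(nn_sets)]
    xbar = float(np.mean(same))
    expected = k / d_mod
    sas = 1.0 - (xbar - expected) / (k - expected)
    return float(np.clip(sas, 0.0, 1.0))


def transfer_accuracy(
    pred: TransferResult,
    truth: LabelSet,
    shared_types: set[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Label-transfer accuracy over shared cell types, plus per-type F1.

    Cells whose true type is not shared between modalities are excluded from
    the accuracy denominator; F1 is the harmonic mean of precision and
    recall per type (0 where undefined).
    """
    y_true = truth.labels_for(pred.cell_ids)
    y_pred = np.asarray(pred.predicted_labels)
    if shared_types is None:
        shared_types = set(truth.classes)
    mask = np.isin(y_true, sorted(shared_types))
    if not mask.any():
        raise ValueError("no evaluable cells within the shared cell types")
    acc = float((y_true[mask] == y_pred[mask]).mean())
    types = sorted(shared_types)
    f1s = f1_score(y_true[mask], y_pred[mask], labels=types, average=None,
                   zero_division=0)
    table = pd.DataFrame({"cell_type": types, "f1": f1s})
    return acc, table


def evaluate_all(
    embedding: np.ndarray,
    modality_labels,
    celltype_labels,
    emb_single: np.ndarray | None = None,
    paired_src: np.ndarray | None = None,
    paired_tgt: np.ndarray | None = None,
    k_eval: int = 30,
    seed: int = 0,
) -> dict[str, float]:
    """All applicable metrics in one report (keys omitted when inputs are
    missing, e.g. FOSCTTM without a ground-truth pairing)."""
    _, s_mod = silhouette(embedding, modality_labels)
    _, s_ct = silhouette(embedding, celltype_labels)
    out = {
        "modality_silhouette": s_mod,
        "celltype_silhouette": s_ct,
        "silhouette_f1": silhouette_f1(embedding, modality_labels, celltype_labels),
        "celltype_asw": celltype_asw(embedding, celltype_labels),
        "omics_asw": omics_asw(embedding, modality_labels, celltype_labels),
        "seurat_alignment_score": seurat_alignment_score(
            embedding, modality_labels, k=k_eval, seed=seed
        ),
    }
    if emb_single is not None:
        out["neighbor_consistency"] = neighbor_consistency(
            emb_single, embedding, k=k_eval
        )
    if paired_src is not None and paired_tgt is not None:
        out["foscttm"] = foscttm(paired_src, paired_tgt)
    return out
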