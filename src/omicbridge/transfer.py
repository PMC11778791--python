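"""k-nearest-neighbor label transfer in the co-embedding space.

Each target cell takes the plurality vote of its k Euclidean-nearest source
cells (default k=30).  The vote fraction is the confidence; cells below the
confidence threshold (default 0.60) keep their plurality label but are
flagged as low-confidence candidates for novel or ambiguous types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import LabelSet, TransferResult

__all__ = ["knn_transfer", "novelty_report"]


def knn_transfer(
    src_emb: np.ndarray,
    src_labels: np.ndarray | LabelSet,
    tgt_emb: np.ndarray,
    k: int = 30,
    conf_threshold: float = 0.60,
    tgt_cell_ids: list[str] | None = None,
    src_cell_ids: list[str] | None = None,
) -> TransferResult:
    """Transfer labels from source to target cells by k-NN plurality vote.

    Distance ties are broken toward the lower source index; vote ties are
    broken by the label of the nearest neighbor among the tied classes.
    """
    src_emb = np.atleast_2d(np.asarray(src_emb, dtype=float))
    tgt_emb = np.atleast_2d(np.asarray(tgt_emb, dtype=float))
    if src_emb.shape[1] != tgt_emb.shape[1]:
        raise ValueError("embeddings must share dimensionality")
    n_s, n_t = src_emb.shape[0], tgt_emb.shape[0]
    if n_s == 0:
        raise ValueError("empty source embedding")
    if k > n_s:
        raise ValueError(f"k={k} exceeds the {n_s} source cells")
    if isinstance(src_labels, LabelSet):
        if src_cell_ids is None:
            raise ValueError("src_cell_ids required with a LabelSet")
        labels = src_labels.labels_for(list(src_cell_ids))
    else:
        labels = np.asarray(src_labels)
        if labels.shape[0] != n_s:
            raise ValueError("label count must match source cells")

    dist = cdist(tgt_emb, src_emb)
    # stable argsort => equal distances resolve to the lower source index
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]

    preds, confs = [], np.empty(n_t)
    for t in range(n_t):
        neigh = order[t]
        votes: dict[str, int] = {}
        for s in neigh:
            votes[labels[s]] = votes.get(labels[s], 0) + 1
        top = max(votes.values())
        tied = {lab for lab, v in votes.items() if v == top}
        if len(tied) == 1:
            (winner,) = tied
        else:  # label of the single nearest neighbor among tied classes
            winner = next(labels[s] for s in neigh if labels[s] in tied)
        preds.append(winner)
        confs[t] = top / k

    ids = list(tgt_cell_ids) if tgt_cell_ids is not None else [
        f"target_{i}" for i in range(n_t)
    ]
    return TransferResult(
        cell_ids=ids,
        predicted_labels=preds,
        confidences=confs,
        neighbor_indices=order,
        conf_threshold=conf_threshold,
    )


def novelty_report(result: TransferResult) -> pd.DataFrame:
    """Counts of confident vs flagged calls per predicted class.

    Rows sum to the number of target cells; flagged cells are candidates for
    types absent from (or ambiguous in) the source annotation.
    """
    if not result.cell_ids:
        return pd.DataFrame(columns=["predicted_label", "confident", "flagged"])
    df = pd.DataFrame(
        {
            "predicted_label": result.predicted_labels,
            "flagged": result.flag_low_confidence,
        }
    )
    out = (
        df.groupby("predicted_label")["flagged"]
        .agg(confident=lambda s: int((~s).sum()), flagged=lambda s: int(s.sum()))
        .reset_index()
    )
    return out
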