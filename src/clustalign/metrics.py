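"""Evaluation metrics: silhouette-based integration F1, annotation
precision/recall/F1, and the Adjusted Rand Index.

Integration quality trades off batch mixing against cell-type separation.
Both are measured with mean silhouette coefficients on the same embedding
(Euclidean distance, unweighted mean over cells), rescaled to [0, 1] via
s′ = (s + 1)/2, and combined as

    F1_sil = 2 · (1 − s′_batch) · s′_celltype / ((1 − s′_batch) + s′_celltype)

so a perfect score needs batches mixed (s_batch → −1) and cell types
separated (s_celltype → 1).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import (adjusted_rand_score,
                             precision_recall_fscore_support,
                             silhouette_score)


def _mean_silhouette(embedding: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 groups")
    return float(silhouette_score(embedding, labels, metric="euclidean"))


def silhouette_f1_from_scores(s_batch: float, s_celltype: float) -> float:
    """Combine the two mean silhouettes into the integration F1."""
    b = (s_batch + 1.0) / 2.0
    c = (s_celltype + 1.0) / 2.0
    denom = (1.0 - b) + c
    if denom == 0:
        return 0.0
    return 2.0 * (1.0 - b) * c / denom


def silhouette_f1(
    embedding: np.ndarray, batch_labels, type_labels
) -> tuple[float, float, float]:
    """(s_batch, s_celltype, F1) on one embedding.

    Low (ideally negative) batch silhouette and high cell-type silhouette
    both raise the F1.
    """
    s_batch = _mean_silhouette(embedding, batch_labels)
    s_type = _mean_silhouette(embedding, type_labels)
    return s_batch, s_type, silhouette_f1_from_scores(s_batch, s_type)


def annotation_metrics(truth_labels, predicted_labels) -> dict:
    """One-vs-rest precision/recall/F1 per class plus macro averages.

    Classes are those present in the truth; a class never predicted has
    precision 0 by convention.
    """
    truth = np.asarray(truth_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    classes = sorted(set(truth))
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, pred, labels=classes, zero_division=0
    )
    per_class = {
        c: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for c, p, r, f in zip(classes, prec, rec, f1)
    }
    return {
        "per_class": per_class,
        "macro_precision": float(prec.mean()),
        "macro_recall": float(rec.mean()),
        "macro_f1": float(f1.mean()),
    }


def adjusted_rand(labels1, labels2) -> float:
    """Chance-adjusted pair-counting agreement between two labelings."""
    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    if labels1.shape != labels2.shape:
        raise ValueError("labelings must have the same length")
    if labels1.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(labels1, labels2))
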