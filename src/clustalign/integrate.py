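"""Post-matching integration and reference-based cell-type annotation.

After clusters are matched, the cluster-anchored embedding update pulls the
joint CCA coordinates of matched clusters together:

    V₁′ = V₁ + αV₂(S−J)ᵀ        V₂′ = V₂ + αV₁(S−J)
    V₁″ = V₁′ + V₂′Sᵀ           V₂″ = V₂′ + V₁′S
    U₁′ = U₁ + C₁(V₁″−V₁)ᵀ      U₂′ = U₂ + C₂(V₂″−V₂)ᵀ
    E  = Uᵀ V   with U = L2([U₁′ᵀ, U₂′ᵀ]),  V = L2([V₁″, V₂″])

where J is the all-ones K₁×K₂ matrix and α regulates how far unmatched
clusters are repelled.  For a one-to-one matching the construction makes
the updated centroids of matched clusters exactly identical, so their
cells converge in the integrated embedding E.

Annotation transfers reference labels to a query dataset: the reference
partition is the given labeling, the query is clustered at a chosen
resolution, both are projected by CCA, and each query cluster adopts the
label of its highest-scoring reference cluster (or "unassigned" below a
score floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess
from .cca import DEFAULT_Q, fit_cca
from .containers import (CCAEmbedding, ExpressionMatrix, MatchResult,
                         OrthologMap, Partition)
from .modularity import louvain
from .representation import (DEGParams, build_cluster_repr, build_scores,
                             compute_epsilon)

DEFAULT_ALPHA = 0.5
UNASSIGNED = "unassigned"


@dataclass
class IntegratedEmbedding:
    """Joint cell × cluster correlation embedding E (rows: dataset-1 cells
    then dataset-2 cells; columns: dataset-1 clusters then dataset-2
    clusters)."""

    e: np.ndarray
    cell_ids: np.ndarray
    alpha: float
    u1_updated: np.ndarray
    u2_updated: np.ndarray
    v1_updated: np.ndarray
    v2_updated: np.ndarray


def _l2_columns(mat: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm column {int(zero[0])} in {what}")
    return mat / norms


def update_embeddings(
    u1: np.ndarray, u2: np.ndarray,
    v1: np.ndarray, v2: np.ndarray,
    match: MatchResult,
    p1: Partition, p2: Partition,
    alpha: float = DEFAULT_ALPHA,
    cell_ids: np.ndarray | None = None,
) -> IntegratedEmbedding:
    """Cluster-anchored update of cell and cluster embeddings.

    With a one-to-one matching the updated centroid columns of matched
    clusters coincide exactly for any α.
    """
    q = u1.shape[1]
    k1, k2 = v1.shape[1], v2.shape[1]
    if u2.shape[1] != q or v1.shape[0] != q or v2.shape[0] != q:
        raise ValueError("embedding dimension mismatch")
    if match.s.shape != (k1, k2):
        raise ValueError("matching shape does not fit the cluster counts")
    s = match.s.astype(float)
    j = np.ones_like(s)
    v1p = v1 + alpha * v2 @ (s - j).T
    v2p = v2 + alpha * v1 @ (s - j)
    v1pp = v1p + v2p @ s.T
    v2pp = v2p + v1p @ s
    c1, c2 = p1.indicator(), p2.indicator()
    u1p = u1 + c1 @ (v1pp - v1).T
    u2p = u2 + c2 @ (v2pp - v2).T
    u_cat = _l2_columns(np.hstack([u1p.T, u2p.T]), "cell embedding")
    v_cat = _l2_columns(np.hstack([v1pp, v2pp]), "cluster embedding")
    e = u_cat.T @ v_cat
    if cell_ids is None:
        cell_ids = np.arange(u1.shape[0] + u2.shape[0]).astype(str)
    return IntegratedEmbedding(e, np.asarray(cell_ids, dtype=object), alpha,
                               u1p, u2p, v1pp, v2pp)


def matched_marker_genes(deg1: list, deg2: list, match: MatchResult) -> dict:
    """Per matched pair (k₁, k₂): the intersection of both clusters' DEG
    sets — the markers the two datasets corroborate for that population."""
    return {(k1, k2): deg1[k1] & deg2[k2] for k1, k2 in match.pairs()}


@dataclass
class AnnotationResult:
    """Per-cell transferred labels plus the cluster-level assignment."""

    labels: pd.Series            # cell id → predicted label
    query_partition: Partition
    assignment: dict             # query cluster → (label, score)
    epsilon: float
    beta2: float


def labels_to_partition(labels) -> tuple[Partition, list]:
    """Turn per-cell labels into a partition (clusters ordered by first
    appearance of each label) and the label per cluster index."""
    seen: dict = {}
    idx = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
        idx.append(seen[lab])
    order = [lab for lab, _ in sorted(seen.items(), key=lambda kv: kv[1])]
    return Partition(np.asarray(idx), resolution=1.0), order


def transfer_labels(
    x_ref: ExpressionMatrix,
    ref_labels,
    x_query: ExpressionMatrix,
    lambda_query: float = 2.0,
    q: int = DEFAULT_Q,
    min_score: float = 0.0,
    n_hvg: int = preprocess.DEFAULT_N_HVG,
    n_pcs: int = preprocess.DEFAULT_N_PCS,
    k_snn: int = preprocess.DEFAULT_K,
    ortholog_map: OrthologMap | None = None,
    deg_params: DEGParams | None = None,
    seed: int = 0,
) -> AnnotationResult:
    """Annotate query cells from a labeled reference.

    The reference partition is the labeling itself; the query is clustered
    at ``lambda_query`` (default 2) on its SNN graph; both datasets are
    projected with CCA on the shared feature space, scored (ε from the mean
    embeddings, β₂ = max P / max J), and each query cluster takes the label
    of its best reference cluster, or "unassigned" when the best score is
    ≤ ``min_score``.
    """
    ref_labels = list(ref_labels)
    if len(ref_labels) != x_ref.n_cells:
        raise ValueError("one reference label per reference cell required")
    if len(set(ref_labels)) < 2:
        warnings.warn("single reference label: matching is degenerate")
    ln1 = normalize_if_raw(x_ref)
    ln2 = normalize_if_raw(x_query)
    ln1, ln2 = preprocess.shared_feature_space(ln1, ln2, ortholog_map, n_hvg)
    s1, s2 = preprocess.scale_genes(ln1), preprocess.scale_genes(ln2)
    p1, label_order = labels_to_partition(ref_labels)
    pcs2 = preprocess.run_pca(s2, min(n_pcs, s2.n_genes, s2.n_cells))
    g2 = preprocess.build_snn(pcs2, s2.cell_ids, k=min(k_snn, s2.n_cells - 1))
    p2 = louvain(g2, lambda_query, seed=seed)
    emb = fit_cca(s1, s2, min(q, s1.n_cells, s2.n_cells))
    r1 = build_cluster_repr(emb.u1, p1, ln1, deg_params)
    r2 = build_cluster_repr(emb.u2, p2, ln2, deg_params)
    sc = build_scores(r1, r2, compute_epsilon(emb))
    assignment = {}
    cell_labels = np.empty(x_query.n_cells, dtype=object)
    for k2 in range(p2.k):
        col = sc.combined[:, k2]
        best = int(col.argmax())
        if col[best] > min_score:
            lab = label_order[best]
        else:
            lab = UNASSIGNED
        assignment[k2] = (lab, float(col[best]))
        cell_labels[p2.labels == k2] = lab
    labels = pd.Series(cell_labels, index=pd.Index(x_query.cell_ids, name="cell"),
                       name="predicted_label")
    return AnnotationResult(labels, p2, assignment, sc.epsilon, sc.beta2)


def normalize_if_raw(x: ExpressionMatrix) -> ExpressionMatrix:
    return preprocess.normalize_counts(x) if x.stage == "raw" else x
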