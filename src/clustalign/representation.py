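"""Cluster representations and the cross-dataset score matrix.

Each cluster is represented twice: by the centroid of its cells in the joint
CCA space (V = UᵀCB, with B = diag(1/b₁,…,1/b_K)), and by its set of
positively differentially expressed genes from a Wilcoxon rank-sum test.
Centroid columns are compared across datasets with the Pearson correlation,
marker sets with the Jaccard coefficient, and the two are combined into the
matching score

    m_{k₁k₂} = max(P_{k₁k₂} + β₂ J_{k₁k₂} − ε, 0)

where ε — the noise floor — is the correlation between the two datasets'
mean cell embeddings, and β₂ balances embedding against marker evidence
(max P / max J in the final phase; 0 during the resolution search, where
marker detection would be recomputed at every grid point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (CCAEmbedding, ClusterRepr, ExpressionMatrix,
                         MatchResult, Partition, ScoreMatrix)


def cluster_centroids(u: np.ndarray, p: Partition) -> np.ndarray:
    """Q × K matrix whose column k is the mean embedding of cluster k."""
    if u.shape[0] != p.n_cells:
        raise ValueError("embedding rows must match partition cells")
    sizes = p.sizes
    if (sizes == 0).any():
        raise ValueError("empty cluster")
    sums = np.zeros((p.k, u.shape[1]))
    np.add.at(sums, p.labels, u)
    return (sums / sizes[:, None]).T


@dataclass
class DEGParams:
    """Thresholds for positive marker detection per cluster."""

    p_adj: float = 0.05      # Benjamini–Hochberg adjusted p-value cut
    lfc: float = 0.25        # log2 fold-change (cluster vs rest) lower bound
    min_pct: float = 0.10    # minimum in-cluster detection fraction
    min_cells: int = 3       # clusters below this size get an empty set


def deg_table(
    x: ExpressionMatrix, p: Partition, params: DEGParams | None = None
):
    """Per-cluster marker statistics as a tidy DataFrame.

    Columns: cluster, gene, adj_p, log2fc, pct_in — one row per gene that
    passes the thresholds in its cluster.  ``deg_sets`` is the set view of
    this table.
    """
    import pandas as pd

    if x.stage != "lognorm":
        raise ValueError("marker detection expects log-normalized data")
    if x.n_cells != p.n_cells:
        raise ValueError("matrix cells must match partition cells")
    params = params or DEGParams()
    rows = []
    expm = np.expm1(x.values)
    for k in range(p.k):
        mask = p.labels == k
        n_in = int(mask.sum())
        if n_in < params.min_cells or n_in == p.n_cells:
            warnings.warn(f"cluster {k} too small/large for DE testing; empty set")
            continue
        xin, xout = x.values[:, mask], x.values[:, ~mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(xin, xout, axis=1, alternative="two-sided")
            pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        padj = multipletests(pvals, method="fdr_bh")[1]
        lfc = np.log2(expm[:, mask].mean(axis=1) + 1.0) - np.log2(
            expm[:, ~mask].mean(axis=1) + 1.0
        )
        pct = (xin > 0).mean(axis=1)
        keep = (padj < params.p_adj) & (lfc > params.lfc) & (pct >= params.min_pct)
        for i in np.flatnonzero(keep):
            rows.append({"cluster": k, "gene": str(x.gene_ids[i]),
                         "adj_p": float(padj[i]), "log2fc": float(lfc[i]),
                         "pct_in": float(pct[i])})
    return pd.DataFrame(rows, columns=["cluster", "gene", "adj_p", "log2fc",
                                       "pct_in"])


def deg_sets(
    x: ExpressionMatrix, p: Partition, params: DEGParams | None = None
) -> list:
    """Per-cluster positively differentially expressed gene sets.

    For every cluster, each gene's log-normalized values in the cluster are
    compared against all other cells with a two-sided Wilcoxon rank-sum
    (Mann–Whitney) test; genes pass with BH-adjusted p < ``p_adj``,
    log2 fold-change of mean back-transformed expression > ``lfc``, and
    in-cluster detection fraction ≥ ``min_pct``.
    """
    table = deg_table(x, p, params)
    return [set(table.gene[table.cluster == k]) for k in range(p.k)]


def build_cluster_repr(
    u: np.ndarray, p: Partition, x: ExpressionMatrix | None = None,
    params: DEGParams | None = None,
) -> ClusterRepr:
    """Bundle centroid and marker-set representations for one dataset."""
    degs = deg_sets(x, p, params) if x is not None else [set()] * p.k
    return ClusterRepr(cluster_centroids(u, p), degs, p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        warnings.warn("zero-variance vector in Pearson correlation; using 0")
        return 0.0
    return float(a @ b / (na * nb))


def pearson_matrix(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of centroid columns (K₁ × K₂)."""
    if v1.shape[0] != v2.shape[0]:
        raise ValueError("centroid matrices must share the embedding dimension")
    if v1.shape[0] < 2:
        raise ValueError("need at least 2 embedding dimensions for correlation")
    a = v1 - v1.mean(axis=0)
    b = v2 - v2.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    if (na == 0).any() or (nb == 0).any():
        warnings.warn("zero-variance centroid column; correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (a.T @ b) / np.outer(na, nb)
    out[np.isnan(out)] = 0.0
    return np.clip(out, -1.0, 1.0)


def jaccard_matrix(sets1: list, sets2: list) -> np.ndarray:
    """Pairwise Jaccard overlap of marker-gene sets (both empty → 0)."""
    out = np.zeros((len(sets1), len(sets2)))
    for i, e1 in enumerate(sets1):
        for j, e2 in enumerate(sets2):
            union = len(e1 | e2)
            out[i, j] = len(e1 & e2) / union if union else 0.0
    return out


def compute_epsilon(e: CCAEmbedding) -> float:
    """Noise floor ε: correlation of the two datasets' mean cell embeddings."""
    return _pearson(e.u1.mean(axis=0), e.u2.mean(axis=0))


def compute_beta2(pearson: np.ndarray, jaccard: np.ndarray) -> float:
    """β₂ = max(P) / max(J); 0 when no marker set overlaps at all."""
    max_j = float(jaccard.max(initial=0.0))
    if max_j == 0:
        warnings.warn("all-zero Jaccard matrix; beta2 = 0 (Pearson-only match)")
        return 0.0
    return float(pearson.max()) / max_j


def combined_scores(
    pearson: np.ndarray, jaccard: np.ndarray, beta2: float, epsilon: float
) -> np.ndarray:
    """m = (P + β₂ J − ε)₊ elementwise."""
    if pearson.shape != jaccard.shape:
        raise ValueError("score matrices must share a shape")
    return np.maximum(pearson + beta2 * jaccard - epsilon, 0.0)


def build_scores(
    repr1: ClusterRepr, repr2: ClusterRepr, epsilon: float,
    beta2: float | None = None,
) -> ScoreMatrix:
    """Assemble the full score matrix; ``beta2=None`` → max P / max J."""
    p = pearson_matrix(repr1.centroids, repr2.centroids)
    j = jaccard_matrix(repr1.deg_sets, repr2.deg_sets)
    if beta2 is None:
        beta2 = compute_beta2(p, j)
    return ScoreMatrix(p, j, combined_scores(p, j, beta2, epsilon), epsilon, beta2)


def compute_beta3(s: MatchResult, combined: np.ndarray) -> float:
    """Cluster-count penalty weight from the current matching.

    Reading of a typographically damaged printed formula: with M = Σ s the
    number of matched pairs, β₃ = ((M − 1)/M) × mean combined score of the
    matched pairs — "the average correlation of the paired clusters",
    vanishing for a single match.  Returns 0 for an empty matching.
    """
    m_total = s.n_matches
    if m_total == 0:
        return 0.0
    matched_sum = float((s.s * combined).sum())
    return (m_total - 1) / m_total * (matched_sum / m_total)
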