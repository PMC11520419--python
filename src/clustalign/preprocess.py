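"""Normalization, feature selection, scaling, PCA and SNN-graph construction.

The stages mirror the standard single-cell workflow: library-size
log-normalization, highly-variable-gene (HVG) selection by standardized
variance, per-gene z-scaling with clipping, PCA, and a shared-nearest-neighbor
graph weighted by the Jaccard overlap of k-neighborhoods.  Two datasets are
put on a shared feature space by intersecting their HVG lists, optionally
after translating one dataset's genes through an ortholog map.

Conventions (stated once): sample (n−1) variance throughout; z-scaling clips
at ±10; SNN neighborhoods include the cell itself; SNN edges below 1/15 are
pruned.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from scipy import sparse

from .containers import ExpressionMatrix, OrthologMap, SNNGraph

DEFAULT_SCALE_FACTOR = 1e4
DEFAULT_CLIP = 10.0
DEFAULT_N_HVG = 2000
DEFAULT_N_PCS = 50
DEFAULT_K = 20
DEFAULT_PRUNE = 1.0 / 15.0


def normalize_counts(
    x: ExpressionMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ExpressionMatrix:
    """Library-size normalize and log-transform raw counts.

    value_gc = log(1 + count_gc / colsum_c × scale_factor), natural log.
    """
    if x.stage != "raw":
        raise ValueError(f"normalize_counts expects raw counts, got {x.stage}")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    colsums = x.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(f"all-zero cell(s): {list(x.cell_ids[zero[:5]])}")
    vals = np.log1p(x.values / colsums * scale_factor)
    return ExpressionMatrix(vals, x.gene_ids, x.cell_ids, x.batch_id, "lognorm")


def _standardized_variance(vals: np.ndarray) -> np.ndarray:
    """Per-gene variance standardized by a degree-2 mean–variance trend.

    A polynomial in log10(mean) is fitted to log10(variance) over genes with
    positive mean and variance; each gene's variance is divided by the trend's
    prediction.  Falls back to raw variance when too few genes support a fit.
    """
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        return var
    lm, lv = np.log10(mean[ok]), np.log10(var[ok])
    deg = min(2, len(np.unique(lm)) - 1)
    coef = np.polyfit(lm, lv, deg=deg)
    std_var = np.zeros_like(var)
    expected = 10.0 ** np.polyval(coef, np.log10(mean[ok]))
    std_var[ok] = var[ok] / expected
    return std_var


def select_hvgs(
    x: ExpressionMatrix, n: int = DEFAULT_N_HVG, method: str = "standardized"
) -> list:
    """Top-``n`` highly variable genes, ties broken by gene id.

    ``method`` is ``"standardized"`` (variance over a fitted mean–variance
    trend) or ``"raw"`` (plain per-gene variance).
    """
    if x.stage != "lognorm":
        raise ValueError("select_hvgs expects log-normalized data")
    if not 0 < n <= x.n_genes:
        raise ValueError(f"n={n} out of range for {x.n_genes} genes")
    if x.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate variance")
    if method == "standardized":
        score = _standardized_variance(x.values)
    elif method == "raw":
        score = x.values.var(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown HVG method {method!r}")
    order = sorted(range(x.n_genes), key=lambda i: (-score[i], str(x.gene_ids[i])))
    return [x.gene_ids[i] for i in order[:n]]


def scale_genes(
    x: ExpressionMatrix,
    genes: Optional[Sequence[str]] = None,
    clip_max: float = DEFAULT_CLIP,
) -> ExpressionMatrix:
    """Z-scale each retained gene to mean 0 / unit sample variance, clipped.

    Zero-variance rows become all-zero rather than NaN.
    """
    if x.stage != "lognorm":
        raise ValueError("scale_genes expects log-normalized data")
    if genes is not None:
        if len(genes) == 0:
            raise ValueError("empty gene list")
        x = x.subset_genes(genes)
    mean = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (x.values - mean) / sd
    vals[np.broadcast_to(sd == 0, vals.shape)] = 0.0
    vals = np.clip(vals, -clip_max, clip_max)
    return ExpressionMatrix(vals, x.gene_ids, x.cell_ids, x.batch_id, "scaled")


def translate_genes(x: ExpressionMatrix, omap: OrthologMap) -> ExpressionMatrix:
    """Rename ``x``'s genes into the partner namespace via an ortholog map.

    One-to-one orthologs are renamed; when several source genes map to one
    target (one2many / many2many groups) their expression rows are averaged.
    Genes absent from the map are dropped.
    """
    targets: dict[str, list[int]] = {}
    index = {g: i for i, g in enumerate(x.gene_ids)}
    for src, tgt in omap.pairs:
        if src in index:
            targets.setdefault(tgt, []).append(index[src])
    if not targets:
        raise ValueError("ortholog map shares no genes with the dataset")
    names = sorted(targets)
    rows = np.stack([x.values[targets[t]].mean(axis=0) for t in names])
    return ExpressionMatrix(rows, np.asarray(names, dtype=object),
                            x.cell_ids, x.batch_id, x.stage)


def shared_feature_space(
    x1: ExpressionMatrix,
    x2: ExpressionMatrix,
    ortholog_map: Optional[OrthologMap] = None,
    n_hvg: int = DEFAULT_N_HVG,
    hvg_method: str = "standardized",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both log-normalized datasets to intersecting HVGs.

    ``x2`` is first translated through ``ortholog_map`` when given (so that
    cross-species runs share a namespace), then each dataset's top-``n_hvg``
    HVG list is computed and both matrices are cut to the intersection in a
    common order (dataset-1 HVG rank order).
    """
    if ortholog_map is not None:
        x2 = translate_genes(x2, ortholog_map)
    n1, n2 = min(n_hvg, x1.n_genes), min(n_hvg, x2.n_genes)
    hvg1 = select_hvgs(x1, n1, hvg_method)
    hvg2 = set(select_hvgs(x2, n2, hvg_method))
    shared = [g for g in hvg1 if g in hvg2]
    if not shared:
        raise ValueError(
            f"no shared highly variable genes ({n1} vs {n2} per-dataset HVGs)"
        )
    return x1.subset_genes(shared), x2.subset_genes(shared)


def run_pca(x: ExpressionMatrix, n_pcs: int = DEFAULT_N_PCS) -> np.ndarray:
    """Cells × n_pcs principal-component embedding of a z-scaled matrix.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-|loading| gene weight is positive.
    """
    if x.stage != "scaled":
        raise ValueError("run_pca expects z-scaled data")
    if not 0 < n_pcs <= min(x.n_genes, x.n_cells):
        raise ValueError(f"n_pcs={n_pcs} out of range for {x.n_genes}×{x.n_cells}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(x.values.T)
    flip = np.sign(pca.components_[np.arange(n_pcs),
                                   np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return emb * flip


def build_snn(
    embedding: np.ndarray,
    cell_ids: Sequence[str],
    k: int = DEFAULT_K,
    prune: float = DEFAULT_PRUNE,
) -> SNNGraph:
    """Shared-nearest-neighbor graph over an embedding.

    Edge weight a_ij is the Jaccard overlap of the two cells' k-nearest
    neighborhoods (self included); entries below ``prune`` are dropped and
    the diagonal is zeroed.
    """
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"need more cells ({n}) than neighbors (k={k})")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    idx = nn.kneighbors(embedding, return_distance=False)
    rows = np.repeat(np.arange(n), k)
    b = sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (b @ b.T).toarray()
    union = 2.0 * k - inter
    with np.errstate(invalid="ignore"):
        jac = inter / union
    jac[union == 0] = 1.0
    jac[jac < prune] = 0.0
    np.fill_diagonal(jac, 0.0)
    return SNNGraph(jac, np.asarray(list(cell_ids), dtype=object))
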