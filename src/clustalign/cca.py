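"""Shared-space projection by SVD of the expression cross-product.

Both z-scaled datasets (genes matched, identical order) are projected into a
common Q-dimensional space by maximizing tr(U₁ᵀ X₁ᵀX₂ U₂) subject to
unit-norm columns — the left/right singular vectors of the N₁ × N₂
cross-product K = X₁ᵀX₂, with objective value Σ of the top-Q singular
values.  This is the cross-product trace formulation (no inverse-covariance
whitening of classical CCA).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.utils.extmath import randomized_svd

from .containers import CCAEmbedding, ExpressionMatrix

DEFAULT_Q = 20
# above this cross-product dimension a randomized truncated SVD is used
# (agreement with the dense route ~1e-8 at the default iteration count)
DENSE_SVD_LIMIT = 3000


def _standardize_cells(vals: np.ndarray) -> np.ndarray:
    """Standardize each cell's profile (column) to mean 0, unit variance."""
    mean = vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (vals - mean) / sd


def fit_cca(
    x1: ExpressionMatrix, x2: ExpressionMatrix, q: int = DEFAULT_Q,
    standardize_cells: bool = True,
) -> CCAEmbedding:
    """Top-q singular triplets of K = X₁ᵀX₂ as a joint embedding.

    By default each cell's profile is standardized across genes before the
    cross-product.  This matters beyond numerics: on per-gene centered
    input every row and column of X₁ᵀX₂ sums to exactly zero, so all
    singular vectors have exactly zero mean and the downstream noise floor
    ε (a correlation of mean embeddings) would be undefined — per-cell
    standardization keeps the grand-mean direction in the cross-product
    and makes ε a meaningful baseline.

    Columns of u1/u2 are unit-norm with a deterministic sign convention:
    the largest-|entry| element of each u1 column is positive, and the u2
    column flips with it (the objective is invariant to paired flips).
    """
    if x1.n_genes != x2.n_genes or not np.array_equal(x1.gene_ids, x2.gene_ids):
        raise ValueError("datasets must share an identical gene order")
    if not 0 < q <= min(x1.n_cells, x2.n_cells):
        raise ValueError(f"q={q} out of range for {x1.n_cells}×{x2.n_cells} cells")
    a, b = x1.values, x2.values
    if standardize_cells:
        a, b = _standardize_cells(a), _standardize_cells(b)
    k = a.T @ b
    if max(k.shape) <= DENSE_SVD_LIMIT:
        u, s, vt = linalg.svd(k, full_matrices=False)
        u, s, vt = u[:, :q], s[:q], vt[:q]
    else:
        u, s, vt = randomized_svd(k, n_components=q, n_iter=10, random_state=0)
    u1, u2 = u, vt.T
    anchor = np.abs(u1).argmax(axis=0)
    flip = np.sign(u1[anchor, np.arange(q)])
    flip[flip == 0] = 1.0
    return CCAEmbedding(u1 * flip, u2 * flip, s.copy())
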