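"""Core data containers shared across the pipeline.

The pipeline operates on gene × cell expression matrices at three stages
(raw counts, log-normalized, z-scaled), shared-nearest-neighbor cell graphs,
resolution-parameterized partitions, a joint CCA embedding, per-cluster
representations (centroid + marker-gene set), cross-dataset score matrices,
and binary cluster matchings.  Containers are plain dataclasses with cheap
invariant checks at construction; heavy numerics live in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

Stage = Literal["raw", "lognorm", "scaled"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        uniq, counts = np.unique(ids, return_counts=True)
        dup = uniq[counts > 1][:5]
        raise ValueError(f"duplicated {what}: {list(dup)}")


@dataclass
class ExpressionMatrix:
    """Genes × cells expression matrix with identifiers and a processing stage.

    ``values`` is dense float64, oriented genes in rows, cells in columns.
    ``stage`` tracks where the matrix sits in the normalize → scale pipeline;
    operations check it so a z-scaled matrix cannot be normalized twice.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    batch_id: str = ""
    stage: Stage = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes × cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "cell id")
        if self.stage == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        rows = np.array([index[g] for g in genes], dtype=int)
        return ExpressionMatrix(
            self.values[rows], np.asarray(list(genes), dtype=object),
            self.cell_ids, self.batch_id, self.stage,
        )


@dataclass
class SNNGraph:
    """Symmetric weighted cell–cell graph (shared-nearest-neighbor Jaccard).

    Stores the dense weight matrix ``weights`` (zero diagonal), per-node
    degrees d_i = Σ_j a_ij and total edge weight m = ½ΣΣ a_ij.
    """

    weights: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n = len(self.cell_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match cell count")
        if self.weights.size:
            if not np.allclose(self.weights, self.weights.T, atol=1e-12):
                raise ValueError("weights must be symmetric")
            if self.weights.min() < 0:
                raise ValueError("weights must be non-negative")
            np.fill_diagonal(self.weights, 0.0)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """m = ½ ΣΣ a_ij."""
        return float(self.weights.sum()) / 2.0


@dataclass
class Partition:
    """Cluster assignment at resolution λ.

    Labels are 0-based and contiguous; clusters are non-empty.
    """

    labels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.labels.size:
            if self.labels.min() < 0:
                raise ValueError("labels must be non-negative")
            k = self.labels.max() + 1
            sizes = np.bincount(self.labels, minlength=k)
            if (sizes == 0).any():
                raise ValueError("labels must be contiguous (no empty cluster)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def sizes(self) -> np.ndarray:
        """Cluster sizes b_k."""
        return np.bincount(self.labels, minlength=self.k)

    def indicator(self) -> np.ndarray:
        """Binary N × K membership matrix C."""
        c = np.zeros((self.n_cells, self.k))
        c[np.arange(self.n_cells), self.labels] = 1.0
        return c


@dataclass
class OrthologMap:
    """Gene homology pairs (source → target) with a relation class per pair."""

    pairs: list  # of (source_gene, target_gene)
    relation: list  # of {"one2one", "one2many", "many2many"} per pair

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.relation):
            raise ValueError("pairs and relation lengths differ")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicated ortholog pair")
        bad = set(self.relation) - {"one2one", "one2many", "many2many"}
        if bad:
            raise ValueError(f"unknown relation classes: {bad}")


@dataclass
class CCAEmbedding:
    """Joint low-dimensional embedding from the cross-product SVD.

    ``u1`` (N₁ × Q) and ``u2`` (N₂ × Q) hold unit-norm canonical vectors;
    ``singular_values`` are the top-Q singular values of X₁ᵀX₂ in
    non-increasing order, whose sum is the achieved objective tr(U₁ᵀX₁ᵀX₂U₂).
    """

    u1: np.ndarray
    u2: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self) -> None:
        if self.u1.shape[1] != self.u2.shape[1]:
            raise ValueError("u1 and u2 must have the same number of columns")
        if len(self.singular_values) != self.u1.shape[1]:
            raise ValueError("singular value count must equal Q")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")

    @property
    def q(self) -> int:
        return self.u1.shape[1]

    @property
    def objective(self) -> float:
        return float(self.singular_values.sum())


@dataclass
class ClusterRepr:
    """Dual cluster representation: CCA centroid + marker-gene set.

    ``centroids`` is Q × K with column k the mean embedding of cluster k's
    cells (V = UᵀCB); ``deg_sets`` holds one marker-gene set per cluster.
    """

    centroids: np.ndarray
    deg_sets: list
    partition: Partition

    def __post_init__(self) -> None:
        if self.centroids.shape[1] != self.partition.k:
            raise ValueError("centroid count must equal cluster count")
        if len(self.deg_sets) != self.partition.k:
            raise ValueError("one DEG set per cluster required")


@dataclass
class ScoreMatrix:
    """Cross-dataset cluster similarity scores.

    ``combined`` = max(pearson + β₂·jaccard − ε, 0) elementwise; ε is the
    noise floor and β₂ balances embedding versus marker-set evidence.
    """

    pearson: np.ndarray
    jaccard: np.ndarray
    combined: np.ndarray
    epsilon: float
    beta2: float

    def __post_init__(self) -> None:
        if not (self.pearson.shape == self.jaccard.shape == self.combined.shape):
            raise ValueError("score matrices must share a shape")
        if self.beta2 < 0:
            raise ValueError("beta2 must be non-negative")


@dataclass
class MatchResult:
    """Binary cluster–cluster matching under per-cluster capacity t."""

    s: np.ndarray
    t: int
    algorithm: str
    scores: Optional[ScoreMatrix] = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s)
        if not np.isin(self.s, (0, 1)).all():
            raise ValueError("matching entries must be 0/1")
        self.s = self.s.astype(np.int8)
        if self.t < 1:
            raise ValueError("capacity t must be ≥ 1")
        if self.s.size and (
            self.s.sum(axis=1).max(initial=0) > self.t
            or self.s.sum(axis=0).max(initial=0) > self.t
        ):
            raise ValueError("capacity constraint violated")

    @property
    def n_matches(self) -> int:
        return int(self.s.sum())

    def pairs(self) -> list:
        """Matched (k1, k2) index pairs in row-major order."""
        return [tuple(p) for p in np.argwhere(self.s == 1)]
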