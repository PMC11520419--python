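"""Outer optimization: resolution search and the end-to-end alignment.

The full objective couples, for a candidate resolution pair (λ₁, λ₂):

    total = Q₁(λ₁) + Q₂(λ₂) + tr(U₁ᵀX₁ᵀX₂U₂)
            + β₁ Σ s_{k₁k₂} m_{k₁k₂} − β₃ Σ s_{k₁k₂}

i.e. per-dataset generalized modularity, the (λ-independent) CCA term, a
reward for high-scoring matched cluster pairs (β₁ = 60), and a penalty on
the match count that keeps the resolutions from inflating the cluster
number.  The search phase sweeps a resolution grid with a cheap schedule
(β₂ = 0 — no marker detection per grid point; β₃ re-derived from each
candidate matching); the final phase re-clusters at the selected
resolutions with the full schedule (markers on, β₂ = max P / max J,
β₃ = 0) and produces the matching, matched markers and the integrated
embedding.

Grid geometry: the default explores the full Cartesian product
{λ⁰+ih} × {λ⁰+jh}; ``diagonal_only`` restricts to the literal diagonal walk
λ₁, λ₂ incremented together.  The full grid is enumerated by default; with
``early_stop`` the sweep ends once the running best total has not improved
for ``patience`` consecutive grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import preprocess
from .cca import DEFAULT_Q, fit_cca
from .containers import (CCAEmbedding, ExpressionMatrix, MatchResult,
                         OrthologMap, Partition, ScoreMatrix)
from .integrate import (IntegratedEmbedding, matched_marker_genes,
                        update_embeddings)
from .matching import check_stability, gale_shapley, mnn_match
from .modularity import generalized_modularity, louvain
from .representation import (DEGParams, build_cluster_repr, build_scores,
                             cluster_centroids, combined_scores,
                             compute_beta3, compute_epsilon, pearson_matrix)

DEFAULT_BETA1 = 60.0


@dataclass
class SearchConfig:
    """Knobs of the resolution search and alignment pipeline."""

    lambda_start: tuple = (0.2, 0.2)
    step: float = 0.2
    n_iter: int = 15
    q: int = DEFAULT_Q
    t: int = 1
    solver: str = "mnn"              # or "gale_shapley"
    seed: int = 0
    beta1: float = DEFAULT_BETA1
    diagonal_only: bool = False
    early_stop: bool = False
    patience: int = 3
    # preprocessing
    n_hvg: int = preprocess.DEFAULT_N_HVG
    n_pcs: int = preprocess.DEFAULT_N_PCS
    k_snn: int = preprocess.DEFAULT_K
    prune: float = preprocess.DEFAULT_PRUNE
    scale_factor: float = preprocess.DEFAULT_SCALE_FACTOR
    hvg_method: str = "standardized"
    # final phase
    alpha: float = 0.5
    min_score: Optional[float] = None
    deg_params: DEGParams = field(default_factory=DEGParams)

    def __post_init__(self) -> None:
        if min(self.lambda_start) <= 0 or self.step <= 0 or self.n_iter < 1:
            raise ValueError("grid must be positive with at least one point")
        if self.solver not in ("mnn", "gale_shapley"):
            raise ValueError(f"unknown solver {self.solver!r}")

    def grid(self) -> list:
        l1 = [self.lambda_start[0] + i * self.step for i in range(self.n_iter)]
        l2 = [self.lambda_start[1] + i * self.step for i in range(self.n_iter)]
        if self.diagonal_only:
            return list(zip(l1, l2))
        return [(a, b) for a in l1 for b in l2]


@dataclass
class AlignmentResult:
    """Everything the aligned pair produces."""

    lambda_opt: tuple
    partitions: tuple            # (Partition, Partition)
    embedding: CCAEmbedding
    reprs: tuple                 # (ClusterRepr, ClusterRepr)
    scores: ScoreMatrix
    match: MatchResult
    objective_trace: pd.DataFrame
    matched_markers: dict
    integrated: IntegratedEmbedding
    config: SearchConfig

    def matching_table(self) -> pd.DataFrame:
        """Edge list of the alignment graph with per-pair evidence."""
        rows = []
        comb = self.scores.combined
        for k1, k2 in self.match.pairs():
            mutual_best = bool(
                comb[k1, k2] == comb[k1].max() == comb[:, k2].max()
                and comb[k1, k2] > 0
            )
            rows.append({
                "cluster1": k1, "cluster2": k2,
                "pearson": self.scores.pearson[k1, k2],
                "jaccard": self.scores.jaccard[k1, k2],
                "combined": comb[k1, k2],
                "mutual_best": "yes" if mutual_best else "no",
            })
        return pd.DataFrame(
            rows, columns=["cluster1", "cluster2", "pearson", "jaccard",
                           "combined", "mutual_best"])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matching_table().to_csv(outdir / "matching.tsv", sep="\t", index=False)
        for i, (p, r) in enumerate(zip(self.partitions, self.reprs), start=1):
            pd.DataFrame({
                "cell_id": self.embedding_cell_ids(i),
                "cluster": p.labels,
            }).to_csv(outdir / f"partition_{i}.tsv", sep="\t", index=False)
        self.objective_trace.to_csv(outdir / "objective_trace.tsv", sep="\t", index=False)
        rows = [{"cluster1": k1, "cluster2": k2, "gene": g}
                for (k1, k2), genes in sorted(self.matched_markers.items())
                for g in sorted(genes)]
        pd.DataFrame(rows, columns=["cluster1", "cluster2", "gene"]).to_csv(
            outdir / "matched_markers.tsv", sep="\t", index=False)
        emb = pd.DataFrame(self.integrated.e)
        emb.insert(0, "cell_id", self.integrated.cell_ids)
        emb.to_csv(outdir / "integrated_embedding.tsv", sep="\t", index=False)

    def embedding_cell_ids(self, dataset: int) -> np.ndarray:
        n1 = self.embedding.u1.shape[0]
        if dataset == 1:
            return self.integrated.cell_ids[:n1]
        return self.integrated.cell_ids[n1:]


def objective_value(
    g1, g2, p1: Partition, p2: Partition, cca_term: float,
    combined: np.ndarray, match: MatchResult,
    beta1: float, beta3: float,
) -> dict:
    """All components of the coupled objective at one grid point."""
    q1 = generalized_modularity(g1, p1, p1.resolution)
    q2 = generalized_modularity(g2, p2, p2.resolution)
    match_term = beta1 * float((match.s * combined).sum())
    penalty = beta3 * match.n_matches
    return {
        "lambda1": p1.resolution, "lambda2": p2.resolution,
        "k1": p1.k, "k2": p2.k,
        "modularity1": q1, "modularity2": q2,
        "cca_term": cca_term,
        "match_term": match_term, "penalty": penalty,
        "total": q1 + q2 + cca_term + match_term - penalty,
    }


def _louvain_seeds(seed: int) -> tuple:
    """One derived sub-seed, shared by both graphs: identical graphs then
    yield identical partitions (self-alignment symmetry)."""
    sub = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    return (sub, sub)


def _solve_matching(combined: np.ndarray, cfg: SearchConfig,
                    scores: ScoreMatrix | None = None) -> MatchResult:
    if cfg.solver == "gale_shapley":
        return gale_shapley(combined, scores, min_score=cfg.min_score)
    return mnn_match(combined, cfg.t, scores)


class _PartitionCache:
    """Louvain partitions and centroids per (graph, λ), seeded per graph."""

    def __init__(self, graphs, embeddings, seeds):
        self.graphs = graphs
        self.embeddings = embeddings
        self.seeds = seeds
        self._parts: dict = {}
        self._cents: dict = {}

    def partition(self, l: int, lam: float) -> Partition:
        key = (l, round(lam, 12))
        if key not in self._parts:
            self._parts[key] = louvain(self.graphs[l], lam, seed=self.seeds[l])
        return self._parts[key]

    def centroids(self, l: int, lam: float) -> np.ndarray:
        key = (l, round(lam, 12))
        if key not in self._cents:
            self._cents[key] = cluster_centroids(
                self.embeddings[l], self.partition(l, lam))
        return self._cents[key]


def search_resolutions(
    g1, g2, emb: CCAEmbedding, cfg: SearchConfig,
    cache: _PartitionCache | None = None,
):
    """Sweep the resolution grid under the search-phase schedule.

    Returns (λ₁*, λ₂*, trace DataFrame).  The CCA term and ε are fixed for
    the whole sweep; each grid point clusters both graphs (cached per λ),
    scores centroid correlations, solves the matching with β₂ = 0, derives
    β₃ from that matching and records the objective.
    """
    if cache is None:
        cache = _PartitionCache((g1, g2), (emb.u1, emb.u2),
                                _louvain_seeds(cfg.seed))
    cca_term = emb.objective
    eps = compute_epsilon(emb)
    records = []
    best_total, since_best = -np.inf, 0
    for lam1, lam2 in cfg.grid():
        p1 = cache.partition(0, lam1)
        p2 = cache.partition(1, lam2)
        pmat = pearson_matrix(cache.centroids(0, lam1), cache.centroids(1, lam2))
        comb = combined_scores(pmat, np.zeros_like(pmat), 0.0, eps)
        match = _solve_matching(comb, cfg)
        beta3 = compute_beta3(match, comb)
        rec = objective_value(g1, g2, p1, p2, cca_term, comb, match,
                              cfg.beta1, beta3)
        records.append(rec)
        if rec["total"] > best_total + 1e-12:
            best_total, since_best = rec["total"], 0
        else:
            since_best += 1
            if cfg.early_stop and since_best >= cfg.patience:
                break
    trace = pd.DataFrame(records)
    best = trace["total"].idxmax()
    return (trace.loc[best, "lambda1"], trace.loc[best, "lambda2"]), trace


def align(
    x1_raw: ExpressionMatrix,
    x2_raw: ExpressionMatrix,
    cfg: SearchConfig | None = None,
    ortholog_map: OrthologMap | None = None,
) -> AlignmentResult:
    """Full pipeline: preprocess → resolution search → final alignment.

    The final phase re-uses the cached partitions at the selected
    resolutions, detects per-cluster markers on the log-normalized shared
    feature space, switches the schedule to β₂ = max P / max J and β₃ = 0,
    solves the final matching, intersects the matched clusters' marker
    sets, and integrates the embeddings.
    """
    cfg = cfg or SearchConfig()
    ln1 = preprocess.normalize_counts(x1_raw, cfg.scale_factor) \
        if x1_raw.stage == "raw" else x1_raw
    ln2 = preprocess.normalize_counts(x2_raw, cfg.scale_factor) \
        if x2_raw.stage == "raw" else x2_raw
    ln1, ln2 = preprocess.shared_feature_space(
        ln1, ln2, ortholog_map, cfg.n_hvg, cfg.hvg_method)
    s1, s2 = preprocess.scale_genes(ln1), preprocess.scale_genes(ln2)
    graphs = []
    for s in (s1, s2):
        pcs = preprocess.run_pca(s, min(cfg.n_pcs, s.n_genes, s.n_cells))
        graphs.append(preprocess.build_snn(
            pcs, s.cell_ids, k=min(cfg.k_snn, s.n_cells - 1), prune=cfg.prune))
    g1, g2 = graphs
    emb = fit_cca(s1, s2, min(cfg.q, s1.n_cells, s2.n_cells))
    cache = _PartitionCache((g1, g2), (emb.u1, emb.u2),
                            _louvain_seeds(cfg.seed))
    (lam1, lam2), trace = search_resolutions(g1, g2, emb, cfg, cache)
    p1, p2 = cache.partition(0, lam1), cache.partition(1, lam2)
    r1 = build_cluster_repr(emb.u1, p1, ln1, cfg.deg_params)
    r2 = build_cluster_repr(emb.u2, p2, ln2, cfg.deg_params)
    sc = build_scores(r1, r2, compute_epsilon(emb))
    match = _solve_matching(sc.combined, cfg, sc)
    markers = matched_marker_genes(r1.deg_sets, r2.deg_sets, match)
    cell_ids = np.concatenate([
        np.char.add(f"{x1_raw.batch_id or 'd1'}:", s1.cell_ids.astype(str)),
        np.char.add(f"{x2_raw.batch_id or 'd2'}:", s2.cell_ids.astype(str)),
    ]).astype(object)
    integrated = update_embeddings(
        emb.u1, emb.u2, r1.centroids, r2.centroids, match, p1, p2,
        alpha=cfg.alpha, cell_ids=cell_ids)
    return AlignmentResult((lam1, lam2), (p1, p2), emb, (r1, r2), sc, match,
                           trace, markers, integrated, cfg)


def rematch(
    result: AlignmentResult,
    epsilon: float | None = None,
    beta2: float | None = None,
    t: int | None = None,
    solver: str | None = None,
    alpha: float | None = None,
) -> AlignmentResult:
    """Re-solve the final matching of a completed alignment with overridden
    schedule constants (noise floor ε, evidence weight β₂, capacity t,
    solver, update strength α), reusing the cached partitions, embeddings
    and marker sets.  This is the workhorse of hyperparameter sensitivity
    sweeps: everything upstream of the matching is fixed, so the sweep
    isolates the constant under study.
    """
    cfg = replace(result.config,
                  t=result.config.t if t is None else t,
                  solver=result.config.solver if solver is None else solver,
                  alpha=result.config.alpha if alpha is None else alpha)
    r1, r2 = result.reprs
    sc = build_scores(
        r1, r2,
        result.scores.epsilon if epsilon is None else epsilon,
        beta2=result.scores.beta2 if beta2 is None else beta2)
    match = _solve_matching(sc.combined, cfg, sc)
    markers = matched_marker_genes(r1.deg_sets, r2.deg_sets, match)
    integrated = update_embeddings(
        result.embedding.u1, result.embedding.u2,
        r1.centroids, r2.centroids, match,
        result.partitions[0], result.partitions[1],
        alpha=cfg.alpha, cell_ids=result.integrated.cell_ids)
    return AlignmentResult(result.lambda_opt, result.partitions,
                           result.embedding, result.reprs, sc, match,
                           result.objective_trace, markers, integrated, cfg)


def chain_align(
    datasets: Sequence[ExpressionMatrix],
    cfg: SearchConfig | None = None,
    ortholog_maps: Optional[Sequence[Optional[OrthologMap]]] = None,
) -> list:
    """Align consecutive datasets of an ordered series pairwise.

    ``ortholog_maps[i]`` (when given) translates dataset i+1 into dataset
    i's gene namespace for the (i, i+1) alignment — e.g. the cross-species
    step at the end of a developmental series.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to chain")
    if ortholog_maps is None:
        ortholog_maps = [None] * (len(datasets) - 1)
    if len(ortholog_maps) != len(datasets) - 1:
        raise ValueError("need one ortholog map slot per consecutive pair")
    return [
        align(datasets[i], datasets[i + 1], cfg, ortholog_maps[i])
        for i in range(len(datasets) - 1)
    ]
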