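"""Synthetic paired scRNA-seq batches with planted, known structure.

The generator emulates the regimes the aligner must handle: two batches
sharing a subset of cell types, optional batch-private types (a population
present in only one batch must not be matched), per-type marker-gene blocks,
optional two-level subtypes (to exercise the multi-scale resolution search),
an additive per-gene batch effect on the log-mean (a technical shift the
shared-space projection should absorb), and optional "confounded" markers
elevated in one whole batch (the over-correction trap).

Counts follow a gamma–Poisson (negative-binomial) model: gene g in cell i
has mean

    μ_gi = exp(base_g + effect·marker_g(type_i) + subeffect·marker_g(sub_i)
               + shift_g·[batch 2] + log lib_i)

with gamma noise of shape ``dispersion`` and a final Poisson draw.  All
randomness flows from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ExpressionMatrix


@dataclass
class SimConfig:
    """Generative settings; the defaults are the study conditions used
    throughout the tests: 1000 genes, ~800 cells per batch, 6 shared plus
    one private type per batch, 20 markers per type at an e^1.5 ≈ 4.5-fold
    effect, moderate overdispersion and a mild additive batch effect."""

    n_genes: int = 1000
    n_cells: int = 800               # per batch
    n_shared_types: int = 6
    n_private_per_batch: int = 1
    markers_per_type: int = 20
    marker_strength: float = 1.5     # natural-log fold change on markers
    subtype_split_types: int = 0     # leading shared types given 2 subtypes
    subtype_markers: int = 10
    subtype_strength: float = 0.8
    dispersion: float = 10.0         # gamma shape; larger = closer to Poisson
    batch_effect_scale: float = 0.3  # sd of the per-gene additive log shift
    confounded_markers: int = 0      # genes strongly elevated in batch 2 only
    confounded_strength: float = 1.5
    libsize_sigma: float = 0.2       # log-normal library-size spread
    base_mean_loc: float = float(np.log(0.2))
    base_mean_scale: float = 1.0


@dataclass
class SimTruth:
    """Ground truth of a simulated pair."""

    type_of_cell: tuple              # (batch-1 array, batch-2 array)
    subtype_of_cell: tuple
    shared_types: list
    private_types: tuple             # (batch-1 list, batch-2 list)
    marker_genes: dict               # type/subtype name → set of gene ids
    subtype_tree: dict               # type → list of subtype names
    batch_shift: np.ndarray
    seed: int


def simulate_pair(
    cfg: SimConfig | None = None, seed: int = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Draw a pair of raw count matrices with known correspondence."""
    cfg = cfg or SimConfig()
    if cfg.n_shared_types < 1 or cfg.n_shared_types + cfg.n_private_per_batch < 2:
        raise ValueError("need at least 2 types with at least 1 shared")
    rng = np.random.default_rng(seed)

    shared = [f"T{i}" for i in range(cfg.n_shared_types)]
    priv1 = [f"P1_{i}" for i in range(cfg.n_private_per_batch)]
    priv2 = [f"P2_{i}" for i in range(cfg.n_private_per_batch)]
    all_types = shared + priv1 + priv2

    subtype_tree: dict = {}
    sub_names: list = []
    for t in shared[: cfg.subtype_split_types]:
        subs = [f"{t}a", f"{t}b"]
        subtype_tree[t] = subs
        sub_names.extend(subs)

    n_marker_blocks = len(all_types) * cfg.markers_per_type \
        + len(sub_names) * cfg.subtype_markers + cfg.confounded_markers
    if n_marker_blocks > cfg.n_genes:
        raise ValueError(
            f"marker demand ({n_marker_blocks} genes) exceeds n_genes={cfg.n_genes}")

    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    marker_genes: dict = {}
    cursor = 0
    type_effect = {}
    for t in all_types:
        block = np.arange(cursor, cursor + cfg.markers_per_type)
        cursor += cfg.markers_per_type
        marker_genes[t] = {str(g) for g in genes[block]}
        eff = np.zeros(cfg.n_genes)
        eff[block] = cfg.marker_strength
        type_effect[t] = eff
    sub_effect = {}
    for s in sub_names:
        block = np.arange(cursor, cursor + cfg.subtype_markers)
        cursor += cfg.subtype_markers
        marker_genes[s] = {str(g) for g in genes[block]}
        eff = np.zeros(cfg.n_genes)
        eff[block] = cfg.subtype_strength
        sub_effect[s] = eff
    confounded = np.arange(cursor, cursor + cfg.confounded_markers)

    base = rng.normal(cfg.base_mean_loc, cfg.base_mean_scale, size=cfg.n_genes)
    batch_shift = rng.normal(0.0, cfg.batch_effect_scale, size=cfg.n_genes)
    batch_shift[confounded] += cfg.confounded_strength

    def _draw_batch(batch: int, types_here: list):
        n_types = len(types_here)
        counts_per = np.full(n_types, cfg.n_cells // n_types)
        counts_per[: cfg.n_cells % n_types] += 1
        type_lab = np.repeat(types_here, counts_per)
        sub_lab = np.array([
            rng.choice(subtype_tree[t]) if t in subtype_tree else ""
            for t in type_lab
        ], dtype=object)
        lib = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=cfg.n_cells))
        logmu = np.tile(base[:, None], (1, cfg.n_cells))
        for j, (t, s) in enumerate(zip(type_lab, sub_lab)):
            logmu[:, j] += type_effect[t]
            if s:
                logmu[:, j] += sub_effect[s]
        if batch == 2:
            logmu += batch_shift[:, None]
        mu = np.exp(logmu) * lib
        lam = rng.gamma(cfg.dispersion, mu / cfg.dispersion)
        counts = rng.poisson(lam).astype(np.float64)
        cells = np.array([f"b{batch}_c{j:04d}" for j in range(cfg.n_cells)],
                         dtype=object)
        return counts, cells, type_lab, sub_lab

    c1, cells1, t1, s1 = _draw_batch(1, shared + priv1)
    c2, cells2, t2, s2 = _draw_batch(2, shared + priv2)
    x1 = ExpressionMatrix(c1, genes.copy(), cells1, batch_id="batch1")
    x2 = ExpressionMatrix(c2, genes.copy(), cells2, batch_id="batch2")
    truth = SimTruth((t1, t2), (s1, s2), shared, (priv1, priv2),
                     marker_genes, subtype_tree, batch_shift, seed)
    return x1, x2, truth


def simulate_reference_query(
    cfg: SimConfig | None = None, seed: int = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Reference/query pair for the annotation scenario.

    Defaults model a labeled-reference transfer setting: four well-separated
    cell types (distinct neuronal classes rather than subtly different
    subtypes), all present in both datasets, no batch-private population.
    Batch 1 plays the annotated reference, batch 2 the unlabeled query.
    """
    if cfg is None:
        cfg = SimConfig(n_shared_types=4, n_private_per_batch=0,
                        marker_strength=2.0)
    return simulate_pair(cfg, seed=seed)


def expected_matching(truth: SimTruth) -> dict:
    """Ground-truth cluster correspondence between the two batches.

    ``edges`` pairs each shared type (and each shared subtype) with itself
    across batches; ``isolated`` lists the batch-private populations that
    must stay unmatched.
    """
    edges = [(t, t) for t in truth.shared_types]
    sub_edges = [(s, s) for subs in truth.subtype_tree.values() for s in subs]
    return {
        "edges": edges,
        "subtype_edges": sub_edges,
        "isolated": list(truth.private_types[0]) + list(truth.private_types[1]),
    }


def majority_types(labels: np.ndarray, true_types: np.ndarray) -> dict:
    """Dominant true type of each cluster label."""
    out = {}
    for k in np.unique(labels):
        vals, counts = np.unique(true_types[labels == k], return_counts=True)
        out[int(k)] = str(vals[counts.argmax()])
    return out


def match_recovery(result, truth: SimTruth) -> dict:
    """Score an alignment against the planted correspondence.

    A shared-type edge counts as recovered when some matched cluster pair
    has that type dominant on both sides.  ``cross_type_mutual_best``
    counts mutual-best pairs whose dominant types differ, and
    ``private_in_mutual_best`` flags a batch-private population appearing
    in a mutual-best pair — both must be 0 for a clean alignment.
    """
    p1, p2 = result.partitions
    maj1 = majority_types(p1.labels, truth.type_of_cell[0])
    maj2 = majority_types(p2.labels, truth.type_of_cell[1])
    table = result.matching_table()
    matched_type_pairs = {
        (maj1[int(r.cluster1)], maj2[int(r.cluster2)])
        for r in table.itertuples()
    }
    expected = expected_matching(truth)
    recovered = [e for e in expected["edges"] if e in matched_type_pairs]
    best = table[table.mutual_best == "yes"]
    cross = sum(
        maj1[int(r.cluster1)] != maj2[int(r.cluster2)] for r in best.itertuples())
    private = set(expected["isolated"])
    private_hit = sum(
        maj1[int(r.cluster1)] in private or maj2[int(r.cluster2)] in private
        for r in best.itertuples())
    return {
        "n_expected_edges": len(expected["edges"]),
        "n_recovered_edges": len(recovered),
        "recovery_rate": len(recovered) / len(expected["edges"]),
        "cross_type_mutual_best": int(cross),
        "private_in_mutual_best": int(private_hit),
    }
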