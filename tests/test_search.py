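import numpy as np
import pytest

from clustalign import (MatchResult, Partition, SearchConfig, SNNGraph, align,
                        chain_align, check_stability, generalized_modularity,
                        mnn_match, objective_value, simulate_pair)
from clustalign.containers import ScoreMatrix

from conftest import ring_graph, small_sim_config


def fast_cfg(seed=0, **kw):
    base = dict(lambda_start=(0.4, 0.4), step=0.3, n_iter=4, n_hvg=200,
                n_pcs=20, q=10, seed=seed)
    base.update(kw)
    return SearchConfig(**base)


class TestObjectiveValue:
    def _parts(self, n):
        return Partition(np.array([0] * (n // 2) + [1] * (n - n // 2)),
                         resolution=1.0)

    def test_empty_matching_reduces_to_modularities_plus_cca(self):
        g = ring_graph(6)
        p = self._parts(6)
        match = MatchResult(np.zeros((2, 2), dtype=int), 1, "mnn")
        rec = objective_value(g, g, p, p, cca_term=3.5,
                              combined=np.zeros((2, 2)), match=match,
                              beta1=60.0, beta3=0.0)
        q = generalized_modularity(g, p, 1.0)
        assert rec["total"] == pytest.approx(2 * q + 3.5)

    def test_beta1_scales_match_term_only(self, rng):
        g = ring_graph(6)
        p = self._parts(6)
        comb = rng.random((2, 2))
        match = mnn_match(comb, 1)
        a = objective_value(g, g, p, p, 1.0, comb, match, beta1=60, beta3=0.1)
        b = objective_value(g, g, p, p, 1.0, comb, match, beta1=120, beta3=0.1)
        assert b["match_term"] == pytest.approx(2 * a["match_term"])
        assert b["penalty"] == pytest.approx(a["penalty"])

    def test_total_matches_term_by_term_sum(self, rng):
        g = ring_graph(8)
        p = self._parts(8)
        comb = rng.random((2, 2))
        match = mnn_match(comb, 1)
        rec = objective_value(g, g, p, p, 2.0, comb, match, 60.0, 0.3)
        manual = (generalized_modularity(g, p, 1.0) * 2 + 2.0
                  + 60.0 * float((match.s * comb).sum())
                  - 0.3 * match.n_matches)
        assert rec["total"] == pytest.approx(manual, abs=1e-9)


class TestAlign:
    @pytest.fixture(scope="class")
    def aligned_small(self):
        x1, x2, truth = simulate_pair(small_sim_config(), seed=7)
        return align(x1, x2, fast_cfg(seed=7)), truth

    def test_single_point_grid_returns_that_point(self):
        x1, x2, _ = simulate_pair(small_sim_config(), seed=1)
        res = align(x1, x2, fast_cfg(seed=1, lambda_start=(1.0, 1.0), n_iter=1))
        assert res.lambda_opt == (1.0, 1.0)
        assert len(res.objective_trace) == 1

    def test_self_alignment_is_symmetric_bijection(self):
        """Identical datasets have ε = 1 exactly, so the search term is flat
        and only the final-phase marker evidence separates pairs; at any
        resolution with K > 1 the matching must be the identity bijection."""
        x1, _, _ = simulate_pair(small_sim_config(), seed=2)
        res = align(x1, x1, fast_cfg(seed=2, lambda_start=(1.0, 1.0), n_iter=1))
        l1, l2 = res.lambda_opt
        assert l1 == l2
        p1, p2 = res.partitions
        np.testing.assert_array_equal(p1.labels, p2.labels)
        # every cluster matches itself with the maximal score of its row
        assert res.match.pairs() == [(k, k) for k in range(p1.k)]
        comb = res.scores.combined
        for k in range(p1.k):
            assert comb[k, k] == pytest.approx(comb[k].max())

    def test_cca_term_constant_across_grid(self, aligned_small):
        res, _ = aligned_small
        assert res.objective_trace["cca_term"].nunique() == 1

    def test_trace_totals_recomputable(self, aligned_small):
        res, _ = aligned_small
        tr = res.objective_trace
        manual = (tr.modularity1 + tr.modularity2 + tr.cca_term
                  + tr.match_term - tr.penalty)
        np.testing.assert_allclose(tr.total, manual, atol=1e-9)

    def test_optimum_attains_trace_maximum(self, aligned_small):
        res, _ = aligned_small
        tr = res.objective_trace
        best = tr.loc[tr.total.idxmax()]
        assert (best.lambda1, best.lambda2) == res.lambda_opt

    def test_final_matching_respects_mutual_criterion(self, aligned_small):
        res, _ = aligned_small
        again = mnn_match(res.scores.combined, res.config.t)
        np.testing.assert_array_equal(res.match.s, again.s)

    def test_gale_shapley_solver_final_match_stable(self):
        x1, x2, _ = simulate_pair(small_sim_config(), seed=3)
        res = align(x1, x2, fast_cfg(seed=3, solver="gale_shapley"))
        ok, blocking = check_stability(res.match, res.scores.combined)
        assert ok, blocking

    def test_matched_markers_subset_of_both_deg_sets(self, aligned_small):
        res, _ = aligned_small
        for (k1, k2), genes in res.matched_markers.items():
            assert genes <= res.reprs[0].deg_sets[k1]
            assert genes <= res.reprs[1].deg_sets[k2]

    def test_removing_a_type_breaks_its_match(self):
        """Ablation: dropping every cell of one shared type from dataset 2
        leaves that type's dataset-1 cluster without a same-type match."""
        from clustalign import ExpressionMatrix
        from clustalign.simulate import majority_types
        x1, x2, truth = simulate_pair(small_sim_config(), seed=4)
        keep = truth.type_of_cell[1] != "T0"
        x2_ablate = ExpressionMatrix(x2.values[:, keep], x2.gene_ids,
                                     x2.cell_ids[keep], x2.batch_id)
        res = align(x1, x2_ablate, fast_cfg(seed=4))
        maj1 = majority_types(res.partitions[0].labels, truth.type_of_cell[0])
        maj2 = majority_types(res.partitions[1].labels,
                              truth.type_of_cell[1][keep])
        pairs = {(maj1[k1], maj2[k2]) for k1, k2 in res.match.pairs()}
        assert ("T0", "T0") not in pairs


class TestChain:
    def test_three_copies_give_self_bijections(self):
        x1, _, _ = simulate_pair(small_sim_config(), seed=5)
        results = chain_align([x1, x1, x1],
                              fast_cfg(seed=5, lambda_start=(1.0, 1.0), n_iter=1))
        assert len(results) == 2
        for res in results:
            assert res.match.pairs() == [(k, k)
                                         for k in range(res.partitions[0].k)]

    def test_two_datasets_equal_single_align(self):
        x1, x2, _ = simulate_pair(small_sim_config(), seed=6)
        single = align(x1, x2, fast_cfg(seed=6))
        chained = chain_align([x1, x2], fast_cfg(seed=6))[0]
        np.testing.assert_array_equal(single.match.s, chained.match.s)
        np.testing.assert_array_equal(single.partitions[0].labels,
                                      chained.partitions[0].labels)

    def test_too_few_datasets(self):
        x1, _, _ = simulate_pair(small_sim_config(), seed=6)
        with pytest.raises(ValueError, match="at least 2"):
            chain_align([x1])
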