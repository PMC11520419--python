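import numpy as np
import pytest

from clustalign import (CCAEmbedding, DEGParams, ExpressionMatrix, MatchResult,
                        Partition, cluster_centroids, combined_scores,
                        compute_beta2, compute_beta3, compute_epsilon,
                        deg_sets, jaccard_matrix, pearson_matrix)


def make_partition(labels):
    return Partition(np.asarray(labels), resolution=1.0)


class TestCentroids:
    def test_one_cell_per_cluster(self, rng):
        u = rng.normal(size=(4, 3))
        v = cluster_centroids(u, make_partition([2, 0, 3, 1]))
        np.testing.assert_allclose(v[:, 2], u[0])
        np.testing.assert_allclose(v[:, 0], u[1])

    def test_matches_loop_mean(self, rng):
        u = rng.normal(size=(50, 6))
        labels = rng.integers(0, 5, size=50)
        labels = np.unique(labels, return_inverse=True)[1]
        v = cluster_centroids(u, make_partition(labels))
        for k in range(labels.max() + 1):
            np.testing.assert_allclose(v[:, k], u[labels == k].mean(axis=0),
                                       atol=1e-12)

    def test_identical_cells_identical_centroids(self):
        u = np.tile([1.0, -2.0, 0.5], (6, 1))
        v = cluster_centroids(u, make_partition([0, 0, 1, 1, 2, 2]))
        for k in range(3):
            np.testing.assert_allclose(v[:, k], [1.0, -2.0, 0.5])


class TestDEG:
    def _lognorm(self, vals):
        g, n = vals.shape
        return ExpressionMatrix(vals, [f"g{i}" for i in range(g)],
                                [f"c{i}" for i in range(n)], stage="lognorm")

    def test_all_or_none_gene_found_only_in_its_cluster(self):
        n_in, n_out = 20, 40
        vals = np.ones((3, n_in + n_out)) * 0.5
        vals[0, :n_in] = 3.0   # marker of cluster 0
        vals[0, n_in:] = 0.0
        labels = np.array([0] * n_in + [1] * n_out)
        sets = deg_sets(self._lognorm(vals), make_partition(labels))
        assert "g0" in sets[0]
        assert "g0" not in sets[1]

    def test_constant_gene_nowhere(self):
        vals = np.ones((2, 30))
        vals[1, :10] = 2.0
        labels = np.array([0] * 10 + [1] * 20)
        sets = deg_sets(self._lognorm(vals), make_partition(labels))
        assert all("g0" not in s for s in sets)

    def test_planted_markers_recovered(self):
        """≥4/5 planted marker genes recovered at default thresholds in
        each of 10 seeded replicates."""
        hits = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            vals = local.exponential(0.3, size=(40, 60))
            vals[:5, :20] += 2.0   # 5 markers of cluster 0
            labels = np.array([0] * 20 + [1] * 40)
            sets = deg_sets(self._lognorm(vals), make_partition(labels))
            hits.append(len({f"g{i}" for i in range(5)} & sets[0]))
        assert all(h >= 4 for h in hits)

    def test_permutation_invariance(self, rng):
        vals = rng.exponential(0.5, size=(20, 40))
        vals[:3, :15] += 1.5
        labels = np.array([0] * 15 + [1] * 25)
        x = self._lognorm(vals)
        base = deg_sets(x, make_partition(labels))
        perm = rng.permutation(40)
        xp = ExpressionMatrix(vals[:, perm], x.gene_ids,
                              [f"c{i}" for i in perm], stage="lognorm")
        permuted = deg_sets(xp, make_partition(labels[perm]))
        assert base == permuted

    def test_tiny_cluster_gives_empty_set_with_warning(self):
        vals = np.random.default_rng(0).random((5, 10))
        labels = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="too small"):
            sets = deg_sets(self._lognorm(vals), make_partition(labels))
        assert sets[1] == set()


class TestScores:
    def test_pearson_hand_values(self):
        v1 = np.array([[1.0], [0.0], [0.0]])
        v2 = np.array([[0.0], [1.0], [0.0]])
        assert pearson_matrix(v1, v2)[0, 0] == pytest.approx(-0.5)
        v = np.array([[1.0], [2.0], [3.0]])
        assert pearson_matrix(v, v)[0, 0] == pytest.approx(1.0)
        assert pearson_matrix(v, v[::-1])[0, 0] == pytest.approx(-1.0)

    def test_pearson_diagonal_and_affine_invariance(self, rng):
        v = rng.normal(size=(6, 4))
        p = pearson_matrix(v, v)
        np.testing.assert_allclose(np.diag(p), 1.0, atol=1e-12)
        scaled = v * 3.0 + 2.0
        np.testing.assert_allclose(pearson_matrix(v, scaled), p, atol=1e-10)

    def test_pearson_zero_variance_column(self):
        v1 = np.ones((3, 1))
        v2 = np.array([[1.0], [2.0], [3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            assert pearson_matrix(v1, v2)[0, 0] == 0.0

    def test_jaccard_values(self):
        s1 = [{"A", "B", "C"}, set()]
        s2 = [{"B", "C", "D"}, set(), {"A", "B", "C"}]
        j = jaccard_matrix(s1, s2)
        assert j[0, 0] == pytest.approx(0.5)
        assert j[0, 2] == pytest.approx(1.0)
        assert j[1, 1] == 0.0   # empty vs empty, by convention

    def test_epsilon_direct_recomputation(self, rng):
        u1 = rng.normal(size=(30, 5))
        u2 = rng.normal(size=(40, 5))
        emb = CCAEmbedding(u1, u2, np.sort(rng.random(5))[::-1])
        m1, m2 = u1.mean(axis=0), u2.mean(axis=0)
        expected = np.corrcoef(m1, m2)[0, 1]
        assert compute_epsilon(emb) == pytest.approx(expected, abs=1e-12)

    def test_epsilon_extremes(self, rng):
        u = rng.normal(size=(10, 4))
        sv = np.sort(rng.random(4))[::-1]
        assert compute_epsilon(CCAEmbedding(u, u.copy(), sv)) == pytest.approx(1.0)
        mean_flip = np.tile([1.0, 2.0, 3.0], (5, 1))
        rev = np.tile([3.0, 2.0, 1.0], (5, 1))
        emb = CCAEmbedding(mean_flip, rev, np.array([1.0, 0.5, 0.2]))
        assert compute_epsilon(emb) == pytest.approx(-1.0)

    def test_beta2(self, rng):
        p = np.array([[0.9, 0.1], [0.2, 0.3]])
        j = np.array([[0.45, 0.0], [0.1, 0.2]])
        assert compute_beta2(p, j) == pytest.approx(2.0)
        assert compute_beta2(j, j) == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="Jaccard"):
            assert compute_beta2(p, np.zeros((2, 2))) == 0.0

    def test_combined_clamps_and_schedules(self):
        p = np.array([[0.8, 0.1]])
        j = np.array([[0.5, 0.05]])
        out = combined_scores(p, j, beta2=1.0, epsilon=0.3)
        np.testing.assert_allclose(out, [[1.0, 0.0]])
        # β₂ = 0 reduces to (P − ε)₊, the search-phase schedule
        np.testing.assert_allclose(
            combined_scores(p, j, 0.0, 0.3), np.maximum(p - 0.3, 0))

    def test_combined_monotone_in_epsilon(self, rng):
        p, j = rng.random((4, 5)), rng.random((4, 5))
        lo = combined_scores(p, j, 1.0, 0.2)
        hi = combined_scores(p, j, 1.0, 0.5)
        assert (hi <= lo + 1e-12).all()
        assert (lo >= 0).all()


class TestBeta3:
    def _match(self, s):
        return MatchResult(np.asarray(s), t=1, algorithm="mnn")

    def test_single_match_is_zero(self):
        m = np.array([[0.8]])
        assert compute_beta3(self._match([[1]]), m) == 0.0

    def test_two_matches_hand_value(self):
        s = [[1, 0], [0, 1]]
        m = np.array([[0.6, 0.0], [0.0, 1.0]])
        assert compute_beta3(self._match(s), m) == pytest.approx(0.4)

    def test_uniform_closed_form(self):
        s = np.eye(4, dtype=int)
        m = np.full((4, 4), 0.7)
        assert compute_beta3(self._match(s), m) == pytest.approx(0.7 * 3 / 4)

    def test_empty_matching(self):
        assert compute_beta3(self._match(np.zeros((2, 2))), np.zeros((2, 2))) == 0.0
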