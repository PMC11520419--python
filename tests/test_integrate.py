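import numpy as np
import pandas as pd
import pytest

from clustalign import (ExpressionMatrix, MatchResult, Partition, SimConfig,
                        annotation_metrics, matched_marker_genes,
                        simulate_pair, transfer_labels, update_embeddings)
from clustalign.simulate import simulate_reference_query


def random_setup(rng, n1=12, n2=15, k1=3, k2=3, q=4):
    u1 = rng.normal(size=(n1, q))
    u2 = rng.normal(size=(n2, q))
    v1 = rng.normal(size=(q, k1))
    v2 = rng.normal(size=(q, k2))
    p1 = Partition(np.resize(np.arange(k1), n1), resolution=1.0)
    p2 = Partition(np.resize(np.arange(k2), n2), resolution=1.0)
    return u1, u2, v1, v2, p1, p2


class TestUpdateEmbeddings:
    def test_single_matched_pair_centroids_coincide(self, rng):
        u1, u2, v1, v2, p1, p2 = random_setup(rng, k1=1, k2=1)
        match = MatchResult(np.array([[1]]), 1, "mnn")
        out = update_embeddings(u1, u2, v1, v2, match, p1, p2, alpha=0.7)
        np.testing.assert_allclose(out.v1_updated, out.v2_updated, atol=1e-12)
        np.testing.assert_allclose(out.v1_updated, v1 + v2, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.5, 1.0])
    def test_matched_columns_identical_for_any_permutation(self, rng, alpha):
        u1, u2, v1, v2, p1, p2 = random_setup(rng, k1=4, k2=4)
        s = np.zeros((4, 4), dtype=int)
        s[np.arange(4), rng.permutation(4)] = 1
        match = MatchResult(s, 1, "mnn")
        out = update_embeddings(u1, u2, v1, v2, match, p1, p2, alpha=alpha)
        for k1, k2 in match.pairs():
            diff = np.abs(out.v1_updated[:, k1] - out.v2_updated[:, k2]).max()
            assert diff < 1e-10

    def test_partial_matching_matched_columns_identical(self, rng):
        u1, u2, v1, v2, p1, p2 = random_setup(rng, k1=3, k2=5)
        s = np.zeros((3, 5), dtype=int)
        s[0, 2] = s[2, 0] = 1
        match = MatchResult(s, 1, "mnn")
        out = update_embeddings(u1, u2, v1, v2, match, p1, p2, alpha=0.5)
        for k1, k2 in match.pairs():
            assert np.abs(out.v1_updated[:, k1] -
                          out.v2_updated[:, k2]).max() < 1e-10

    def test_empty_matching_alpha_zero_is_plain_projection(self, rng):
        u1, u2, v1, v2, p1, p2 = random_setup(rng)
        match = MatchResult(np.zeros((3, 3), dtype=int), 1, "mnn")
        out = update_embeddings(u1, u2, v1, v2, match, p1, p2, alpha=0.0)
        u_cat = np.hstack([u1.T, u2.T])
        v_cat = np.hstack([v1, v2])
        u_cat = u_cat / np.linalg.norm(u_cat, axis=0)
        v_cat = v_cat / np.linalg.norm(v_cat, axis=0)
        np.testing.assert_allclose(out.e, u_cat.T @ v_cat, atol=1e-12)

    def test_embedding_shape_and_order(self, rng):
        u1, u2, v1, v2, p1, p2 = random_setup(rng, n1=10, n2=20, k1=2, k2=4)
        match = MatchResult(np.zeros((2, 4), dtype=int), 1, "mnn")
        out = update_embeddings(u1, u2, v1, v2, match, p1, p2)
        assert out.e.shape == (30, 6)

    def test_zero_norm_column_raises(self, rng):
        u1, u2, v1, v2, p1, p2 = random_setup(rng)
        v1 = v1.copy()
        v1[:, 1] = 0.0
        match = MatchResult(np.zeros((3, 3), dtype=int), 1, "mnn")
        with pytest.raises(ValueError, match="zero-norm column 1"):
            update_embeddings(u1, u2, v1, v2, match, p1, p2, alpha=0.0)


class TestMatchedMarkers:
    def test_intersection_rules(self):
        deg1 = [{"a", "b", "c"}, {"x"}]
        deg2 = [{"b", "c", "d"}, {"y"}]
        s = np.eye(2, dtype=int)
        match = MatchResult(s, 1, "mnn")
        out = matched_marker_genes(deg1, deg2, match)
        assert out[(0, 0)] == {"b", "c"}
        assert out[(1, 1)] == set()


class TestTransferLabels:
    def test_self_annotation_is_exact(self):
        cfg = SimConfig(n_genes=300, n_cells=150, n_shared_types=3,
                        n_private_per_batch=0, marker_strength=2.5)
        x, _, truth = simulate_pair(cfg, seed=11)
        res = transfer_labels(x, truth.type_of_cell[0], x,
                              lambda_query=1.0, n_hvg=200, q=10, seed=11)
        assert (res.labels.to_numpy() == truth.type_of_cell[0]).all()

    def test_reference_query_recovery(self):
        cfg = SimConfig(n_genes=400, n_cells=300, n_shared_types=4,
                        n_private_per_batch=0, marker_strength=2.0)
        x1, x2, truth = simulate_pair(cfg, seed=12)
        res = transfer_labels(x1, truth.type_of_cell[0], x2,
                              n_hvg=300, q=10, seed=12)
        m = annotation_metrics(truth.type_of_cell[1], res.labels.to_numpy())
        assert m["macro_f1"] >= 0.9

    def test_novel_type_unassigned_with_positive_floor(self):
        """A query population absent from the reference must come out
        "unassigned" once a positive score floor is set."""
        cfg = SimConfig(n_genes=400, n_cells=300, n_shared_types=3,
                        n_private_per_batch=1, marker_strength=2.0)
        x1, x2, truth = simulate_pair(cfg, seed=13)
        ref_mask = truth.type_of_cell[0] != "P1_0"
        x_ref = ExpressionMatrix(x1.values[:, ref_mask], x1.gene_ids,
                                 x1.cell_ids[ref_mask], x1.batch_id)
        res = transfer_labels(x_ref, truth.type_of_cell[0][ref_mask], x2,
                              n_hvg=300, q=10, min_score=0.05, seed=13)
        novel = truth.type_of_cell[1] == "P2_0"
        predicted = res.labels.to_numpy()
        assert (predicted[novel] == "unassigned").mean() >= 0.9
        shared = ~novel
        agree = (predicted[shared] == truth.type_of_cell[1][shared]).mean()
        assert agree >= 0.9

    def test_cells_in_same_cluster_share_label(self):
        x1, x2, truth = simulate_reference_query(
            SimConfig(n_genes=300, n_cells=200, n_shared_types=3,
                      n_private_per_batch=0, marker_strength=2.0), seed=14)
        res = transfer_labels(x1, truth.type_of_cell[0], x2,
                              n_hvg=200, q=10, seed=14)
        df = pd.DataFrame({"cluster": res.query_partition.labels,
                           "label": res.labels.to_numpy()})
        assert (df.groupby("cluster")["label"].nunique() == 1).all()

    def test_query_cell_order_invariance(self):
        cfg = SimConfig(n_genes=300, n_cells=150, n_shared_types=3,
                        n_private_per_batch=0, marker_strength=2.0)
        x1, x2, truth = simulate_pair(cfg, seed=15)
        res = transfer_labels(x1, truth.type_of_cell[0], x2,
                              n_hvg=200, q=10, seed=15)
        rng = np.random.default_rng(0)
        perm = rng.permutation(x2.n_cells)
        x2p = ExpressionMatrix(x2.values[:, perm], x2.gene_ids,
                               x2.cell_ids[perm], x2.batch_id)
        resp = transfer_labels(x1, truth.type_of_cell[0], x2p,
                               n_hvg=200, q=10, seed=15)
        a = res.labels.sort_index()
        b = resp.labels.sort_index()
        assert (a == b).all()
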