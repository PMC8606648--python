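import numpy as np
import pytest

from schybridnmf import (
    SpatialKMeans,
    centroids_from_labels,
    confidence_matrix,
    kmeans_locations,
)


class TestCentroidsFromLabels:
    def test_means(self):
        L = np.array([[0.0, 2.0], [0.0, 0.0]])
        W = centroids_from_labels(L, np.array([1, 1]), k=1)
        np.testing.assert_allclose(W[:, 0], [1.0, 0.0])

    def test_singletons_equal_cells(self):
        L = np.array([[0.0, 3.0, -1.0], [1.0, 2.0, 4.0]])
        W = centroids_from_labels(L, np.array([1, 2, 3]), k=3)
        np.testing.assert_allclose(W, L)

    def test_empty_cluster_reseeds_at_an_input_cell(self, rng):
        L = rng.normal(size=(2, 10))
        labels = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        W = centroids_from_labels(L, labels, k=3)
        # third centroid must coincide with one of the cells
        assert any(np.allclose(W[:, 2], L[:, i]) for i in range(10))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            centroids_from_labels(np.zeros((2, 0)), np.array([], dtype=int), 1)


class TestKMeansLocations:
    def test_two_separated_pairs_closed_form(self):
        # pairs at x=0 and x=10, each split by 2 in y: WCSS = 4 * (1^2)
        L = np.array([[0.0, 0.0, 10.0, 10.0], [0.0, 2.0, 0.0, 2.0]])
        init = np.array([[0.0, 10.0], [0.0, 0.0]])
        res = kmeans_locations(L, 2, init)
        assert res.wcss == pytest.approx(4.0)
        assert len(set(res.labels[:2])) == 1 and len(set(res.labels[2:])) == 1
        assert res.labels[0] != res.labels[2]

    def test_k_equals_n_gives_zero_wcss(self, rng):
        L = rng.normal(size=(2, 5))
        res = kmeans_locations(L, 5, L.copy())
        assert res.wcss == pytest.approx(0.0, abs=1e-15)

    def test_matrix_objective_equals_wcss(self, rng):
        L = rng.normal(size=(2, 40))
        init = L[:, rng.choice(40, 4, replace=False)]
        res = kmeans_locations(L, 4, init)
        matrix_obj = np.sum((L - res.W_L @ res.H_L) ** 2)
        assert matrix_obj == pytest.approx(res.wcss, rel=1e-12)

    def test_indicator_structure_and_centroid_consistency(self, rng):
        L = rng.normal(size=(2, 30))
        res = kmeans_locations(L, 3, L[:, :3].copy())
        np.testing.assert_array_equal(res.H_L.sum(axis=0), np.ones(30))
        for j in range(3):
            members = res.labels == j + 1
            if members.any():
                np.testing.assert_allclose(
                    res.W_L[:, j], L[:, members].mean(axis=1), rtol=1e-10
                )

    def test_wcss_trace_monotone(self, rng):
        L = rng.normal(size=(2, 60))
        res = kmeans_locations(L, 5, L[:, :5].copy())
        assert (np.diff(res.wcss_trace) <= 1e-9).all()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_locations(np.zeros((2, 3)), 4, np.zeros((2, 4)))


class TestConfidenceMatrix:
    def test_cell_at_centroid_scores_zero_there(self):
        L = np.array([[0.0], [0.0]])
        W = np.array([[0.0, 3.0], [0.0, 0.0]])
        conf = confidence_matrix(L, W)
        # printed form: numerator is the distance to that centroid
        np.testing.assert_allclose(conf.H_hat[:, 0], [0.0, 1.0])

    def test_equidistant_cell_splits_half_half(self):
        L = np.array([[1.0], [0.0]])
        W = np.array([[0.0, 2.0, 9.0], [0.0, 0.0, 9.0]])
        conf = confidence_matrix(L, W)
        np.testing.assert_allclose(conf.H_hat[:2, 0], [0.5, 0.5])
        assert conf.H_hat[2, 0] == 0.0

    def test_coincident_centroids_give_half_half(self):
        L = np.zeros((2, 1))
        W = np.zeros((2, 2))
        conf = confidence_matrix(L, W)
        np.testing.assert_allclose(conf.H_hat[:, 0], [0.5, 0.5])

    def test_structure_on_random_instances(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(3, 30)), int(rng.integers(2, 7))
            L = rng.normal(size=(2, n))
            W = rng.normal(size=(2, k))
            conf = confidence_matrix(L, W)
            nnz = (conf.H_hat > 0).sum(axis=0)
            # two nonzeros per column (a zero-distance tie is measure-zero)
            assert (nnz == 2).all()
            np.testing.assert_allclose(conf.H_hat.sum(axis=0), 1.0, rtol=1e-12)
            np.testing.assert_allclose(conf.C, 1.0 - conf.H_hat)
            assert (conf.C >= 0).all() and (conf.C <= 1).all()

    def test_translation_invariance(self, rng):
        L = rng.normal(size=(2, 12))
        W = rng.normal(size=(2, 4))
        shift = np.array([[3.7], [-1.2]])
        base = confidence_matrix(L, W)
        moved = confidence_matrix(L + shift, W + shift)
        np.testing.assert_allclose(base.H_hat, moved.H_hat, atol=1e-12)

    def test_invert_swaps_top2_weights(self, rng):
        L = rng.normal(size=(2, 8))
        W = rng.normal(size=(2, 3))
        a = confidence_matrix(L, W).H_hat
        b = confidence_matrix(L, W, invert=True).H_hat
        mask = a > 0
        np.testing.assert_allclose(np.sort(a[mask]), np.sort(b[mask]), rtol=1e-12)
        # inverted variant gives the larger weight to the closer centroid
        np.testing.assert_allclose((a + b)[mask], 1.0, rtol=1e-12)

    def test_fewer_than_two_centroids_rejected(self):
        with pytest.raises(ValueError):
            confidence_matrix(np.zeros((2, 3)), np.zeros((2, 1)))


class TestSpatialKMeansEstimator:
    def test_fit_predict_and_inertia(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)), rng.normal(size=(20, 2)) + 8])
        est = SpatialKMeans(n_clusters=2, random_state=0).fit(X)
        assert est.labels_.shape == (40,)
        assert est.inertia_ == pytest.approx(est.result_.wcss)
        preds = est.predict(X)
        np.testing.assert_array_equal(preds, est.labels_)

    def test_matches_sklearn_kmeans_on_separated_data(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        X = np.vstack(
            [rng.normal(size=(25, 2)), rng.normal(size=(25, 2)) + 10]
        )
        ours = SpatialKMeans(n_clusters=2, init=X[[0, -1]]).fit(X)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert adjusted_rand_score(ours.labels_, ref.labels_) == 1.0
        assert ours.inertia_ == pytest.approx(ref.inertia_, rel=1e-9)
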