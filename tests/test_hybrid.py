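import numpy as np
import pytest

from schybridnmf import (
    HybridConfig,
    SCHybridNMF,
    SparseNMFConfig,
    confidence_matrix,
    run_schybridnmf,
)
from schybridnmf.hybrid import kkt_residual, objective, update_H, update_W

from .oracles import brute_force_nnls


def random_instance(rng, m=12, n=18, k=3):
    A = rng.uniform(size=(m, n))
    W = rng.uniform(size=(m, k))
    H = rng.uniform(size=(k, n))
    H_hat = confidence_matrix(
        rng.normal(size=(2, n)), rng.normal(size=(2, k))
    ).H_hat
    return A, W, H, H_hat


class TestObjective:
    def test_alpha_zero_is_plain_residual(self, rng):
        A, W, H, H_hat = random_instance(rng)
        assert objective(A, W, H, H_hat, 0.0) == pytest.approx(
            np.sum((A - W @ H) ** 2), rel=1e-12
        )

    def test_penalty_vanishes_on_full_confidence_support(self, rng):
        A, W, H, H_hat = random_instance(rng)
        H_bin = (H_hat == H_hat.max(axis=0)).astype(float)
        H_sup = H * H_bin  # supported only where H_hat is made exactly 1
        val0 = objective(A, W, H_sup, H_bin, 0.0)
        val9 = objective(A, W, H_sup, H_bin, 1e9)
        assert val9 == pytest.approx(val0, rel=1e-9)

    def test_two_route_evaluation_agrees(self, rng):
        A, W, H, H_hat = random_instance(rng)
        C = 1.0 - H_hat
        direct = np.sum((H - H * H_hat) ** 2)
        via_c = np.sum((H * C) ** 2)
        assert direct == pytest.approx(via_c, rel=1e-12)
        assert objective(A, W, H, H_hat, 2.5) == pytest.approx(
            np.sum((A - W @ H) ** 2) + 2.5 * via_c, rel=1e-12
        )

    def test_shape_mismatch_rejected(self, rng):
        A, W, H, H_hat = random_instance(rng)
        with pytest.raises(ValueError):
            objective(A, W, H[:, :-1], H_hat, 1.0)


class TestUpdateH:
    def test_alpha_zero_equals_plain_nnls(self, rng):
        A, W, _, H_hat = random_instance(rng)
        from schybridnmf import nnls_columns

        np.testing.assert_allclose(
            update_H(A, W, 1.0 - H_hat, 0.0), nnls_columns(W, A)
        )

    def test_uniform_penalty_shrinks_solution(self, rng):
        A, W, _, _ = random_instance(rng)
        C = np.ones((W.shape[1], A.shape[1]))
        h0 = update_H(A, W, C, 0.0)
        h_big = update_H(A, W, C, 100.0)
        assert np.linalg.norm(h_big) < np.linalg.norm(h0)

    def test_columns_are_independent(self, rng):
        A, W, _, H_hat = random_instance(rng)
        C = 1.0 - H_hat
        full = update_H(A, W, C, 3.0)
        single = update_H(A[:, [4]], W, C[:, [4]], 3.0)
        np.testing.assert_allclose(full[:, 4], single[:, 0], atol=1e-10)


class TestUpdateW:
    def test_identity_membership_returns_data(self, rng):
        A = rng.uniform(size=(6, 4))
        np.testing.assert_allclose(update_W(A, np.eye(4)), A, atol=1e-10)

    def test_recovers_generating_factor(self, rng):
        H = rng.uniform(size=(3, 20)) + 0.1
        W_true = rng.uniform(size=(10, 3))
        A = W_true @ H
        W = update_W(A, H)
        assert np.sum((A - W @ H) ** 2) <= 1e-8 * np.sum(A * A)

    def test_per_column_kkt_vs_brute_force(self, rng):
        A = rng.uniform(size=(8, 10))
        H = rng.uniform(size=(3, 10))
        W = update_W(A, H)
        for i in range(8):  # row i of W solves NNLS with design H^T
            x_star = brute_force_nnls(H.T, A[i])
            obj = np.sum((H.T @ W[i] - A[i]) ** 2)
            assert obj <= np.sum((H.T @ x_star - A[i]) ** 2) + 1e-8


class TestKKTResidual:
    def test_zero_at_exact_stationary_point(self, rng):
        W = rng.uniform(size=(6, 2)) + 0.5
        H = rng.uniform(size=(2, 9)) + 0.5
        A = W @ H
        C = np.zeros((2, 9))
        assert kkt_residual(A, W, H, C, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_first_iteration_normalizes_to_one(self, small_dataset):
        ds, A = small_dataset
        est = SCHybridNMF(n_clusters=3, alpha=1.0, max_iter=5,
                          random_state=0).fit(A.T, locations=ds.locations.T)
        assert est.kkt_trace_[0] == pytest.approx(1.0)

    def test_converges_below_loose_tolerance(self, small_dataset):
        ds, A = small_dataset
        est = SCHybridNMF(n_clusters=3, alpha=1.0, tol=0.2, max_iter=500,
                          random_state=0).fit(A.T, locations=ds.locations.T)
        assert est.termination_ == "kkt_converged"
        assert est.kkt_trace_[-1] < 0.2


class TestFullRun:
    def test_monotone_objective_trace(self, small_dataset):
        ds, A = small_dataset
        est = SCHybridNMF(n_clusters=3, alpha=5.0, max_iter=60,
                          random_state=1).fit(A.T, locations=ds.locations.T)
        interleaved = [est.objective_trace_[0]]
        for oh, ow in est.objective_halfsteps_:
            interleaved += [oh, ow]
        t = np.asarray(interleaved)
        assert (np.diff(t) <= 1e-9 * np.maximum(t[:-1], 1.0)).all()

    def test_alpha_continuity_of_labels(self, small_dataset):
        ds, A = small_dataset
        common = dict(n_clusters=3, max_iter=40, random_state=3)
        l0 = SCHybridNMF(alpha=0.0, **common).fit_predict(
            A.T, locations=ds.locations.T
        )
        l_eps = SCHybridNMF(alpha=1e-9, **common).fit_predict(
            A.T, locations=ds.locations.T
        )
        np.testing.assert_array_equal(l0, l_eps)

    def test_huge_alpha_confines_support_to_top2_rows(self, small_dataset):
        ds, A = small_dataset
        est = SCHybridNMF(n_clusters=3, alpha=1e6, max_iter=40,
                          random_state=2).fit(A.T, locations=ds.locations.T)
        H, C = est.H_, est.complement_
        # dominant membership of every cell sits where C is smallest
        top2 = np.argsort(C, axis=0)[:2]
        lead = H.argmax(axis=0)
        frac = np.mean((lead == top2[0]) | (lead == top2[1]))
        assert frac > 0.95

    def test_deterministic_given_seed(self, small_dataset):
        ds, A = small_dataset
        runs = [
            SCHybridNMF(n_clusters=3, alpha=2.0, max_iter=30,
                        random_state=9).fit(A.T, locations=ds.locations.T)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].labels_, runs[1].labels_)
        np.testing.assert_array_equal(runs[0].H_, runs[1].H_)

    def test_functional_wrapper_round_trip(self, small_dataset):
        ds, A = small_dataset
        res = run_schybridnmf(
            A, ds.locations, k=3,
            nmf_config=SparseNMFConfig(k=3, seed=5),
            hybrid_config=HybridConfig(alpha=2.0, max_iter=30, seed=5),
        )
        assert res.labels.shape == (A.shape[1],)
        assert res.termination in ("kkt_converged", "max_iter")
        assert res.W_A.shape == (A.shape[0], 3)
        assert res.nmf_labels is not None and res.kmeans_labels is not None

    def test_anndata_input(self, small_dataset):
        anndata = pytest.importorskip("anndata")
        ds, A = small_dataset
        adata = anndata.AnnData(X=A.T.copy())
        adata.obsm["spatial"] = ds.locations.T.copy()
        est = SCHybridNMF(n_clusters=3, max_iter=10, random_state=0).fit(adata)
        assert est.labels_.shape == (A.shape[1],)

    def test_bad_inputs_rejected(self, small_dataset):
        ds, A = small_dataset
        with pytest.raises(ValueError):
            SCHybridNMF(n_clusters=3).fit(A.T)  # no locations
        with pytest.raises(ValueError):
            SCHybridNMF(n_clusters=3).fit(A.T, locations=ds.locations.T[:-1])
        with pytest.raises(ValueError):
            SCHybridNMF(n_clusters=1).fit(A.T, locations=ds.locations.T)
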