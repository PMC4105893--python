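import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from microcalc import (
    FcmConfig,
    InputError,
    defuzzify,
    fcm_fit,
    initialize_membership,
    objective,
    update_centroids,
    update_membership,
)


def naive_centroids(X, U, m):
    """Loop-based oracle for the centroid update."""
    N, K = U.shape
    C = np.zeros((K, X.shape[1]))
    for j in range(K):
        num = np.zeros(X.shape[1])
        den = 0.0
        for i in range(N):
            w = U[i, j] ** m
            num += w * X[i]
            den += w
        C[j] = num / den
    return C


def polish_to_fixed_point(X, U, m=2.0, max_iter=20000, u_tol=1e-13):
    """Iterate the library updates until memberships stop moving."""
    for _ in range(max_iter):
        C = update_centroids(X, U, m)
        U_next = update_membership(X, C, m)
        if np.abs(U_next - U).max() < u_tol:
            return U_next, C
        U = U_next
    return U, C


def naive_membership(X, C, m):
    """Loop-based oracle for the membership update."""
    N, K = X.shape[0], C.shape[0]
    U = np.zeros((N, K))
    for i in range(N):
        d = np.array([np.linalg.norm(X[i] - C[j]) for j in range(K)])
        if np.any(d < 1e-9):
            hits = d < 1e-9
            U[i, hits] = 1.0 / hits.sum()
            continue
        for j in range(K):
            U[i, j] = 1.0 / np.sum((d[j] / d) ** (2.0 / (m - 1.0)))
    return U


class TestInitialization:
    def test_single_cluster_memberships_are_one(self):
        U = initialize_membership(5, 1, seed=0)
        assert np.all(U == 1.0)

    def test_rows_sum_to_one(self):
        U = initialize_membership(40, 7, seed=3)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-12)
        assert U.min() >= 0

    def test_seed_determinism(self):
        a = initialize_membership(10, 3, seed=42)
        b = initialize_membership(10, 3, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(InputError):
            initialize_membership(2, 3)


class TestCentroidUpdate:
    def test_single_cluster_gives_mean(self, rng):
        X = rng.normal(size=(12, 4))
        C = update_centroids(X, np.ones((12, 1)), m=2.0)
        np.testing.assert_allclose(C[0], X.mean(axis=0), atol=1e-12)

    def test_crisp_memberships_give_cluster_means(self, rng):
        X = rng.normal(size=(10, 3))
        U = np.zeros((10, 2))
        U[:5, 0] = 1
        U[5:, 1] = 1
        C = update_centroids(X, U, m=3.7)
        np.testing.assert_allclose(C[0], X[:5].mean(axis=0))
        np.testing.assert_allclose(C[1], X[5:].mean(axis=0))

    def test_matches_naive_oracle(self, rng):
        X = rng.normal(size=(6, 2))
        U = initialize_membership(6, 2, seed=1)
        np.testing.assert_allclose(update_centroids(X, U, 2.0), naive_centroids(X, U, 2.0), atol=1e-12)


class TestMembershipUpdate:
    def test_equidistant_point_splits_evenly(self):
        X = np.array([[0.0, 0.0]])
        C = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(update_membership(X, C, 2.0), [[0.5, 0.5]])

    def test_point_on_centroid_is_crisp(self):
        X = np.array([[1.0, 2.0]])
        C = np.array([[1.0, 2.0], [5.0, 5.0]])
        np.testing.assert_allclose(update_membership(X, C, 2.0), [[1.0, 0.0]])

    def test_matches_naive_oracle(self, rng):
        X = rng.normal(size=(8, 3))
        C = rng.normal(size=(3, 3))
        np.testing.assert_allclose(update_membership(X, C, 1.8),
                                   naive_membership(X, C, 1.8), atol=1e-12)

    def test_update_minimizes_fixed_centroid_objective(self, rng):
        X = rng.normal(size=(7, 2))
        C = rng.normal(size=(3, 2))
        U_opt = update_membership(X, C, 2.0)
        J_opt = objective(X, U_opt, C, 2.0)
        for _ in range(100):
            U = rng.random((7, 3))
            U /= U.sum(axis=1, keepdims=True)
            assert objective(X, U, C, 2.0) >= J_opt - 1e-12


class TestObjective:
    def test_zero_when_points_sit_on_centroids(self):
        X = np.tile([[1.0, 1.0]], (4, 1))
        C = np.tile([[1.0, 1.0]], (2, 1))
        U = np.full((4, 2), 0.5)
        assert objective(X, U, C, 2.0) == 0.0

    def test_single_point_squared_distance(self):
        X = np.array([[3.0, 4.0]])
        C = np.array([[0.0, 0.0]])
        assert objective(X, np.array([[1.0]]), C, 2.0) == pytest.approx(25.0)

    def test_hand_computed_three_point_instance(self):
        X = np.array([[0.0], [1.0], [2.0]])
        C = np.array([[0.0], [2.0]])
        U = np.array([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]])
        m = 2.0
        # by hand: 0.64*0 + 0.04*4 + 0.25*1 + 0.25*1 + 0.01*4 + 0.81*0
        assert objective(X, U, C, m) == pytest.approx(0.16 + 0.5 + 0.04)


class TestFit:
    def test_separated_blobs_recovered_exactly(self, rng):
        a = rng.normal(0.0, 0.5, size=(20, 2))
        b = rng.normal(0.0, 0.5, size=(20, 2)) + [10.0, 0.0]
        X = np.vstack([a, b])
        part = fcm_fit(X, FcmConfig(K=2, seed=0, feature_mode="spatial_only"))
        labels = defuzzify(part.U)
        truth = np.r_[np.zeros(20), np.ones(20)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_drives_objective_to_zero(self, rng):
        X = rng.normal(size=(6, 2))
        part = fcm_fit(X, FcmConfig(K=6, seed=1, tol=1e-12, max_iter=2000))
        assert part.J_history[-1] < 1e-6

    def test_objective_non_increasing_many_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            N = int(rng.integers(5, 30))
            K = int(rng.integers(1, min(N, 6) + 1))
            F = int(rng.integers(1, 9))
            X = rng.normal(size=(N, F))
            part = fcm_fit(X, FcmConfig(K=K, seed=int(rng.integers(2**31))))
            J = np.array(part.J_history)
            assert np.all(np.diff(J) <= 1e-9 * np.maximum(J[:-1], 1))
            np.testing.assert_allclose(part.U.sum(axis=1), 1.0, atol=1e-9)

    def test_feature_mode_degenerates_when_structure_constant(self, rng):
        pos = rng.uniform(0, 1, size=(20, 2))
        X = np.hstack([pos, np.full((20, 7), 0.5)])
        wf = fcm_fit(X, FcmConfig(K=3, seed=7, feature_mode="with_features"))
        sp = fcm_fit(X, FcmConfig(K=3, seed=7, feature_mode="spatial_only"))
        assert wf.J_history[-1] == pytest.approx(sp.J_history[-1], abs=1e-6)

    def test_interleaved_populations_need_features(self):
        rng = np.random.default_rng(11)
        n = 25
        pos = rng.uniform(0, 1, size=(2 * n, 2))  # spatially mixed
        bright = np.full(n, 0.8) + rng.normal(0, 0.02, n)
        dim = np.full(n, 0.2) + rng.normal(0, 0.02, n)
        X = np.hstack([pos, np.full((2 * n, 7), 0.5)])
        X[:n, 5] = bright
        X[n:, 5] = dim
        truth = np.r_[np.zeros(n), np.ones(n)]
        wf = defuzzify(fcm_fit(X, FcmConfig(K=2, seed=2)).U)
        sp = defuzzify(fcm_fit(X, FcmConfig(K=2, seed=2, feature_mode="spatial_only")).U)
        assert adjusted_rand_score(truth, wf) > adjusted_rand_score(truth, sp)

    def test_converged_fit_is_fixed_point_of_naive_updates(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            X = rng.normal(size=(6, 2))
            part = fcm_fit(X, FcmConfig(K=2, seed=int(rng.integers(2**31)),
                                        tol=1e-13, max_iter=5000))
            U_star, C_star = polish_to_fixed_point(X, part.U)
            C_next = naive_centroids(X, U_star, 2.0)
            U_next = naive_membership(X, C_next, 2.0)
            np.testing.assert_allclose(C_next, C_star, atol=1e-9)
            np.testing.assert_allclose(U_next, U_star, atol=1e-9)

    def test_no_better_optimum_in_exhaustive_restarts(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(6, 2))
        part = fcm_fit(X, FcmConfig(K=2, seed=0, tol=1e-12, max_iter=2000))
        J_fit = part.J_history[-1]
        best = np.inf
        for _ in range(2000):
            U = rng.random((6, 2))
            U /= U.sum(axis=1, keepdims=True)
            for _ in range(60):
                C = naive_centroids(X, U, 2.0)
                U = naive_membership(X, C, 2.0)
            best = min(best, objective(X, U, C, 2.0))
        assert J_fit <= best + 1e-9


class TestDefuzzify:
    def test_argmax_and_tie_rule(self):
        U = np.array([[0.7, 0.3], [0.5, 0.5], [0.0, 1.0]])
        np.testing.assert_array_equal(defuzzify(U), [0, 0, 1])

    def test_crisp_identity(self):
        U = np.eye(4)
        np.testing.assert_array_equal(defuzzify(U), [0, 1, 2, 3])
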