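"""Medoid/fuzzy baselines and validity indexes against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from trajmix.baselines import (
    clara,
    dunn,
    fcm,
    mds_2d,
    pad_series,
    pam,
    silhouette_summary,
)

from oracles import (
    brute_best_medoids,
    brute_dunn,
    brute_pam_cost,
    brute_silhouette,
)


def dist_1d(points):
    return squareform(pdist(np.asarray(points, dtype=float)[:, None]))


class TestPadSeries:
    def test_zero_padding_and_distance(self):
        vec = pad_series([[1, 2], [1, 2, 3]])
        np.testing.assert_array_equal(vec.vectors, [[1, 2, 0], [1, 2, 3]])
        assert vec.distances[0, 1] == pytest.approx(3.0)

    def test_identical_series_distance_zero(self):
        vec = pad_series([[2, 3, 1], [2, 3, 1]])
        assert vec.distances[0, 1] == 0.0

    def test_matrix_matches_pairwise_loop(self, rng):
        series = [rng.integers(0, 5, size=rng.integers(2, 7)) for _ in range(12)]
        vec = pad_series(series)
        n = len(series)
        for i in range(n):
            assert vec.distances[i, i] == 0.0
            for j in range(i + 1, n):
                d = np.linalg.norm(vec.vectors[i] - vec.vectors[j])
                assert vec.distances[i, j] == pytest.approx(d)
                assert vec.distances[j, i] == pytest.approx(d)


class TestPAM:
    def test_two_pairs_recovered(self):
        D = dist_1d([0, 1, 10, 11])
        labels, medoids = pam(D, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        _, best_cost = brute_best_medoids(D, 2)
        assert brute_pam_cost(D, medoids) == pytest.approx(best_cost)

    def test_m_equals_n_costs_zero(self):
        D = dist_1d([0, 3, 7, 12])
        labels, medoids = pam(D, 4)
        assert sorted(medoids.tolist()) == [0, 1, 2, 3]
        assert brute_pam_cost(D, medoids) == 0.0

    def test_swap_optimal_on_random_instances(self, rng):
        # PAM is a local search: at convergence no single swap of a medoid
        # with a non-medoid may lower the cost (checked by brute force)
        for _ in range(10):
            pts = rng.normal(size=(12, 2))
            D = squareform(pdist(pts))
            _, medoids = pam(D, 3)
            cost = brute_pam_cost(D, medoids)
            for j in range(3):
                for h in range(12):
                    if h in medoids:
                        continue
                    trial = medoids.copy()
                    trial[j] = h
                    assert brute_pam_cost(D, trial) >= cost - 1e-9

    def test_matches_global_optimum_on_separated_instances(self, rng):
        # with well-separated blobs the swap-optimal solution is the global one
        for _ in range(5):
            centers = np.array([[0, 0], [20, 0], [0, 20]])
            pts = np.vstack([c + rng.normal(size=(4, 2)) for c in centers])
            D = squareform(pdist(pts))
            _, medoids = pam(D, 3)
            _, best = brute_best_medoids(D, 3)
            assert brute_pam_cost(D, medoids) == pytest.approx(best)

    def test_deterministic_with_duplicates(self):
        D = dist_1d([0, 0, 5, 5, 9])
        l1, m1 = pam(D, 2, seed=1)
        l2, m2 = pam(D, 2, seed=2)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(m1, m2)


class TestCLARA:
    def test_full_sample_reduces_to_pam(self, rng):
        pts = rng.normal(size=(30, 2))
        D = squareform(pdist(pts))
        lp, mp = pam(D, 3)
        lc, mc = clara(D, 3, sample_size=30, n_samples=1, seed=0)
        np.testing.assert_array_equal(mp, mc)
        np.testing.assert_array_equal(lp, lc)

    def test_toy_two_cluster_agreement(self):
        D = dist_1d([0, 1, 2, 20, 21, 22])
        lp, _ = pam(D, 2)
        lc, _ = clara(D, 2, sample_size=4, n_samples=10, seed=3)
        # same partition up to label permutation
        assert len({(a, b) for a, b in zip(lp, lc)}) == 2

    def test_seed_reproducible(self, rng):
        pts = rng.normal(size=(40, 3))
        D = squareform(pdist(pts))
        l1, m1 = clara(D, 3, sample_size=15, n_samples=3, seed=11)
        l2, m2 = clara(D, 3, sample_size=15, n_samples=3, seed=11)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(m1, m2)


class TestFCM:
    def test_point_on_center_gets_full_membership(self):
        # two coincident clumps: centers land exactly on them, so the
        # zero-distance limit gives membership 1
        X = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.0]])
        U, centers = fcm(X, 2, seed=0)
        np.testing.assert_allclose(sorted(centers[:, 0]), [0, 10], atol=1e-9)
        assert U[0].max() == pytest.approx(1.0)
        assert U[-1].max() == pytest.approx(1.0)

    def test_equidistant_point_membership_half(self):
        # symmetric configuration: the middle point stays equidistant from
        # the two (symmetric) centers, so its membership is (0.5, 0.5)
        X = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.0], [5.0]])
        U, centers = fcm(X, 2, seed=1, tol=1e-12, max_iter=2000)
        assert abs((centers[0, 0] + centers[1, 0]) - 10.0) < 1e-6  # symmetry
        np.testing.assert_allclose(U[-1], [0.5, 0.5], atol=1e-6)

    def test_memberships_row_normalized_and_objective_decreases(self, rng):
        X = rng.normal(size=(60, 4))
        q = 2.0
        U, centers = fcm(X, 3, seed=5)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)
        # recompute objective trajectory manually over two alternations
        def objective(U, C):
            d2 = ((X[:, None, :] - C[None]) ** 2).sum(axis=2)
            return ((U**q) * d2).sum()

        W = U**q
        C2 = (W.T @ X) / W.sum(axis=0)[:, None]
        assert objective(U, C2) <= objective(U, centers) + 1e-9


class TestSilhouette:
    def test_hand_example_two_pairs(self):
        D = dist_1d([0, 1, 10, 11])
        s = silhouette_summary(D, [0, 0, 1, 1])
        assert s["mean"] == pytest.approx(0.8997, abs=1e-4)
        assert s["min"] == pytest.approx(0.8947, abs=1e-4)
        assert s["max"] == pytest.approx(0.9048, abs=1e-4)

    def test_perfect_separation_limit(self):
        D = dist_1d([0, 0, 100, 100])
        s = silhouette_summary(D, [0, 0, 1, 1])
        assert s["min"] > 0.99

    def test_matches_brute_force_on_random_labels(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(25, 3))
            D = squareform(pdist(pts))
            labels = rng.integers(0, 3, size=25)
            if len(np.unique(labels)) < 2:
                continue
            expected = brute_silhouette(D, labels)
            got = silhouette_summary(D, labels)
            assert got["mean"] == pytest.approx(expected.mean(), abs=1e-10)
            assert got["min"] == pytest.approx(expected.min(), abs=1e-10)


class TestDunn:
    def test_hand_example(self):
        D = dist_1d([0, 1, 10, 11])
        assert dunn(D, [0, 0, 1, 1]) == pytest.approx(9.0)

    def test_zero_diameter_clusters_flagged_infinite(self):
        D = dist_1d([0, 0, 5, 5])
        assert np.isinf(dunn(D, [0, 0, 1, 1]))

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(20, 2))
            D = squareform(pdist(pts))
            labels = rng.integers(0, 3, size=20)
            if len(np.unique(labels)) < 2:
                continue
            assert dunn(D, labels) == pytest.approx(
                brute_dunn(D, labels), abs=1e-10
            )


class TestMDS:
    def test_exact_embedding_of_planar_points(self, rng):
        pts = rng.normal(size=(15, 2))
        D = squareform(pdist(pts))
        coords = mds_2d(D)
        D2 = squareform(pdist(coords))
        np.testing.assert_allclose(D2, D, atol=1e-6)

    def test_collinear_points(self):
        D = dist_1d([0, 5, 10])
        coords = mds_2d(D)
        d = squareform(pdist(coords))
        assert d[0, 1] == pytest.approx(5.0, abs=1e-8)
        assert d[1, 2] == pytest.approx(5.0, abs=1e-8)
        assert d[0, 2] == pytest.approx(10.0, abs=1e-8)
        assert np.abs(coords[:, 1]).max() == pytest.approx(0.0, abs=1e-8)

    def test_identical_points_collapse_to_origin(self):
        D = np.zeros((4, 4))
        np.testing.assert_allclose(mds_2d(D), 0.0, atol=1e-12)
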