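"""Unit and property tests for the Lloyd's k-means core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import elbowseg as es
from elbowseg.kmeans import PixelKMeans

from util_oracles import best_partition_sse, pairwise_within_sse


def random_instance(rng, n=None, d=None):
    n = n or int(rng.integers(4, 30))
    d = d or int(rng.integers(1, 4))
    return rng.normal(size=(n, d))


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------
class TestInitCentroids:
    def test_single_point_k1_is_that_point(self):
        x = np.array([[0.3, 0.7, 0.1]])
        for method in ("kmeanspp", "random_points"):
            np.testing.assert_array_equal(es.init_centroids(x, 1, method, seed=0), x)

    def test_k_equals_n_random_points_is_exhaustive(self, rng):
        x = rng.normal(size=(5, 2))
        c = es.init_centroids(x, 5, "random_points", seed=3)
        # sampling 5 of 5 without replacement returns the points in some order
        assert sorted(map(tuple, c)) == sorted(map(tuple, x))

    def test_kmeanspp_splits_two_blobs(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 10.0]])
        x = np.vstack([c + 0.1 * rng.normal(size=(50, 2)) for c in centers])
        hits = 0
        for seed in range(100):
            c = es.init_centroids(x, 2, "kmeanspp", seed=seed)
            blob_of = np.argmin(
                ((c[:, None, :] - centers[None]) ** 2).sum(-1), axis=1
            )
            hits += len(set(blob_of)) == 2
        assert hits >= 95

    def test_deterministic_given_seed(self, rng):
        x = random_instance(rng)
        a = es.init_centroids(x, 3, "kmeanspp", seed=11)
        b = es.init_centroids(x, 3, "kmeanspp", seed=11)
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_rejected(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError, match="k=5.*n=3"):
            es.init_centroids(x, 5, "kmeanspp", seed=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown init"):
            es.init_centroids(np.zeros((3, 2)), 2, "genetic", seed=0)


# ----------------------------------------------------------------------
# assignment / update
# ----------------------------------------------------------------------
class TestAssignUpdate:
    def test_zero_distance_assignment(self):
        labels = es.assign_points(
            np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        )
        assert labels.tolist() == [0]

    def test_equidistant_tie_goes_to_lowest_index(self):
        labels = es.assign_points(np.array([[0.5]]), np.array([[0.0], [1.0]]))
        assert labels.tolist() == [0]

    def test_matches_hand_computed_distance_table(self):
        # 6 points, 2 centroids; nearest centroid worked out by hand:
        # d^2 to (0,0): 0, 2, 8, 25, 13, 0.5   d^2 to (3,3): 18, 8, 2, 5, 1, 12.5
        pts = np.array([[0, 0], [1, 1], [2, 2], [5, 0], [2, 3], [0.5, 0.5]])
        cents = np.array([[0.0, 0.0], [3.0, 3.0]])
        assert es.assign_points(pts, cents).tolist() == [0, 0, 1, 1, 1, 0]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensionality"):
            es.assign_points(np.zeros((4, 3)), np.zeros((2, 2)))

    def test_update_all_one_cluster_gives_grand_mean(self, rng):
        x = random_instance(rng)
        c, empty = es.update_centroids(x, np.zeros(len(x), dtype=int), 1)
        assert empty == []
        np.testing.assert_allclose(c[0], x.mean(axis=0))

    def test_update_singleton_clusters_give_points_back(self, rng):
        x = random_instance(rng, n=6)
        c, empty = es.update_centroids(x, np.arange(6), 6)
        assert empty == []
        np.testing.assert_allclose(c, x)

    def test_update_reports_empty_clusters(self):
        x = np.array([[0.0], [1.0], [2.0]])
        c, empty = es.update_centroids(x, np.array([0, 0, 2]), 4)
        assert empty == [1, 3]
        np.testing.assert_allclose(c[0], [0.5])
        np.testing.assert_allclose(c[2], [2.0])


# ----------------------------------------------------------------------
# sum-of-squares objectives
# ----------------------------------------------------------------------
class TestSumsOfSquares:
    def test_zero_when_points_sit_on_centroids(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert es.sse_within(x, np.array([0, 1]), x) == 0.0

    def test_one_dim_two_points(self):
        x = np.array([[0.0], [2.0]])
        assert es.sse_within(x, np.array([0, 0]), np.array([[1.0]])) == pytest.approx(2.0)

    def test_between_is_zero_for_single_cluster(self, rng):
        x = random_instance(rng)
        c = x.mean(axis=0, keepdims=True)
        assert es.sse_between(x, np.zeros(len(x), dtype=int), c) == pytest.approx(0.0)

    def test_between_two_singletons(self):
        x = np.array([[0.0], [2.0]])
        assert es.sse_between(x, np.array([0, 1]), x) == pytest.approx(2.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_centroid_form_equals_pairwise_form(self, trial):
        rng = np.random.default_rng(1000 + trial)
        x = rng.normal(size=(20, 3))
        labels = rng.integers(0, 3, size=20)
        # empty clusters (zero rows in cents) contribute to neither form
        cents, _ = es.update_centroids(x, labels, 3)
        a = es.sse_within(x, labels, cents)
        b = pairwise_within_sse(x, labels)
        assert a == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_anova_decomposition(self, trial):
        rng = np.random.default_rng(2000 + trial)
        x = rng.normal(size=(25, 2))
        labels = rng.integers(0, 4, size=25)
        cents, _ = es.update_centroids(x, labels, 4)
        within = es.sse_within(x, labels, cents)
        between = es.sse_between(x, labels, cents)
        assert within + between == pytest.approx(es.total_ss(x), rel=1e-10)


# ----------------------------------------------------------------------
# the full algorithm
# ----------------------------------------------------------------------
class TestRunKMeans:
    def test_k_equals_n_reaches_zero_sse(self, rng):
        x = random_instance(rng, n=6)
        res = es.run_kmeans(x, es.KMeansConfig(k=6, n_init=5, seed=0))
        assert res.sse_within == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.cluster_sizes.tolist()) == [1] * 6

    def test_recovers_three_separated_blobs(self, three_blobs):
        pm, truth = three_blobs
        res = es.run_kmeans(pm, es.KMeansConfig(k=3, n_init=5, seed=0))
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, res.labels) == 1.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_partition_optimum(self, trial):
        rng = np.random.default_rng(3000 + trial)
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, 4))
        x = rng.normal(size=(n, 2))
        res = es.run_kmeans(x, es.KMeansConfig(k=k, n_init=50, seed=trial))
        assert res.sse_within == pytest.approx(best_partition_sse(x, k), rel=1e-9, abs=1e-12)

    def test_sse_history_monotone_descent(self, rng):
        x = random_instance(rng, n=200, d=3)
        res = es.run_kmeans(x, es.KMeansConfig(k=5, n_init=3, seed=1))
        assert np.all(np.diff(res.sse_history) <= 1e-9 * max(res.sse_history[0], 1.0))

    def test_decomposition_on_returned_result(self, three_blobs):
        pm, _ = three_blobs
        res = es.run_kmeans(pm, es.KMeansConfig(k=3, seed=0))
        total = es.total_ss(pm)
        assert res.sse_within + res.sse_between == pytest.approx(total, rel=1e-8)

    def test_deterministic_bit_identical(self, rng):
        x = random_instance(rng, n=100, d=3)
        cfg = es.KMeansConfig(k=4, n_init=3, seed=9)
        a = es.run_kmeans(x, cfg)
        b = es.run_kmeans(x, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=10)
    def test_row_permutation_invariance(self, seed):
        """On instances where the optimum is found, permuting rows permutes
        the labels identically (up to cluster renaming) and leaves the
        objective unchanged."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(seed)
        pm, _ = es.generate_point_cloud(
            k_true=3, n_per_cluster=10, dim=3, separation=0.8, sigma=0.03, seed=seed
        )
        x = pm.features
        perm = rng.permutation(len(x))
        cfg = es.KMeansConfig(k=3, n_init=10, seed=0)
        res = es.run_kmeans(x, cfg)
        res_p = es.run_kmeans(x[perm], cfg)
        assert res_p.sse_within == pytest.approx(res.sse_within, rel=1e-9)
        assert adjusted_rand_score(res.labels[perm], res_p.labels) == 1.0

    def test_empty_cluster_repair_keeps_all_clusters_populated(self):
        # many duplicate points force empty clusters during iteration
        x = np.vstack([np.zeros((20, 2)), np.ones((2, 2)), 5 * np.ones((1, 2))])
        res = es.run_kmeans(x, es.KMeansConfig(k=3, n_init=5, seed=0))
        assert res.cluster_sizes.min() >= 1
        assert res.cluster_sizes.sum() == len(x)

    def test_nonfinite_features_rejected(self):
        x = np.array([[0.0, np.nan], [1.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            es.run_kmeans(x, es.KMeansConfig(k=1))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="between 1 and"):
            es.run_kmeans(np.zeros((2, 2)), es.KMeansConfig(k=5))

    def test_agrees_with_sklearn_reference(self, three_blobs):
        """Independent route check: same objective value as scikit-learn's
        KMeans on an easy instance (both should find the global structure)."""
        from sklearn.cluster import KMeans

        pm, _ = three_blobs
        ours = es.run_kmeans(pm, es.KMeansConfig(k=3, n_init=10, seed=0))
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pm.features)
        assert ours.sse_within == pytest.approx(ref.inertia_, rel=1e-6)


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = PixelKMeans(n_clusters=3, tol=1e-4)
        params = est.get_params()
        assert params["n_clusters"] == 3
        est2 = PixelKMeans(**params)
        assert est2.get_params() == params

    def test_fit_predict_consistency(self, three_blobs):
        pm, _ = three_blobs
        est = PixelKMeans(n_clusters=3, n_init=5, random_state=0).fit(pm)
        np.testing.assert_array_equal(est.predict(pm), est.labels_)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_init"):
            es.KMeansConfig(k=2, n_init=0)
        with pytest.raises(ValueError, match="tol"):
            es.KMeansConfig(k=2, tol=-1)
        with pytest.raises(ValueError, match="init_method"):
            es.KMeansConfig(k=2, init_method="nope")
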