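"""Mahalanobis k-means and brute-force excitability fitting."""

import numpy as np
import pytest

from thalamodbs import default_parameters
from thalamodbs.classification_optimization import (
    GridSpec,
    brute_force_optimize,
    expected_grouping,
    grouping_matches,
    mahalanobis_kmeans,
    model_feature_vector,
)
from thalamodbs.model_core import spawn_seeds


def _blobs(rng, centers, n_per=15, sd=0.05):
    X = np.vstack([c + sd * rng.standard_normal((n_per, len(c)))
                   for c in centers])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


def _agreement(a, b):
    """Best label-permutation agreement between two clusterings."""
    from itertools import permutations
    k = max(a.max(), b.max()) + 1
    return max(np.mean(np.array([p[x] for x in a]) == b)
               for p in permutations(range(k)))


class TestKmeans:
    def test_identity_metric_matches_sklearn(self):
        """With a fixed identity covariance the algorithm is plain
        Euclidean k-means; on separable data it must agree with the
        scikit-learn solution up to label permutation."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(0)
        X, _ = _blobs(rng, [np.zeros(4), np.full(4, 3.0), np.r_[3.0, 0, 3, 0]])
        ours = mahalanobis_kmeans(X, 3, seed=1, cov=np.eye(4))
        theirs = KMeans(n_clusters=3, n_init=10, random_state=1).fit(X)
        assert _agreement(ours.labels, theirs.labels_) == 1.0
        assert ours.inertia == pytest.approx(theirs.inertia_, rel=1e-6)

    def test_separated_blobs_recovered(self):
        # Centers span the whole space: under the pooled-covariance
        # metric, directions carrying no structure are amplified to unit
        # variance, so separations must not be confined to a subspace.
        rng = np.random.default_rng(3)
        centers = [np.zeros(2), np.array([5.0, 0.0]), np.array([0.0, 5.0])]
        X, y = _blobs(rng, centers, sd=0.05)
        res = mahalanobis_kmeans(X, 3, seed=0)
        assert _agreement(res.labels, y) == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 3))
        res = mahalanobis_kmeans(X, 6, seed=0, n_restarts=5)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_inertia_non_increasing_over_lloyd_iterations(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 5))
        res = mahalanobis_kmeans(X, 4, seed=2, n_restarts=3)
        assert np.all(np.diff(res.inertia_history) <= 1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 9))
        a = mahalanobis_kmeans(X, 3, seed=5)
        b = mahalanobis_kmeans(X, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_kmeans(np.zeros((2, 3)), 3)

    def test_singular_covariance_handled(self):
        # simplex-constrained data: covariance is rank-deficient by one
        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(5), size=30)
        res = mahalanobis_kmeans(X, 2, seed=0)
        assert np.isfinite(res.inertia)


def test_grouping_match_logic():
    groups = expected_grouping()
    good = {"NS": 0, "IFS50": 0, "LFS2": 1,
            "HFS70": 2, "HFS100": 2, "HFS150": 2}
    assert grouping_matches(good, groups)
    bad = dict(good, IFS50=2)
    assert not grouping_matches(bad, groups)


class TestBruteForce:
    def test_self_consistency_recovers_grid_point(self):
        """A target generated at a known grid point with the same seeds is
        recovered with distance ~ 0."""
        seeds = [11, 12]
        base = default_parameters("pathological")
        grid = GridSpec(a_c=np.array([5.0, 6.0]),
                        b_c=np.array([14.0, 20.0]),
                        g_c=np.array([16.5]))
        truth = base.copy(A_C=6.0, B_C=14.0, G_C=16.5)
        target = model_feature_vector(truth, seeds, n_segments=1,
                                      seg_duration=5.0)
        res = brute_force_optimize(target, grid, base, seeds=seeds,
                                   n_segments=1, seg_duration=5.0)
        assert res.best == (6.0, 14.0, 16.5)
        assert res.best_distance == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.distance[np.isfinite(res.distance)] >= 0.0)

    def test_recovery_with_held_out_seeds(self):
        """A target simulated with held-out seeds is recovered to within
        one grid step per axis."""
        base = default_parameters("pathological")
        grid = GridSpec(a_c=np.array([5.5, 6.0, 6.5]),
                        b_c=np.array([11.0, 14.0, 17.0]),
                        g_c=np.array([15.0, 16.5, 18.0]))
        truth = base.copy(A_C=6.0, B_C=14.0, G_C=16.5)
        target = model_feature_vector(truth, spawn_seeds(77, 2),
                                      n_segments=2, seg_duration=5.0)
        res = brute_force_optimize(target, grid, base, seeds=spawn_seeds(3, 2),
                                   n_segments=2, seg_duration=5.0)
        assert abs(res.best[0] - 6.0) <= 0.5 + 1e-9
        assert abs(res.best[1] - 14.0) <= 3.0 + 1e-9
        assert abs(res.best[2] - 16.5) <= 1.5 + 1e-9

    def test_reproducible_bit_exact(self):
        base = default_parameters()
        grid = GridSpec(a_c=np.array([5.0, 6.0]), b_c=np.array([14.0]),
                        g_c=np.array([16.5]))
        target = np.full(9, 1.0 / 9.0)
        r1 = brute_force_optimize(target, grid, base, seeds=[1],
                                  n_segments=1, seg_duration=5.0)
        r2 = brute_force_optimize(target, grid, base, seeds=[1],
                                  n_segments=1, seg_duration=5.0)
        assert r1.best == r2.best
        np.testing.assert_array_equal(r1.distance, r2.distance)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            brute_force_optimize(np.zeros(5), GridSpec())
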