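"""Validity indices against hand computations and brute-force oracles;
optimal-k selection and the majority-vote consensus."""

import math

import numpy as np
import pytest

from spaclust.validity import (
    _argbest,
    calinski_harabasz,
    consensus_k,
    davies_bouldin,
    fraction_above,
    optimal_k,
    silhouette_mean,
    silhouette_samples,
    validity_report,
)

from bruteforce import (
    calinski_harabasz_naive,
    davies_bouldin_naive,
    silhouette_samples_naive,
)
from conftest import make_blobs_tight


def random_instance(rng):
    n = rng.integers(6, 26)
    d = rng.integers(1, 5)
    k = rng.integers(2, 5)
    points = rng.normal(size=(n, d)) * rng.uniform(0.5, 3)
    labels = rng.integers(0, k, size=n)
    # ensure at least 2 distinct clusters
    labels[0], labels[1] = 0, 1
    return points, labels


class TestHandComputedInstance:
    def test_per_sample_silhouette(self, four_point_instance):
        pts, labs = four_point_instance
        expected = [9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5]
        np.testing.assert_allclose(silhouette_samples(pts, labs), expected,
                                   atol=1e-12)

    def test_mean_silhouette(self, four_point_instance):
        pts, labs = four_point_instance
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert silhouette_mean(pts, labs) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8997, abs=5e-5)

    def test_calinski_harabasz_exact(self, four_point_instance):
        pts, labs = four_point_instance
        assert calinski_harabasz(pts, labs) == pytest.approx(200.0, abs=1e-9)

    def test_davies_bouldin_exact(self, four_point_instance):
        pts, labs = four_point_instance
        assert davies_bouldin(pts, labs) == pytest.approx(0.1, abs=1e-12)


class TestConventionsAndEdges:
    def test_singleton_cluster_silhouette_zero(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        s = silhouette_samples(pts, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_duplicate_points_in_cluster_score_one(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        s = silhouette_samples(pts, np.array([0, 0, 1, 1]))
        np.testing.assert_array_equal(s, [1.0, 1.0, 1.0, 1.0])

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="k=1"):
            silhouette_samples(np.zeros((4, 1)), np.zeros(4))

    def test_mixed_coincident_clouds_nonpositive(self):
        # two coincident clouds with perfectly interleaved labels
        pts = np.array([[0.0], [0.0], [0.0], [0.0],
                        [1.0], [1.0], [1.0], [1.0]])
        labs = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert silhouette_mean(pts, labs) <= 0

    def test_mean_within_sample_bounds(self):
        rng = np.random.default_rng(0)
        pts, labs = random_instance(rng)
        s = silhouette_samples(pts, labs)
        assert s.min() - 1e-12 <= silhouette_mean(pts, labs) <= s.max() + 1e-12

    def test_ch_perfect_separation_sentinel(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert calinski_harabasz(pts, np.array([0, 0, 1, 1])) == math.inf

    def test_ch_scale_invariance(self, four_point_instance):
        pts, labs = four_point_instance
        assert calinski_harabasz(3.7 * pts, labs) == pytest.approx(
            calinski_harabasz(pts, labs), rel=1e-12)

    def test_db_single_point_clusters_zero(self):
        pts = np.array([[0.0], [5.0], [9.0]])
        assert davies_bouldin(pts, np.array([0, 1, 2])) == 0.0

    def test_db_coincident_centroids_rejected(self):
        pts = np.array([[0.0], [2.0], [0.0], [2.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(pts, np.array([0, 0, 1, 1]))

    def test_db_tightening_clusters_never_increases(self):
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [4.0, 6.0]])
        rng = np.random.default_rng(5)
        offsets = rng.normal(size=(30, 2))
        labels = np.repeat(np.arange(3), 10)
        previous = math.inf
        for spread in (2.0, 1.0, 0.5, 0.1):
            pts = centers[labels] + spread * offsets
            current = davies_bouldin(pts, labels)
            assert current <= previous + 1e-12
            previous = current


class TestOracleEquivalence:
    def test_indices_match_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            pts, labs = random_instance(rng)
            np.testing.assert_allclose(
                silhouette_samples(pts, labs),
                silhouette_samples_naive(pts, labs), atol=1e-9)
            assert calinski_harabasz(pts, labs) == pytest.approx(
                calinski_harabasz_naive(pts, labs), abs=1e-9, rel=1e-9)
            try:
                mine = davies_bouldin(pts, labs)
            except ValueError:
                continue
            assert mine == pytest.approx(davies_bouldin_naive(pts, labs),
                                         abs=1e-9, rel=1e-9)

    def test_indices_match_sklearn(self):
        from sklearn.metrics import (
            calinski_harabasz_score,
            silhouette_score,
        )
        rng = np.random.default_rng(7)
        for _ in range(25):
            pts, labs = random_instance(rng)
            assert silhouette_mean(pts, labs) == pytest.approx(
                silhouette_score(pts, labs), abs=1e-9)
            assert calinski_harabasz(pts, labs) == pytest.approx(
                calinski_harabasz_score(pts, labs), rel=1e-9)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_translation_rotation_scale(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 18, 3
        pts = rng.normal(size=(n, d))
        labs = rng.integers(0, 3, size=n)
        labs[:3] = [0, 1, 2]
        base = (silhouette_mean(pts, labs), calinski_harabasz(pts, labs),
                davies_bouldin(pts, labs))
        # relabel clusters and reorder points
        perm = rng.permutation(n)
        relabel = np.array([2, 0, 1])[labs][perm]
        pts_p = pts[perm]
        # rigid motion + uniform scaling
        Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        pts_t = 2.5 * (pts_p @ Q) + rng.normal(size=d)
        moved = (silhouette_mean(pts_t, relabel),
                 calinski_harabasz(pts_t, relabel),
                 davies_bouldin(pts_t, relabel))
        np.testing.assert_allclose(moved, base, rtol=1e-9)

    def test_silhouette_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            pts, labs = random_instance(rng)
            s = silhouette_samples(pts, labs)
            assert np.all(s >= -1 - 1e-12) and np.all(s <= 1 + 1e-12)


class TestOptimalKAndConsensus:
    @pytest.mark.parametrize("criterion", ["silhouette", "calinski_harabasz",
                                           "davies_bouldin"])
    def test_three_tight_blobs_recovered(self, criterion):
        pts, _ = make_blobs_tight(k=3, seed=2)
        assert optimal_k(pts, "kmeans", criterion, seed=0) == 3

    @pytest.mark.parametrize("criterion", ["silhouette", "calinski_harabasz",
                                           "davies_bouldin"])
    def test_two_blobs_recovered(self, criterion):
        pts, _ = make_blobs_tight(k=2, seed=3)
        assert optimal_k(pts, "kmeans", criterion, seed=0) == 2

    def test_ties_break_toward_smaller_k(self):
        assert _argbest({4: 1.0, 2: 1.0, 3: 1.0}, True) == 2
        assert _argbest({5: 0.2, 3: 0.2, 7: 0.5}, False) == 3

    @pytest.mark.parametrize("votes,expected", [
        ({"silhouette": 3, "calinski_harabasz": 7, "davies_bouldin": 3}, 3),
        ({"silhouette": 5, "calinski_harabasz": 5, "davies_bouldin": 9}, 5),
        ({"silhouette": 2, "calinski_harabasz": 3, "davies_bouldin": 4}, 2),
    ])
    def test_consensus_majority_and_tiebreak(self, votes, expected):
        assert consensus_k(votes) == expected

    def test_consensus_requires_all_three_votes(self):
        with pytest.raises(ValueError):
            consensus_k({"silhouette": 3})

    def test_validity_report_on_blobs(self):
        pts, _ = make_blobs_tight(k=3, seed=4)
        rep = validity_report(pts, "kmeans", seed=0)
        assert rep.consensus_k == 3
        assert set(rep.per_k) == set(range(2, 10))
        assert len(rep.per_sample_silhouette_at_consensus) == len(pts)
        assert rep.optimal_k_per_criterion["silhouette"] == 3


class TestFractionAbove:
    def test_examples(self):
        assert fraction_above(np.array([0.7, 0.5, 0.9, 0.61])) == 0.75
        assert fraction_above(np.array([0.1, 0.2])) == 0.0
        assert fraction_above(np.array([0.7, 0.5]), threshold=-1.0) == 1.0

    def test_strictness_at_threshold(self):
        assert fraction_above(np.array([0.6, 0.6000001])) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_above(np.array([]))
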