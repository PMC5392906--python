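"""Feature encoding and Euclidean k-means behaviour."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from thigmo import cluster
from thigmo.cluster import (GeneProfile, InputError, accommodation_delta,
                            euclidean_distance, feature_vector,
                            kmeans_cluster, select_representative,
                            sign_grade_features, velocity_features)


def make_profile(a=None, s=None, r1=0.0, r2=0.0):
    times = (0.5, 2.0, 24.0, 72.0)
    return GeneProfile("g", dict(zip(times, a or [0, 0, 0, 0])),
                       dict(zip(times, s or [0, 0, 0, 0])), r1, r2)


class TestVelocityFeatures:
    def test_zero_profile_both_forms(self):
        p = make_profile()
        for form in ("difference", "sum_printed"):
            np.testing.assert_array_equal(velocity_features(p, form),
                                          np.zeros(5))

    def test_difference_form(self):
        p = make_profile(a=[2, 2, 0, 0])
        v = velocity_features(p, "difference")
        # intervals over padded grid {0, 0.5, 2, 24, 72, 120} h
        np.testing.assert_allclose(
            v, [4.0, 0.0, -2 / 22, 0.0, 0.0], atol=1e-12)

    def test_sum_printed_form(self):
        p = make_profile(a=[2, 2, 0, 0])
        v = velocity_features(p, "sum_printed")
        assert v[0] == pytest.approx(4.0)
        assert v[1] == pytest.approx((2 + 2) / 1.5)

    def test_unknown_form_rejected(self):
        with pytest.raises(InputError):
            velocity_features(make_profile(), "typo")


class TestSignGrades:
    @pytest.mark.parametrize("s,expected", [
        ([1, 0, 0, 0], (1, 0, 0, 0)),
        ([-1, 0, 0, 1], (-1, 0, 0, 1)),  # down at 0.5 h, up at 72 h
        ([0, 0, 0, 0], (0, 0, 0, 0)),
    ])
    def test_grades(self, s, expected):
        np.testing.assert_array_equal(
            sign_grade_features(make_profile(s=s)), expected)

    def test_missing_status_rejected(self):
        p = make_profile()
        del p.s_t[24.0]
        with pytest.raises(InputError, match="24"):
            sign_grade_features(p)


class TestAccommodationDelta:
    @pytest.mark.parametrize("r1,r2,expected", [
        (2.0, 2.0, 0.0),
        (3.15, 3.4, 0.25),   # a non-accommodated gene's two ratios
        (2.0, 0.0, -2.0),    # fully accommodated
    ])
    def test_delta(self, r1, r2, expected):
        assert accommodation_delta(make_profile(r1=r1, r2=r2)) \
            == pytest.approx(expected)

    def test_flat_ns_gene_has_zero_vector(self):
        vec = feature_vector(make_profile())
        np.testing.assert_array_equal(vec, np.zeros(10))


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self):
        assert euclidean_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert euclidean_distance([3, 4, 0], [0, 0, 0]) == 5.0

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x, y = rng.normal(size=10), rng.normal(size=10)
            oracle = sum((xi - yi) ** 2 for xi, yi in zip(x, y)) ** 0.5
            assert euclidean_distance(x, y) == pytest.approx(oracle)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            euclidean_distance([1, 2], [1, 2, 3])


def wcss_of(points, labels):
    points = np.asarray(points, float)
    total = 0.0
    for lab in np.unique(labels):
        sub = points[np.asarray(labels) == lab]
        total += ((sub - sub.mean(axis=0)) ** 2).sum()
    return total


def best_bipartition_wcss(points):
    """Exhaustive minimum over all 2^(n-1) - 1 bipartitions."""
    n = len(points)
    best = np.inf
    for r in range(1, n // 2 + 1):
        for group in combinations(range(n), r):
            labels = np.zeros(n, int)
            labels[list(group)] = 1
            best = min(best, wcss_of(points, labels))
    return best


class TestKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (20, 3)),
                         rng.normal(10, 0.1, (20, 3))])
        assign, _, _ = kmeans_cluster(pd.DataFrame(pts), k=2, seed=0)
        labels = assign["cluster"].to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_wcss_matches_exhaustive_bipartition_search(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 9)
            pts = rng.normal(size=(n, 2))
            _, _, wcss = kmeans_cluster(pd.DataFrame(pts), k=2,
                                        restarts=40, seed=int(rng.integers(2**31)))
            assert wcss == pytest.approx(best_bipartition_wcss(pts), abs=1e-9)

    def test_k_equals_n_gives_zero_wcss(self):
        pts = np.random.default_rng(3).normal(size=(6, 4))
        _, _, wcss = kmeans_cluster(pd.DataFrame(pts), k=6, seed=0)
        assert wcss == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            kmeans_cluster(pd.DataFrame(np.zeros((3, 2))), k=5, seed=0)

    def test_non_finite_rejected(self):
        pts = np.zeros((10, 2))
        pts[0, 0] = np.nan
        with pytest.raises(InputError):
            kmeans_cluster(pd.DataFrame(pts), k=2, seed=0)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(9)
        feats = pd.DataFrame(rng.normal(size=(30, 4)),
                             index=[f"g{i:02d}" for i in range(30)])
        a1, _, w1 = kmeans_cluster(feats, k=4, seed=5)
        shuffled = feats.sample(frac=1, random_state=1)
        a2, _, w2 = kmeans_cluster(shuffled, k=4, seed=5)
        assert w1 == w2
        pd.testing.assert_frame_equal(a1, a2)

    def test_near_sklearn_objective(self):
        # independent route: sklearn's k-means on the same data should not
        # find a meaningfully better objective than ours
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(120, 5))
        _, _, ours = kmeans_cluster(pd.DataFrame(pts), k=6, restarts=25, seed=0)
        ref = KMeans(n_clusters=6, n_init=25, random_state=0).fit(pts).inertia_
        assert ours <= ref * 1.05


class TestSelectRepresentative:
    def test_singleton(self):
        feats = pd.DataFrame([[1.0, 2.0]], index=["only"])
        assert select_representative(["only"], feats) == "only"

    def test_gene_at_median_point_wins(self):
        feats = pd.DataFrame([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]],
                             index=["lo", "mid", "hi"])
        assert select_representative(["lo", "mid", "hi"], feats) == "mid"

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.normal(size=(15, 6)),
                             index=[f"g{i}" for i in range(15)])
        med = feats.median(axis=0).to_numpy()
        dists = {g: np.linalg.norm(feats.loc[g] - med) for g in feats.index}
        assert select_representative(feats.index, feats) == min(dists, key=dists.get)

    def test_empty_cluster_rejected(self):
        with pytest.raises(InputError):
            select_representative([], pd.DataFrame())
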