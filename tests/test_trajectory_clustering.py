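"""DTW distance (vs brute-force path enumeration), DBA, k-means, relabeling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alistrat.pt_model import PTParams, simulate_trajectory
from alistrat.trajectory_clustering import (
    ClusterResult,
    cluster_trajectories,
    dba_barycenter,
    dtw_distance,
    elbow_curve,
    relabel_groups,
)


def dtw_bruteforce(a, b) -> float:
    """Enumerate every monotone warping path (oracle for short series)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += (a[i] - b[j]) ** 2
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDtwDistance:
    def test_identical_series_zero(self):
        s = [10.0, 20.0, 30.0, 25.0]
        assert dtw_distance(s, s) == 0.0

    def test_perfect_warp_alignment(self):
        assert dtw_distance([0, 0, 1], [0, 1, 1]) == 0.0

    def test_window_zero_is_pointwise_sse(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert dtw_distance(a, b, window=0) == pytest.approx(np.sum((a - b) ** 2))

    def test_equals_bruteforce_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.normal(0, 10, rng.integers(2, 7))
            b = rng.normal(0, 10, rng.integers(2, 7))
            assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b), rel=1e-12)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        d_ab = dtw_distance(a, b)
        assert d_ab >= 0.0
        assert d_ab == pytest.approx(dtw_distance(b, a), rel=1e-12, abs=1e-12)
        assert dtw_distance(a, a) == 0.0

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([1, 2], [1, 2], window=-1)


class TestDbaBarycenter:
    def test_singleton_is_identity(self):
        s = np.array([[10.0, 20.0, 30.0]])
        np.testing.assert_allclose(dba_barycenter(s), s[0])

    def test_identical_pair_is_identity(self):
        s = np.array([[5.0, 6.0, 7.0], [5.0, 6.0, 7.0]])
        np.testing.assert_allclose(dba_barycenter(s), s[0])

    def test_symmetric_constant_pair_averages(self):
        s = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        np.testing.assert_allclose(dba_barycenter(s), [1.0, 1.0, 1.0])

    def test_cost_non_increasing(self, rng):
        X = rng.normal(50, 15, size=(12, 5))
        centroid = dba_barycenter(X, max_iter=20)
        cost_final = sum(dtw_distance(x, centroid) for x in X)
        cost_init = sum(dtw_distance(x, X[0]) for x in X)
        assert cost_final <= cost_init + 1e-9


class TestClusterTrajectories:
    def test_single_cluster(self, rng):
        X = rng.normal(50, 5, size=(10, 5))
        res = cluster_trajectories(X, k=1, n_init=2, seed=0)
        assert np.all(res.labels == 0)
        # Inertia is consistent with the returned centroid.
        assert res.inertia == pytest.approx(sum(dtw_distance(x, res.centroids[0]) for x in X))

    def test_planted_two_bundle_partition(self, rng):
        from sklearn.metrics import adjusted_rand_score

        low = rng.normal(30, 1, size=(20, 5))
        high = rng.normal(70, 1, size=(20, 5))
        X = np.vstack([low, high])
        truth = [0] * 20 + [1] * 20
        res = cluster_trajectories(X, k=2, n_init=4, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_inertia_decreases_with_k(self, rng):
        X = rng.normal(50, 15, size=(40, 5))
        i2 = cluster_trajectories(X, k=2, n_init=4, seed=1).inertia
        i6 = cluster_trajectories(X, k=6, n_init=4, seed=1).inertia
        assert i6 <= i2
        assert i2 >= 0 and i6 >= 0

    def test_elbow_single_k(self, rng):
        X = rng.normal(50, 10, size=(15, 5))
        curve = elbow_curve(X, [1], seed=0)
        assert len(curve) == 1 and curve[0][0] == 1
        assert curve[0][1] >= 0

    def test_elbow_on_planted_archetypes(self):
        from alistrat.synthetic_cohort import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n=120, seed=9))
        X = cohort.pt_matrix()
        curve = elbow_curve(X, range(1, 9), seed=0, n_init=3)
        inertia = np.array([c[1] for c in curve])
        assert np.all(inertia >= 0)
        drops = -np.diff(inertia) / np.maximum(inertia[:-1], 1e-9)
        # Largest relative drop at or before k=6.
        assert int(np.argmax(drops)) + 2 <= 6


class TestRelabelGroups:
    def make_result(self, order):
        centroids = np.array([[90.0] * 5, [70.0] * 5, [40.0] * 5, [30.0] * 5, [55.0] * 5, [80.0] * 5])
        labels = np.array(order)
        return ClusterResult(labels=labels, centroids=centroids, inertia=0.0, k=6)

    def test_sorted_by_descending_mean(self):
        res = relabel_groups(self.make_result([0, 1, 2, 3, 4, 5]))
        assert res.group_names == [f"G{i}" for i in range(1, 7)]
        means = res.centroids.mean(axis=1)
        assert np.all(np.diff(means) <= 0)

    def test_permutation_invariance(self):
        base_result = self.make_result([0, 1, 2, 3, 4, 5])
        base = relabel_groups(base_result)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = ClusterResult(
            labels=np.array([perm.index(i) for i in [0, 1, 2, 3, 4, 5]]),
            centroids=base_result.centroids[perm],
            inertia=0.0,
            k=6,
        )
        out = relabel_groups(shuffled)
        np.testing.assert_array_equal(out.centroids, base.centroids)
        assert [out.group_names[l] for l in out.labels] == [
            base.group_names[l] for l in base.labels
        ]

    def test_generic_names_for_other_k(self, rng):
        X = rng.normal(50, 10, size=(12, 5))
        res = relabel_groups(cluster_trajectories(X, k=3, n_init=2, seed=0))
        assert res.group_names == ["C1", "C2", "C3"]

    def test_archetype_g1_maps_to_highest_mean(self):
        from alistrat.synthetic_cohort import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n=200, seed=17))
        res = relabel_groups(cluster_trajectories(cohort.pt_matrix(), 6, n_init=5, seed=17))
        named = res.named_labels()
        true_of_g1 = [p.true_group for p, n in zip(cohort.patients, named) if n == "G1"]
        assert max(set(true_of_g1), key=true_of_g1.count) == "G1"
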