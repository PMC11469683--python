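"""City-block k-means, elbow selection, state matching and descriptors."""

import itertools

import numpy as np
import pytest

from statenergy.exceptions import DegenerateInputError, InvalidParameterError
from statenergy.states import (CityBlockKMeans, describe_state, fit_states,
                               match_states, select_k_elbow)


def brute_force_l1_inertia(x, k):
    """Minimal total L1 inertia over all k-partitions of 1-D points."""
    best = np.inf
    n = len(x)
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        inertia = 0.0
        for c in range(k):
            members = np.array([x[i] for i in range(n) if assignment[i] == c])
            inertia += np.abs(members - np.median(members)).sum()
        best = min(best, inertia)
    return best


class TestCityBlockKMeans:
    def test_one_dimensional_oracle(self):
        """Matches exhaustive enumeration of all 2-partitions."""
        x = np.array([0.0, 0.0, 1.0, 10.0, 10.0, 11.0])
        km = CityBlockKMeans(n_clusters=2, random_state=0).fit(x[:, None])
        assert km.inertia_ == pytest.approx(brute_force_l1_inertia(x, 2)) == 2.0
        assert sorted(km.cluster_centers_.ravel()) == [0.0, 10.0]

    def test_duplicate_rows_reseed(self):
        X = np.ones((10, 3))
        km = CityBlockKMeans(n_clusters=2, random_state=0).fit(X)
        assert km.inertia_ == 0.0
        assert km.n_reseeds_ >= 1

    def test_centroid_is_median_fixed_point(self, rng):
        X = rng.standard_normal((60, 4))
        km = CityBlockKMeans(n_clusters=3, random_state=1).fit(X)
        for j in range(3):
            members = X[km.labels_ == j]
            np.testing.assert_allclose(km.cluster_centers_[j],
                                       np.median(members, axis=0))
        # one more Lloyd pass changes nothing
        again = km.predict(X)
        np.testing.assert_array_equal(again, km.labels_)

    def test_more_replicates_never_worse(self, rng):
        X = rng.standard_normal((80, 5))
        i1 = CityBlockKMeans(n_clusters=4, n_replicates=1, random_state=0).fit(X).inertia_
        i10 = CityBlockKMeans(n_clusters=4, n_replicates=10, random_state=0).fit(X).inertia_
        assert i10 <= i1 + 1e-9

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((50, 6))
        a = CityBlockKMeans(n_clusters=3, random_state=7).fit(X)
        b = CityBlockKMeans(n_clusters=3, random_state=7).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_allclose(a.cluster_centers_, b.cluster_centers_)

    def test_k_exceeds_samples(self):
        with pytest.raises(InvalidParameterError):
            CityBlockKMeans(n_clusters=5).fit(np.zeros((3, 2)))


class TestElbow:
    def test_hand_computed_curve(self):
        assert select_k_elbow({2: 100, 3: 40, 4: 10, 5: 9, 6: 8, 7: 7}) == 4

    def test_linear_decline_warns_smallest_interior(self):
        curve = {k: 100 - 10 * k for k in range(2, 8)}
        with pytest.warns(UserWarning, match="no elbow"):
            assert select_k_elbow(curve) == 3

    def test_non_monotone_smoothed(self):
        curve = {2: 100, 3: 40, 4: 10, 5: 11, 6: 8, 7: 7}
        with pytest.warns(UserWarning, match="isotonic"):
            assert select_k_elbow(curve) == 4

    def test_needs_three_candidates(self):
        with pytest.raises(InvalidParameterError):
            select_k_elbow({2: 10, 3: 5})

    def test_tie_broken_toward_smaller_k(self):
        # symmetric curves: interior distances tie pairwise, smaller k wins
        assert select_k_elbow({2: 10, 3: 5, 4: 5, 5: 0}) == 3
        assert select_k_elbow({2: 40, 3: 20, 4: 20, 5: 20, 6: 0}) == 3


class TestMatchStates:
    def test_recovers_planted_permutation(self, rng):
        ref = rng.standard_normal((4, 50))
        perm = np.array([1, 0, 3, 2])
        got = match_states(ref[perm], ref)
        np.testing.assert_array_equal(got, perm)

    def test_stable_under_noise(self, rng):
        ref = rng.standard_normal((4, 200))
        perm = np.array([2, 3, 0, 1])
        noisy = ref[perm] + 0.1 * rng.standard_normal((4, 200))  # SNR ~ 10
        np.testing.assert_array_equal(match_states(noisy, ref), perm)

    def test_single_state_identity(self, rng):
        c = rng.standard_normal((1, 10))
        np.testing.assert_array_equal(match_states(c, c), [0])


def _edge_index(n):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def exhaustive_modularity(W):
    """Best Newman modularity over all partitions of a tiny weighted graph."""
    n = W.shape[0]
    two_m = W.sum()
    strength = W.sum(axis=1)
    best = -np.inf
    for labels in itertools.product(range(n), repeat=n):
        labels = np.array(labels)
        q = 0.0
        for c in set(labels.tolist()):
            mask = labels == c
            q += W[np.ix_(mask, mask)].sum() / two_m
            q -= (strength[mask].sum() / two_m) ** 2
        best = max(best, q)
    return best


class TestDescribeState:
    def test_complete_graph_unit_weights(self):
        n = 5
        centroid = np.ones(n * (n - 1) // 2)
        d = describe_state(centroid, _edge_index(n), ["net"] * n)
        assert d.global_mean_connectivity == pytest.approx(1.0)
        assert d.global_efficiency == pytest.approx(1.0)

    def test_two_cliques_modularity(self):
        """Louvain matches exhaustive partition search: Q = 0.5 for two 3-cliques."""
        n = 6
        W = np.zeros((n, n))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        W[i, j] = 1.0
        iu, ju = np.triu_indices(n, k=1)
        centroid = W[iu, ju]
        d = describe_state(centroid, _edge_index(n), ["a"] * 3 + ["b"] * 3)
        assert exhaustive_modularity(W) == pytest.approx(0.5)
        assert d.modularity == pytest.approx(0.5)

    def test_ring_centrality_symmetric(self):
        n = 4
        centroid = np.zeros(6)
        for col, (i, j) in enumerate(_edge_index(n)):
            if (j - i) % n == 1 or (j - i) % n == n - 1:
                centroid[col] = 1.0
        d = describe_state(centroid, _edge_index(n), ["x", "y", "x", "y"])
        vals = list(d.centrality_by_network.values())
        assert vals[0] == pytest.approx(vals[1])

    def test_naming_by_max_centrality(self):
        # star on region 0: its network should dominate centrality
        n = 5
        centroid = np.zeros(10)
        for col, (i, j) in enumerate(_edge_index(n)):
            if i == 0:
                centroid[col] = 1.0
        nets = ["hub", "leaf", "leaf", "leaf", "leaf"]
        assert describe_state(centroid, _edge_index(n), nets).name == "hub"

    def test_all_zero_centroid_rejected(self):
        with pytest.raises(DegenerateInputError):
            describe_state(np.zeros(10), _edge_index(5), ["n"] * 5)


def test_fit_states_one_based_labels(rng):
    X = np.vstack([rng.normal(0, 0.1, (30, 6)), rng.normal(5, 0.1, (30, 6))])
    s = fit_states(X, 2, seed=0)
    assert set(s.assignments) == {1, 2}
    assert s.inertia == s.inertia_by_k[2]
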