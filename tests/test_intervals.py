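"""Trait clustering, cluster-number consensus and interval definition."""

import itertools

import numpy as np
import pytest

from jointgp.intervals import (
    CLUSTER_METHODS,
    ClusteringScheme,
    cluster_labels,
    consensus_cluster_count,
    define_intervals,
)


def brute_force_1d_kmeans(v, k):
    """Optimal contiguous partition of sorted 1-D data by within-SSE (exhaustive)."""
    order = np.argsort(v)
    vs = v[order]
    n = len(vs)
    best, best_sse = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = sum(
            ((vs[bounds[i] : bounds[i + 1]] - vs[bounds[i] : bounds[i + 1]].mean()) ** 2).sum()
            for i in range(k)
        )
        if sse < best_sse:
            best_sse, best = sse, cuts
    labels = np.empty(n, dtype=int)
    bounds = [0, *best, n]
    for i in range(k):
        labels[order[bounds[i] : bounds[i + 1]]] = i + 1
    return labels, best_sse


def same_partition(a, b):
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


class TestClusterLabels:
    def test_kmeans_two_separated_groups(self):
        y = np.array([0.0, 0.01, 0.02, 0.90, 0.91, 0.92])
        lab = cluster_labels(y, ClusteringScheme(method="kmeans"), 2)
        assert len(set(lab[:3])) == 1 and len(set(lab[3:])) == 1
        assert lab[0] != lab[3]

    @pytest.mark.parametrize("k", [2, 3])
    def test_kmeans_matches_brute_force(self, rng, k):
        y = rng.random(18)
        lab = cluster_labels(y, ClusteringScheme(method="kmeans", seed=1), k)
        oracle, best_sse = brute_force_1d_kmeans(y, k)
        sse = sum(((y[lab == g] - y[lab == g].mean()) ** 2).sum() for g in set(lab))
        assert sse == pytest.approx(best_sse, rel=1e-9)
        assert same_partition(lab, oracle)

    def test_k_equals_n_gives_singletons(self, rng):
        y = rng.random(6)
        lab = cluster_labels(y, ClusteringScheme(method="complete"), 6)
        assert len(set(lab)) == 6

    def test_k_below_minimum_rejected(self, rng):
        with pytest.raises(ValueError, match="below the minimum"):
            cluster_labels(rng.random(10), ClusteringScheme(), 1)

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_labels(rng.random(4), ClusteringScheme(), 5)

    @pytest.mark.parametrize("method", CLUSTER_METHODS)
    def test_every_method_partitions(self, rng, method):
        y = np.concatenate([rng.normal(0.2, 0.02, 15), rng.normal(0.8, 0.02, 15)])
        lab = cluster_labels(y, ClusteringScheme(method=method, seed=0), 2)
        assert len(set(lab)) == 2

    def test_ward_variants_differ_in_general(self, rng):
        # ward.D and ward.D2 orderings exist as distinct linkages; on most
        # datasets they agree at k=2 but their merge heights differ
        y = rng.random(20)
        l1 = cluster_labels(y, ClusteringScheme(method="wardWSD"), 4)
        l2 = cluster_labels(y, ClusteringScheme(method="wardWoSD"), 4)
        assert len(set(l1)) == len(set(l2)) == 4


class TestConsensus:
    def test_two_blobs(self, rng):
        y = np.concatenate([rng.normal(0.2, 0.02, 30), rng.normal(0.8, 0.02, 30)])
        k, votes = consensus_cluster_count(y, ClusteringScheme(method="wardWSD", seed=0))
        assert k == 2
        assert set(votes) == {
            "calinski_harabasz",
            "silhouette",
            "davies_bouldin",
            "dunn",
            "c_index",
            "hartigan",
            "krzanowski_lai",
            "gap",
        }

    def test_three_blobs(self, rng):
        y = np.concatenate(
            [rng.normal(c, 0.015, 20) for c in (0.1, 0.5, 0.9)]
        )
        k, _ = consensus_cluster_count(y, ClusteringScheme(method="kmeans", seed=0))
        assert k == 3

    def test_k_always_in_range(self, rng):
        y = rng.random(40)
        k, votes = consensus_cluster_count(y, ClusteringScheme(seed=1))
        assert 2 <= k <= 10
        assert all(2 <= v <= 10 for v in votes.values())

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            consensus_cluster_count(np.array([0.1, 0.9]), ClusteringScheme())


class TestDefineIntervals:
    def test_bimodal_trait_ordered_nonoverlapping(self, rng):
        y = np.concatenate([rng.normal(0.15, 0.03, 25), rng.normal(0.85, 0.03, 25)])
        asg = define_intervals(y, ClusteringScheme(method="wardWSD", seed=0))
        assert asg.k == 2
        # classes renamed by ascending mean; ranges must not overlap
        (lo1, hi1), (lo2, hi2) = asg.ranges
        assert hi1 < lo2
        assert set(asg.labels) == {1, 2}

    def test_translation_invariance(self, rng):
        y = np.concatenate([rng.normal(0.2, 0.02, 20), rng.normal(0.7, 0.05, 20)])
        a1 = define_intervals(y, ClusteringScheme(seed=2))
        a2 = define_intervals(y + 5.0, ClusteringScheme(seed=2))
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_scaling_invariance_of_labels(self, rng):
        y = np.concatenate([rng.normal(0.2, 0.02, 20), rng.normal(0.7, 0.05, 20)])
        a1 = define_intervals(y, ClusteringScheme(seed=2))
        a2 = define_intervals(3.0 * y, ClusteringScheme(seed=2))
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_frame_export(self, rng):
        y = np.concatenate([rng.normal(0.2, 0.02, 15), rng.normal(0.8, 0.02, 15)])
        asg = define_intervals(y, ClusteringScheme(seed=0))
        df = asg.to_frame()
        assert list(df.columns) == ["id", "label", "class_min", "class_max"]
        assert (df["class_min"] <= df["class_max"]).all()
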