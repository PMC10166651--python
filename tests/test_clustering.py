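import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, pdist

from microtrace import (
    DistanceMatrix,
    SimilarityMatrix,
    community_detection,
    cut_by_height_gap,
    modularity,
    similarity_to_dissimilarity,
    ward_linkage,
)
from microtrace.clustering import cut_dendrogram

from .oracles import max_modularity_bruteforce, modularity_of_partition, ward_bruteforce


def dm_from_points(x):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return DistanceMatrix(tuple(f"p{i}" for i in range(len(x))), cdist(x, x))


def sim_from_adjacency(A):
    A = np.asarray(A, dtype=float)
    S = A.copy()
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(tuple(f"n{i}" for i in range(len(A))), S)


class TestSimilarityToDissimilarity:
    def test_complement(self):
        S = sim_from_adjacency(np.array([[0, 1.0], [1.0, 0]]))
        D = similarity_to_dissimilarity(S)
        assert D.values[0, 1] == 0.0
        S0 = sim_from_adjacency(np.zeros((2, 2)))
        assert similarity_to_dissimilarity(S0).values[0, 1] == 1.0


class TestWardLinkage:
    def test_forced_geometry(self):
        dend = ward_linkage(dm_from_points([0.0, 1.0, 10.0, 11.0]))
        first_two = {tuple(sorted(m)) for m in dend.merges[:2, :2].astype(int).tolist()}
        assert first_two == {(0, 1), (2, 3)}

    def test_identical_items_zero_heights(self):
        dend = ward_linkage(dm_from_points([2.0, 2.0, 2.0]))
        assert np.allclose(dend.heights, 0.0)

    def test_heights_monotone_on_metric_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.random((12, 3))
            dend = ward_linkage(dm_from_points(x))
            assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_merge_sequence_matches_ess_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            x = rng.random((n, 2))
            dend = ward_linkage(dm_from_points(x))
            oracle = ward_bruteforce(x)
            for t, (a, b, delta) in enumerate(oracle):
                assert (int(dend.merges[t, 0]), int(dend.merges[t, 1])) == (a, b)
                # height convention: h^2 = 2 * delta-ESS for Euclidean input
                assert dend.merges[t, 2] ** 2 / 2.0 == pytest.approx(delta, abs=1e-9)

    def test_matches_scipy_on_tie_free_input(self):
        rng = np.random.default_rng(2)
        x = rng.random((15, 4))
        dend = ward_linkage(dm_from_points(x))
        Z = linkage(pdist(x), method="ward")
        # same heights; merge pairs may be listed in a different order at
        # equal heights, so compare the sorted height sequence
        assert np.allclose(np.sort(dend.heights), np.sort(Z[:, 2]))
        # and the induced flat clusterings agree at every k
        from scipy.cluster.hierarchy import fcluster

        for k in (2, 3, 5):
            ours = cut_dendrogram(dend, k).labels
            theirs = fcluster(Z, k, criterion="maxclust")
            from microtrace import nmi_labels

            assert nmi_labels(ours, theirs) == pytest.approx(1.0)


class TestCutByHeightGap:
    def test_dominant_gap(self):
        dend = ward_linkage(dm_from_points([0.0, 1.0, 10.0, 11.0]))
        lab = cut_by_height_gap(dend, 2)
        assert lab.n_clusters == 2
        assert lab.labels[0] == lab.labels[1] != lab.labels[2] == lab.labels[3]

    def test_three_triplets(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        x = np.vstack([c + 0.1 * rng.random((3, 2)) for c in centers])
        dend = ward_linkage(dm_from_points(x))
        lab = cut_by_height_gap(dend, 3)
        assert lab.n_clusters == 3
        assert len({lab.labels[0:3], lab.labels[3:6], lab.labels[6:9]}) == 3
        assert all(len(set(lab.labels[i : i + 3])) == 1 for i in (0, 3, 6))

    def test_min_clusters_equals_n_gives_singletons(self):
        dend = ward_linkage(dm_from_points([0.0, 1.0, 2.0]))
        lab = cut_by_height_gap(dend, 3)
        assert lab.labels == (1, 2, 3)

    def test_min_clusters_respected(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.random(8)
            dend = ward_linkage(dm_from_points(x))
            for mc in (2, 3):
                assert cut_by_height_gap(dend, mc).n_clusters >= mc

    def test_too_few_items_error(self):
        dend = ward_linkage(dm_from_points([0.0, 1.0]))
        with pytest.raises(ValueError):
            cut_by_height_gap(dend, 3)


def two_triangles():
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[i, j] = A[j, i] = 1.0
    return A


class TestCommunityDetection:
    def test_two_disconnected_triangles(self):
        S = sim_from_adjacency(two_triangles())
        lab = community_detection(S)
        assert lab.n_clusters == 2
        assert lab.labels[:3] == (1, 1, 1) and lab.labels[3:] == (2, 2, 2)
        assert modularity(S, lab) == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        A = np.ones((4, 4)) - np.eye(4)
        lab = community_detection(sim_from_adjacency(A))
        assert lab.n_clusters == 1
        assert modularity(sim_from_adjacency(A), lab) == pytest.approx(0.0)

    def test_two_cliques_3_and_4(self):
        A = np.zeros((7, 7))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        np.fill_diagonal(A, 0.0)
        lab = community_detection(sim_from_adjacency(A))
        assert lab.labels == (1, 1, 1, 2, 2, 2, 2)

    def test_empty_graph_gives_singletons(self):
        lab = community_detection(sim_from_adjacency(np.zeros((4, 4))))
        assert lab.labels == (1, 2, 3, 4)

    def test_matches_partition_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(15):
            n = int(rng.integers(4, 8))
            A = (rng.random((n, n)) < 0.5).astype(float) * rng.random((n, n))
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            S = sim_from_adjacency(np.clip(A, 0, 1))
            lab = community_detection(S)
            q = modularity(S, lab)
            q_star = max_modularity_bruteforce(np.clip(A, 0, 1))
            assert q <= q_star + 1e-12
            if q == pytest.approx(q_star, abs=1e-12):
                hits += 1
            # greedy never does worse than the trivial partitions
            parts_one = [list(range(n))]
            singles = [[i] for i in range(n)]
            Ac = np.clip(A, 0, 1)
            assert q >= modularity_of_partition(Ac, parts_one) - 1e-12
            assert q >= modularity_of_partition(Ac, singles) - 1e-12
        assert hits >= 13  # greedy is optimal on nearly all small instances

    def test_agreement_with_networkx_modularity_value(self):
        import networkx as nx

        S = sim_from_adjacency(two_triangles())
        lab = community_detection(S)
        G = nx.from_numpy_array(two_triangles())
        parts = [
            {i for i in range(6) if lab.labels[i] == c}
            for c in sorted(set(lab.labels))
        ]
        assert modularity(S, lab) == pytest.approx(
            nx.algorithms.community.modularity(G, parts)
        )

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        A = rng.random((10, 10))
        A = np.triu(A, 1) * (np.triu(rng.random((10, 10)), 1) < 0.4)
        A = A + A.T
        S = sim_from_adjacency(np.clip(A, 0, 1))
        assert community_detection(S).labels == community_detection(S).labels
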