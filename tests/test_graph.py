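"""Node strength, signed modularity, Louvain, co-assignment."""

import numpy as np
import networkx as nx
import pytest

from cognet.benchmarks import brute_force_best_partition, iter_partitions
from cognet.graph import (
    CommunityPartition,
    best_partition,
    coassignment,
    louvain,
    modularity_Q,
    node_strength,
)


def _two_cliques(w=1.0):
    """4 nodes, two disconnected single-edge 'cliques'."""
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = w
    W[2, 3] = W[3, 2] = w
    return W


def _triple_cliques():
    """Two disconnected 3-cliques."""
    W = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    return W


class TestNodeStrength:
    def test_empty_network_all_zero(self):
        prof = node_strength(np.zeros((5, 5)))
        assert np.all(prof.strength == 0)

    def test_single_edge(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        s = node_strength(W, labels=["a", "b", "c"]).as_series()
        assert s["a"] == s["b"] == pytest.approx(0.5)
        assert s["c"] == 0

    def test_absolute_value_convention(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.3
        assert node_strength(W).strength[0] == pytest.approx(0.8)

    def test_equals_row_sum_of_absolute_weights(self, rng):
        W = rng.uniform(-1, 1, (6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        assert np.allclose(node_strength(W).strength, np.abs(W).sum(axis=1))


class TestModularityQ:
    def test_two_equal_cliques_give_half(self):
        assert modularity_Q(_two_cliques(), [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_all_in_one_community_matches_brute_sum(self, rng):
        W = rng.uniform(0, 1, (5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        # literal evaluation of (1/s) sum_ij [w_ij - k_i k_j / s]
        k = W.sum(axis=1)
        s = k.sum()
        expected = float(((W - np.outer(k, k) / s) / s).sum())
        assert modularity_Q(W, [0] * 5) == pytest.approx(expected, abs=1e-12)
        assert modularity_Q(W, [0] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_positive_graph_matches_networkx_newman_q(self, rng):
        """With no negative edges the signed formula reduces to plain
        Newman weighted modularity; cross-check against networkx."""
        W = rng.uniform(0, 1, (6, 6)) * (rng.random((6, 6)) < 0.6)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        if W.sum() == 0:
            pytest.skip("degenerate draw")
        G = nx.from_numpy_array(W)
        member = np.array([0, 0, 0, 1, 1, 1])
        communities = [{0, 1, 2}, {3, 4, 5}]
        expected = nx.community.modularity(G, communities, weight="weight")
        assert modularity_Q(W, member) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_network_q_zero(self):
        assert modularity_Q(np.zeros((4, 4)), [0, 1, 2, 3]) == 0.0

    def test_negative_edge_discourages_coassignment(self):
        W = _two_cliques()
        W[0, 2] = W[2, 0] = -0.5
        merged = modularity_Q(W, [0, 0, 0, 0])
        split = modularity_Q(W, [0, 0, 1, 1])
        assert split > merged


class TestLouvain:
    def test_recovers_disconnected_cliques(self):
        part = louvain(_triple_cliques(), seed=0)
        m = part.membership()
        assert m[0] == m[1] == m[2]
        assert m[3] == m[4] == m[5]
        assert m[0] != m[3]

    def test_empty_network_all_singletons(self):
        part = louvain(np.zeros((4, 4)), seed=1)
        assert part.n_communities == 4
        assert part.Q == 0.0

    def test_never_worse_than_singletons(self, rng):
        for _ in range(10):
            W = rng.uniform(-1, 1, (6, 6)) * (rng.random((6, 6)) < 0.5)
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            part = louvain(W, seed=3)
            assert part.Q >= modularity_Q(W, np.arange(6)) - 1e-12

    def test_attains_bruteforce_optimum_on_most_small_graphs(self, rng):
        hits, total = 0, 20
        for g in range(total):
            W = rng.uniform(-1, 1, (5, 5)) * (rng.random((5, 5)) < 0.6)
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            _, q_star = brute_force_best_partition(W)
            part = best_partition(W, restarts=20, seed=g)
            hits += part.Q >= q_star - 1e-9
        assert hits >= total - 1


class TestBestPartition:
    def test_restarts_one_equals_single_louvain(self):
        W = _triple_cliques()
        single_seed = int(np.random.SeedSequence([5, 0]).generate_state(1)[0] % 2**31)
        assert best_partition(W, restarts=1, seed=5).assignment == louvain(
            W, seed=single_seed
        ).assignment

    def test_more_restarts_never_decrease_q(self, rng):
        W = rng.uniform(-1, 1, (7, 7))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        q1 = best_partition(W, restarts=1, seed=2).Q
        q100 = best_partition(W, restarts=100, seed=2).Q
        assert q100 >= q1 - 1e-12

    def test_deterministic_under_seed(self):
        W = _triple_cliques()
        a = best_partition(W, restarts=10, seed=9)
        b = best_partition(W, restarts=10, seed=9)
        assert a.assignment == b.assignment and a.Q == b.Q


class TestCoassignment:
    def _parts(self, assignments):
        labels = ["a", "b", "c"]
        return [
            CommunityPartition(labels=labels, assignment=dict(zip(labels, m)), Q=0.0)
            for m in assignments
        ]

    def test_identical_partitions(self):
        cam = coassignment(self._parts([[0, 0, 1]] * 5))
        assert cam.P[0, 1] == 1.0
        assert cam.P[0, 2] == 0.0 and cam.P[1, 2] == 0.0
        assert np.all(np.diag(cam.P) == 1.0)

    def test_counting_definition(self):
        parts = self._parts([[0, 0, 1]] * 84 + [[0, 1, 1]] * 16)
        cam = coassignment(parts)
        assert cam.P[0, 1] == pytest.approx(0.84)

    def test_invariant_to_community_relabeling(self):
        a = self._parts([[0, 0, 1], [1, 1, 0]])
        cam = coassignment(a)
        assert cam.P[0, 1] == 1.0  # same partition under different ids

    def test_label_mismatch_rejected(self):
        parts = self._parts([[0, 0, 1]])
        other = CommunityPartition(
            labels=["x", "y", "z"], assignment={"x": 0, "y": 0, "z": 1}, Q=0.0
        )
        with pytest.raises(ValueError):
            coassignment(parts + [other])


def test_partition_enumeration_counts_bell_numbers():
    assert sum(1 for _ in iter_partitions(4)) == 15
    assert sum(1 for _ in iter_partitions(6)) == 203
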