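import itertools

import networkx as nx
import numpy as np
import pytest

import tradeflow as tf
from tradeflow.errors import ValidationError
from tradeflow.netcluster import Partition, graph_from_tensor


# ---------------------------------------------------------------------------
# brute-force oracles


def all_set_partitions(n):
    """Every set partition of range(n) as a label vector (restricted growth)."""
    def rec(prefix, max_label):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(max_label + 2):
            yield from rec(prefix + [lab], max(max_label, lab))

    yield from rec([0], 0)


def modularity_oracle(w, labels):
    """Direct double-sum evaluation of the directed weighted modularity."""
    w = np.asarray(w, float)
    total = w.sum()
    kout, kin = w.sum(axis=1), w.sum(axis=0)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] / total - kout[i] * kin[j] / total**2
    return q


def best_partition_oracle(w):
    best_q, best_labels = -np.inf, None
    for labels in all_set_partitions(w.shape[0]):
        q = modularity_oracle(w, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_q, best_labels


def two_three_cycles():
    """Two disconnected directed 3-cycles with unit weights."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
        w[a, b] = 1.0
    return w


# ---------------------------------------------------------------------------
# directed_modularity


class TestDirectedModularity:
    def test_one_big_cluster_is_zero(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 5, (7, 7))
        np.fill_diagonal(w, 0)
        assert tf.directed_modularity(w, np.zeros(7)) == pytest.approx(0.0, abs=1e-12)

    def test_two_cycles_by_component(self):
        w = two_three_cycles()
        labels = [0, 0, 0, 1, 1, 1]
        assert tf.directed_modularity(w, labels) == pytest.approx(0.5)

    def test_two_cycles_singletons(self):
        w = two_three_cycles()
        assert tf.directed_modularity(w, np.arange(6)) == pytest.approx(-1.0 / 6.0)

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(3, 7))
            w = rng.uniform(0, 3, (n, n)) * (rng.random((n, n)) < 0.6)
            np.fill_diagonal(w, 0)
            if w.sum() == 0:
                continue
            labels = rng.integers(0, 3, n)
            assert tf.directed_modularity(w, labels) == pytest.approx(
                modularity_oracle(w, labels)
            )

    def test_invariant_under_relabeling_and_scaling(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0, 2, (6, 6))
        np.fill_diagonal(w, 0)
        labels = np.array([0, 1, 0, 2, 1, 2])
        q = tf.directed_modularity(w, labels)
        relabeled = np.array([5, 9, 5, 7, 9, 7])
        assert tf.directed_modularity(w, relabeled) == pytest.approx(q)
        assert tf.directed_modularity(w * 13.7, labels) == pytest.approx(q)

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValidationError):
            tf.directed_modularity(np.zeros((3, 3)), np.zeros(3))

    def test_accepts_networkx_digraph(self):
        g = nx.DiGraph()
        g.add_weighted_edges_from([("a", "b", 2.0), ("b", "a", 1.0), ("b", "c", 3.0)])
        part = Partition({"a": 0, "b": 0, "c": 1}, 0.0, "manual")
        q = tf.directed_modularity(g, part)
        w = np.array([[0, 2, 0], [1, 0, 3], [0, 0, 0]], float)
        assert q == pytest.approx(modularity_oracle(w, [0, 0, 1]))


# ---------------------------------------------------------------------------
# exact optimiser


class TestExactModularityPartition:
    def test_two_cycles(self):
        part = tf.exact_modularity_partition(two_three_cycles())
        assert part.modularity == pytest.approx(0.5)
        labels = part.labels_for(range(6))
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_complete_symmetric_digraph_single_cluster(self):
        w = np.ones((4, 4)) - np.eye(4)
        part = tf.exact_modularity_partition(w)
        assert part.n_clusters() == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_single_node_zero_weight_error(self):
        with pytest.raises(ValidationError):
            tf.exact_modularity_partition(np.zeros((1, 1)))

    def test_over_limit_directs_to_greedy(self):
        w = np.ones((6, 6)) - np.eye(6)
        with pytest.raises(ValidationError, match="greedy"):
            tf.exact_modularity_partition(w, exact_limit=5)

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 25:
            n = int(rng.integers(3, 9))
            w = rng.uniform(0.1, 4, (n, n)) * (rng.random((n, n)) < 0.5)
            np.fill_diagonal(w, 0)
            if w.sum() == 0:
                continue
            best_q, _ = best_partition_oracle(w)
            part = tf.exact_modularity_partition(w)
            assert part.modularity == pytest.approx(best_q, abs=1e-10)
            # returned Q is consistent with its own assignment
            assert tf.directed_modularity(w, part) == pytest.approx(part.modularity)
            checked += 1


# ---------------------------------------------------------------------------
# greedy optimiser


class TestGreedyModularityPartition:
    def test_two_cycles_matches_exact(self):
        w = two_three_cycles()
        greedy = tf.greedy_modularity_partition(w)
        exact = tf.exact_modularity_partition(w)
        assert greedy.modularity == pytest.approx(exact.modularity)

    def test_never_beats_exact_and_often_ties(self):
        rng = np.random.default_rng(4)
        ties = 0
        for _ in range(10):
            n = int(rng.integers(4, 9))
            w = rng.uniform(0.1, 4, (n, n)) * (rng.random((n, n)) < 0.5)
            np.fill_diagonal(w, 0)
            if w.sum() == 0:
                continue
            g = tf.greedy_modularity_partition(w)
            e = tf.exact_modularity_partition(w)
            assert g.modularity <= e.modularity + 1e-10
            if g.modularity == pytest.approx(e.modularity, abs=1e-10):
                ties += 1
        assert ties >= 7

    def test_equal_weight_complete_graph_single_cluster(self):
        w = np.ones((8, 8)) - np.eye(8)
        part = tf.greedy_modularity_partition(w)
        assert part.n_clusters() == 1

    def test_reported_q_consistent(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0, 3, (10, 10))
        np.fill_diagonal(w, 0)
        part = tf.greedy_modularity_partition(w)
        assert tf.directed_modularity(w, part) == pytest.approx(part.modularity)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0, 3, (12, 12))
        np.fill_diagonal(w, 0)
        p1 = tf.greedy_modularity_partition(w, seed=1)
        p2 = tf.greedy_modularity_partition(w, seed=99)
        assert p1.assignment == p2.assignment


# ---------------------------------------------------------------------------
# walktrap


class TestWalktrapPartition:
    def test_two_cycles_by_component(self):
        part = tf.walktrap_partition(two_three_cycles())
        labels = part.labels_for(range(6))
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_barbell_splits_at_bridge(self):
        w = np.zeros((10, 10))
        for group in (range(5), range(5, 10)):
            for a, b in itertools.permutations(group, 2):
                w[a, b] = 1.0
        w[4, 5] = w[5, 4] = 1.0  # the bridge
        part = tf.walktrap_partition(w)
        labels = part.labels_for(range(10))
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]
        # brute-force check: that cut is the modularity optimum
        best_q, best_labels = -np.inf, None
        # barbell is too big for full enumeration; compare against exact B&B
        exact = tf.exact_modularity_partition(w)
        assert part.modularity == pytest.approx(exact.modularity, abs=1e-10)

    def test_zero_steps_rejected(self):
        with pytest.raises(ValidationError):
            tf.walktrap_partition(two_three_cycles(), steps=0)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValidationError):
            tf.walktrap_partition(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# k-core


class TestKCoreLevels:
    def test_directed_three_cycle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = w[2, 0] = 1.0
        assert tf.k_core_levels(w) == {0: 2, 1: 2, 2: 2}

    def test_star_all_ones(self):
        w = np.zeros((5, 5))
        w[0, 1:] = 1.0
        cores = tf.k_core_levels(w)
        assert all(v == 1 for v in cores.values())

    def test_empty_graph_all_zero(self):
        assert tf.k_core_levels(np.zeros((4, 4))) == {i: 0 for i in range(4)}

    def test_monotone_under_edge_removal(self):
        rng = np.random.default_rng(7)
        w = (rng.random((9, 9)) < 0.4).astype(float)
        np.fill_diagonal(w, 0)
        before = tf.k_core_levels(w)
        edges = np.argwhere(w > 0)
        for _ in range(5):
            w2 = w.copy()
            kill = edges[rng.integers(len(edges))]
            w2[kill[0], kill[1]] = 0.0
            after = tf.k_core_levels(w2)
            assert all(after[v] <= before[v] for v in before)


# ---------------------------------------------------------------------------
# partition comparison


class TestComparePartitions:
    def test_identical_partitions(self):
        p = Partition({c: ord(c) % 3 for c in "abcdefgh"}, 0.0, "manual")
        assert tf.compare_partitions(p, p) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons(self):
        nodes = list("abcdefgh")
        p1 = Partition({c: 0 for c in nodes}, 0.0, "manual")
        p2 = Partition({c: i for i, c in enumerate(nodes)}, 0.0, "manual")
        assert tf.compare_partitions(p1, p2) == pytest.approx(0.0)

    def test_random_independent_partitions_near_zero(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(200)]
        p1 = Partition(dict(zip(nodes, rng.integers(0, 4, 200))), 0.0, "manual")
        p2 = Partition(dict(zip(nodes, rng.integers(0, 4, 200))), 0.0, "manual")
        assert abs(tf.compare_partitions(p1, p2)) < 0.05

    def test_mismatched_sets_rejected(self):
        p1 = Partition({"a": 0, "b": 0}, 0.0, "manual")
        p2 = Partition({"a": 0, "c": 0}, 0.0, "manual")
        with pytest.raises(ValidationError):
            tf.compare_partitions(p1, p2)


# ---------------------------------------------------------------------------
# trade-tensor plumbing


class TestGraphFromTensor:
    def test_edges_match_tensor(self, small_data):
        _, _, tensor, _ = small_data
        year = tensor.years[0]
        g = graph_from_tensor(tensor, year)
        w = tensor.year_matrix(year)
        for i, u in enumerate(tensor.countries):
            for j, v in enumerate(tensor.countries):
                if i != j and w[i, j] > 0:
                    assert g[u][v]["weight"] == pytest.approx(w[i, j])
        assert g.number_of_edges() == int(np.count_nonzero(w))
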