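import itertools

import numpy as np
import pytest

from packsocial.obs_model import ObservationLog
from packsocial.socialnet import (
    DisconnectedNetworkError,
    SightingSummary,
    SocialNetwork,
    association_matrix,
    cooccurrence_counts,
    eigenvector_centrality,
    fast_greedy_partition,
    modularity_q,
)

from conftest import make_event, make_individual


def net_from_edges(n, edges, weights=None):
    ids = tuple(chr(ord("A") + i) for i in range(n))
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        val = 1.0 if weights is None else weights[k]
        w[i, j] = w[j, i] = val
    return SocialNetwork(ids=ids, weights=w)


def brute_force_modularity(weights, labels):
    """Literal double-sum oracle for Q."""
    a = np.asarray(weights, dtype=float)
    two_m = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [head]] + smaller[i + 1 :]
        yield smaller + [[head]]


def random_connected_weights(rng, n, p_edge=0.5):
    """Random symmetric weighted adjacency guaranteed connected."""
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # random spanning tree
        w[a, b] = w[b, a] = rng.uniform(0.5, 3.0)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] == 0 and rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.5, 3.0)
    return w


class TestCooccurrence:
    def _log(self, present_sets, roster_ids):
        roster = [
            make_individual(c, life_stage="juvenile" if c.startswith("P") else "adult")
            for c in roster_ids
        ]
        events = [
            make_event(f"R{i}", "social resting" if len(p) > 1 else "solitary resting",
                       min(p), present=p)
            for i, p in enumerate(present_sets)
        ]
        return ObservationLog(roster=roster, events=events)

    def test_single_shared_recording(self):
        log = self._log([{"A", "B"}], ["A", "B"])
        s = cooccurrence_counts(log, ("A", "B"))
        assert s.n.tolist() == [1, 1]
        assert s.x[0, 1] == 1

    def test_two_pups_in_one_recording_count_once_for_merged_node(self):
        log = self._log([{"P1", "P2"}], ["P1", "P2"])
        s = cooccurrence_counts(
            log, ("Pups",), collapse_map={"P1": "Pups", "P2": "Pups"}
        )
        assert s.n.tolist() == [1]

    def test_solo_recordings_give_zero_cooccurrence(self):
        log = self._log([{"A"}] * 10 + [{"B"}] * 10, ["A", "B"])
        s = cooccurrence_counts(log, ("A", "B"))
        assert s.n.tolist() == [10, 10]
        assert s.x[0, 1] == 0

    def test_empty_log_rejected(self):
        log = ObservationLog([make_individual("A")], [])
        with pytest.raises(ValueError):
            cooccurrence_counts(log, ("A",))


class TestAssociationIndex:
    def test_always_together_sri_is_one(self):
        s = SightingSummary(("A", "B"), np.array([[7, 7], [7, 7]]))
        net = association_matrix(s, "sri")
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_never_together_sri_is_zero(self):
        s = SightingSummary(("A", "B"), np.array([[5, 0], [0, 9]]))
        assert association_matrix(s, "sri").weights[0, 1] == 0.0

    def test_worked_sri_value(self):
        s = SightingSummary(("A", "B"), np.array([[10, 5], [5, 10]]))
        net = association_matrix(s, "sri")
        assert net.weights[0, 1] == pytest.approx(5 / 15, abs=1e-12)

    def test_count_weights_are_the_cooccurrence_counts(self):
        s = SightingSummary(("A", "B"), np.array([[10, 5], [5, 10]]))
        assert association_matrix(s, "count").weights[0, 1] == 5.0


class TestEigenvectorCentrality:
    def test_complete_graph_all_ones(self):
        net = net_from_edges(4, list(itertools.combinations(range(4), 2)))
        scores = eigenvector_centrality(net)
        assert np.allclose(scores.scores, 1.0, atol=1e-9)

    def test_star_graph_closed_form(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        scores = eigenvector_centrality(net)
        assert scores.scores[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(scores.scores[1:], 1 / np.sqrt(3), atol=1e-9)

    def test_disconnected_network_is_an_error(self):
        net = net_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(DisconnectedNetworkError):
            eigenvector_centrality(net)

    def test_largest_component_restriction(self):
        net = net_from_edges(5, [(0, 1), (1, 2), (3, 4)])
        scores = eigenvector_centrality(net, largest_component=True)
        assert set(scores.ids) == {"A", "B", "C"}

    def test_all_zero_weights_rejected(self):
        net = SocialNetwork(("A", "B"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            eigenvector_centrality(net)

    def test_agrees_with_full_eigendecomposition(self, rng):
        for n in (4, 8, 13, 20):
            w = random_connected_weights(rng, n)
            ids = tuple(f"N{i}" for i in range(n))
            scores = eigenvector_centrality(SocialNetwork(ids, w))
            vals, vecs = np.linalg.eigh(w)
            lead = np.abs(vecs[:, np.argmax(vals)])
            lead = lead / lead.max()
            assert np.max(np.abs(np.array(scores.scores) - lead)) < 1e-8

    def test_weight_scaling_invariance(self, rng):
        w = random_connected_weights(rng, 9)
        ids = tuple(f"N{i}" for i in range(9))
        a = eigenvector_centrality(SocialNetwork(ids, w))
        b = eigenvector_centrality(SocialNetwork(ids, w * 37.5))
        assert np.allclose(a.scores, b.scores, atol=1e-9)


class TestModularity:
    def test_single_community_is_zero(self, rng):
        w = random_connected_weights(rng, 6)
        net = SocialNetwork(tuple("ABCDEF"), w)
        part = {c: 0 for c in net.ids}
        assert modularity_q(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_triangles_true_split(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        net = net_from_edges(6, edges)
        part = {c: (0 if i < 3 else 1) for i, c in enumerate(net.ids)}
        assert modularity_q(net, part) == pytest.approx(0.5, abs=1e-9)

    def test_single_edge_singletons(self):
        net = net_from_edges(2, [(0, 1)])
        assert modularity_q(net, {"A": 0, "B": 1}) == pytest.approx(-0.5, abs=1e-9)

    def test_agrees_with_brute_force_double_sum(self, rng):
        for n in (3, 6, 9, 12):
            w = random_connected_weights(rng, n)
            ids = tuple(f"N{i}" for i in range(n))
            net = SocialNetwork(ids, w)
            labels = rng.integers(0, 3, size=n)
            part = {ids[i]: int(labels[i]) for i in range(n)}
            expected = brute_force_modularity(w, labels)
            assert modularity_q(net, part) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_networkx(self, rng):
        import networkx as nx

        w = random_connected_weights(rng, 10)
        ids = tuple(f"N{i}" for i in range(10))
        net = SocialNetwork(ids, w)
        g = nx.Graph()
        g.add_nodes_from(ids)
        for a, b, weight in net.edges():
            g.add_edge(a, b, weight=weight)
        labels = rng.integers(0, 3, size=10)
        part = {ids[i]: int(labels[i]) for i in range(10)}
        comms = [
            {ids[i] for i in range(10) if labels[i] == c}
            for c in sorted(set(labels.tolist()))
        ]
        comms = [c for c in comms if c]
        expected = nx.community.modularity(g, comms, weight="weight")
        assert modularity_q(net, part) == pytest.approx(expected, abs=1e-10)


class TestFastGreedy:
    def test_bridged_triangles_recovered(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        net = net_from_edges(6, edges)
        part, dend = fast_greedy_partition(net)
        assert part.communities() == [
            frozenset({"A", "B", "C"}),
            frozenset({"D", "E", "F"}),
        ]
        assert part.q == pytest.approx(max(dend.q_trace), abs=1e-12)

    def test_single_edge_trace(self):
        net = net_from_edges(2, [(0, 1)])
        part, dend = fast_greedy_partition(net)
        assert dend.q_trace == (-0.5, 0.0)
        assert part.n_communities() == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_complete_graph_single_community(self):
        net = net_from_edges(4, list(itertools.combinations(range(4), 2)))
        part, _ = fast_greedy_partition(net)
        assert part.n_communities() == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_greedy_matches_exhaustive_on_planted_two_clique_graphs(self):
        for size_a, size_b in [(3, 3), (4, 3), (4, 4)]:
            n = size_a + size_b
            edges = (
                list(itertools.combinations(range(size_a), 2))
                + list(itertools.combinations(range(size_a, n), 2))
                + [(size_a - 1, size_a)]  # single bridge
            )
            net = net_from_edges(n, edges)
            part, _ = fast_greedy_partition(net)
            best_q = -np.inf
            for blocks in all_partitions(range(n)):
                labels = np.empty(n, dtype=int)
                for c, block in enumerate(blocks):
                    labels[list(block)] = c
                best_q = max(best_q, brute_force_modularity(net.weights, labels))
            assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_partition_q_at_least_all_in_one(self, rng):
        for _ in range(5):
            w = random_connected_weights(rng, 8)
            net = SocialNetwork(tuple(f"N{i}" for i in range(8)), w)
            part, dend = fast_greedy_partition(net)
            assert part.q >= -1e-12  # all-in-one (Q = 0) is always in the trace
            assert dend.q_trace[-1] == pytest.approx(0.0, abs=1e-9)

    def test_weight_scaling_leaves_partition_and_q_unchanged(self, rng):
        w = random_connected_weights(rng, 8)
        ids = tuple(f"N{i}" for i in range(8))
        p1, _ = fast_greedy_partition(SocialNetwork(ids, w))
        p2, _ = fast_greedy_partition(SocialNetwork(ids, w * 11.0))
        assert p1.communities() == p2.communities()
        assert p1.q == pytest.approx(p2.q, abs=1e-9)

    def test_strong_structure_flag_tracks_threshold(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        part, _ = fast_greedy_partition(net_from_edges(6, edges))
        assert part.strong_structure  # Q ≈ 0.357 > 0.3
        part2, _ = fast_greedy_partition(net_from_edges(2, [(0, 1)]))
        assert not part2.strong_structure

    def test_disconnected_network_is_an_error(self):
        with pytest.raises(DisconnectedNetworkError):
            fast_greedy_partition(net_from_edges(4, [(0, 1), (2, 3)]))
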