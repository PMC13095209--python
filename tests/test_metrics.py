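"""Graph metrics: strengths, reciprocal-weight paths, endpoint-inclusive
betweenness, sub-network extraction, ranking and the statistical helpers."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import brute_betweenness, brute_inventory, random_graph
from wormnet.metrics import (
    average_path_length,
    betweenness,
    compare_groups,
    edge_weights,
    fit_exponential,
    metric_difference,
    node_strengths,
    rank_top,
    sex_shared_subnetwork,
    sex_specific_subnetwork,
    shortest_paths,
    strength_dict,
)


class TestStrengths:
    def test_worked_example_strengths(self, worked_net):
        by_node = {m.node: m for m in node_strengths(worked_net)}
        assert (by_node["A"].strength, by_node["A"].out_strength, by_node["A"].in_strength) == (8, 5, 3)
        assert (by_node["D"].strength, by_node["D"].out_strength, by_node["D"].in_strength) == (10, 4, 6)

    def test_isolated_node_scores_zero(self):
        G = nx.DiGraph()
        G.add_node("X")
        (m,) = node_strengths(G)
        assert (m.strength, m.out_strength, m.in_strength) == (0, 0, 0)

    def test_strength_sums_tie_to_total_weight(self, worked_net):
        ms = node_strengths(worked_net)
        total = sum(w for _, _, w in worked_net.edges(data="weight"))
        assert sum(m.out_strength for m in ms) == total == 17
        assert sum(m.in_strength for m in ms) == total
        assert sum(m.strength for m in ms) == 2 * total == 34


class TestEdgeWeights:
    def test_worked_example_edges(self, worked_net):
        assert dict(((u, v), w) for u, v, w in edge_weights(worked_net)) == {
            ("A", "B"): 2, ("A", "D"): 3, ("B", "C"): 2, ("B", "D"): 2,
            ("C", "A"): 3, ("C", "D"): 1, ("D", "B"): 4,
        }

    def test_empty_network(self):
        assert edge_weights(nx.DiGraph()) == []


class TestShortestPaths:
    def test_worked_example_b_to_d(self, worked_net):
        inv = shortest_paths(worked_net)
        (p,) = [p for p in inv.paths if (p.src, p.dst) == ("B", "D")]
        assert p.nodes == ("B", "D")
        assert p.length == Fraction(1, 2)

    def test_worked_example_has_twelve_paths(self, worked_net):
        inv = shortest_paths(worked_net)
        assert len(inv) == 12
        assert inv.unreachable_pairs == 0

    def test_single_edge_and_unreachable_pair(self):
        G = nx.DiGraph()
        G.add_edge("A", "B", weight=4)
        inv = shortest_paths(G)
        assert len(inv) == 1
        assert inv.paths[0].length == Fraction(1, 4)
        assert inv.unreachable_pairs == 1

    def test_length_recomputes_from_weights(self, worked_net):
        for p in shortest_paths(worked_net).paths:
            recomputed = sum(
                Fraction(1, worked_net.edges[u, v]["weight"])
                for u, v in zip(p.nodes, p.nodes[1:])
            )
            assert recomputed == p.length

    def test_all_cominimal_paths_stored_on_tie(self):
        G = nx.DiGraph()
        G.add_edge("A", "B", weight=1)
        G.add_edge("A", "C", weight=2)
        G.add_edge("C", "B", weight=2)  # A->C->B also length 1
        inv = shortest_paths(G)
        ab = [p.nodes for p in inv.paths if (p.src, p.dst) == ("A", "B")]
        assert sorted(ab) == [("A", "B"), ("A", "C", "B")]
        single = shortest_paths(G, ties="single")
        ab1 = [p.nodes for p in single.paths if (p.src, p.dst) == ("A", "B")]
        assert ab1 == [("A", "B")]

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            G = random_graph(rng)
            inv = shortest_paths(G)
            pairs, unreachable = brute_inventory(G)
            assert inv.unreachable_pairs == unreachable
            got = {}
            for p in inv.paths:
                got.setdefault((p.src, p.dst), (p.length, set()))[1].add(p.nodes)
                assert p.length == pairs[(p.src, p.dst)][0]
            assert {k: v[1] for k, v in got.items()} == {k: v[1] for k, v in pairs.items()}


class TestBetweenness:
    def test_worked_example_values(self, worked_net):
        b = betweenness(worked_net)
        assert b["D"] == Fraction(1, 2)
        assert b["A"] == Fraction(8, 12)

    def test_star_hub_on_every_path(self):
        G = nx.DiGraph()
        for leaf in ("a", "b", "c"):
            G.add_edge(leaf, "hub", weight=1)
            G.add_edge("hub", leaf, weight=1)
        assert betweenness(G)["hub"] == 1

    def test_empty_inventory_is_signalled(self):
        G = nx.DiGraph()
        G.add_node("X")
        with pytest.raises(ValueError, match="empty"):
            betweenness(G)

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            G = random_graph(rng)
            if not any(True for _ in G.edges):
                continue
            assert betweenness(G) == brute_betweenness(G)
            checked += 1
        assert checked > 20


def flagged(pairs):
    G = nx.DiGraph()
    for n, spec in pairs.items():
        G.add_node(n, sex_specific=spec)
    return G


class TestSubnetworks:
    def test_specific_node_pulls_in_direct_neighbors_only(self):
        G = flagged({"s": True, "x": False, "y": False, "z": False})
        G.add_edge("s", "x", weight=1)
        G.add_edge("y", "s", weight=2)
        G.add_edge("y", "z", weight=1)
        sub = sex_specific_subnetwork(G)
        assert set(sub.nodes) == {"s", "x", "y"}
        # induced edges include shared-shared edges within the kept set
        assert set(sub.edges) == {("s", "x"), ("y", "s")}

    def test_all_specific_is_identity(self):
        G = flagged({"a": True, "b": True})
        G.add_edge("a", "b", weight=3)
        sub = sex_specific_subnetwork(G)
        assert nx.utils.graphs_equal(sub, G)

    def test_no_specific_warns_and_returns_empty(self):
        G = flagged({"a": False})
        with pytest.warns(UserWarning):
            sub = sex_specific_subnetwork(G)
        assert sub.number_of_nodes() == 0

    def test_shared_subnetwork_is_induced_restriction(self):
        from wormnet.connectome import build_network
        from wormnet.synthetic import SyntheticSpec, generate

        table, merge, _ = generate(SyntheticSpec(n_nodes=50, seed=3))
        net = build_network(table, merge)
        sub = sex_shared_subnetwork(net)
        shared = {n for n, d in net.nodes(data=True) if not d["sex_specific"]}
        assert set(sub.nodes) == shared
        expected = {(u, v): w for u, v, w in net.edges(data="weight")
                    if u in shared and v in shared}
        assert {(u, v): w for u, v, w in sub.edges(data="weight")} == expected

    def test_specific_neighborhood_matches_bruteforce_scan(self):
        from wormnet.connectome import build_network
        from wormnet.synthetic import SyntheticSpec, generate

        table, merge, _ = generate(SyntheticSpec(n_nodes=50, seed=5))
        net = build_network(table, merge)
        sub = sex_specific_subnetwork(net)
        specific = {n for n, d in net.nodes(data=True) if d["sex_specific"]}
        expected = set(specific)
        for u, v in net.edges:
            if u in specific:
                expected.add(v)
            if v in specific:
                expected.add(u)
        assert set(sub.nodes) == expected

    def test_extraction_idempotent(self):
        G = flagged({"s": True, "x": False})
        G.add_edge("s", "x", weight=1)
        once = sex_specific_subnetwork(G)
        twice = sex_specific_subnetwork(once)
        assert nx.utils.graphs_equal(once, twice)


class TestMetricDifference:
    def test_identical_networks_give_zero(self, worked_net):
        d = metric_difference(worked_net, worked_net, "strength")
        assert set(d) == set(worked_net.nodes)
        assert all(v == 0 for v in d.values())

    def test_single_edge_perturbation_shifts_strength(self, worked_net):
        other = worked_net.copy()
        other.edges["A", "B"]["weight"] += 2
        d = metric_difference(other, worked_net, "strength")
        assert d["A"] == 2 and d["B"] == 2 and d["C"] == 0 and d["D"] == 0

    def test_domain_is_intersection(self, worked_net):
        other = worked_net.subgraph(["A", "B", "C"]).copy()
        d = metric_difference(worked_net, other, "strength")
        assert set(d) == {"A", "B", "C"}

    def test_disjoint_networks_warn(self):
        g1, g2 = nx.DiGraph(), nx.DiGraph()
        g1.add_node("a")
        g2.add_node("b")
        with pytest.warns(UserWarning):
            assert metric_difference(g1, g2, "strength") == {}

    def test_edge_weight_difference_keyed_by_edge(self, worked_net):
        other = worked_net.copy()
        other.edges["D", "B"]["weight"] = 1
        d = metric_difference(worked_net, other, "edge_weight")
        assert d[("D", "B")] == 3
        assert all(v == 0 for k, v in d.items() if k != ("D", "B"))


class TestRankTop:
    def test_tie_at_top_breaks_by_name(self, worked_net):
        values = strength_dict(worked_net)
        assert rank_top(values, 1) == ["B"]  # B and D tie at 10

    def test_full_ordering(self, worked_net):
        assert rank_top(strength_dict(worked_net), 4) == ["B", "D", "A", "C"]

    def test_all_equal_gives_lexicographic(self):
        assert rank_top({"c": 1, "a": 1, "b": 1}, 3) == ["a", "b", "c"]

    def test_truncates_with_warning(self):
        with pytest.warns(UserWarning):
            assert rank_top({"a": 1}, 5) == ["a"]

    @given(st.permutations(["w", "x", "y", "z"]))
    def test_deterministic_under_input_order(self, order):
        base = {"w": 3.0, "x": 3.0, "y": 1.0, "z": 5.0}
        values = {k: base[k] for k in order}
        assert rank_top(values, 3) == ["z", "w", "x"]


class TestStatistics:
    def test_exponential_rate_recovered_within_sampling_error(self):
        rng = np.random.default_rng(0)
        values = rng.exponential(scale=10.0, size=500)  # rate 0.1
        fit = fit_exponential(values)
        assert abs(fit.rate - 0.1) / 0.1 < 0.15
        assert fit.p_value > 0.01

    def test_constant_values_rejected_by_ks(self):
        fit = fit_exponential([2.0] * 50)
        assert fit.p_value < 0.01

    def test_too_few_or_nonpositive_values_error(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0])
        with pytest.raises(ValueError):
            fit_exponential([1.0, -1.0, 2.0, 3.0, 4.0])

    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r = compare_groups(a, list(a))
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_tiny_variance_is_significant(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0.0, 1e-3, size=10)
        r = compare_groups(b + 10.0, b)
        assert r.p_value < 1e-6
        assert r.mean_a - r.mean_b == pytest.approx(10.0, abs=1e-3)

    def test_minimal_groups_run_and_small_ones_error(self):
        compare_groups([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestAveragePathLength:
    def test_group_restriction_uses_either_endpoint(self, worked_net):
        inv = shortest_paths(worked_net)
        overall = average_path_length(inv)
        only_d = average_path_length(inv, involving={"D"})
        lengths = inv.pair_lengths()
        expected = np.mean([float(v) for (s, t), v in lengths.items() if "D" in (s, t)])
        assert only_d == pytest.approx(expected)
        assert overall == pytest.approx(np.mean([float(v) for v in lengths.values()]))
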