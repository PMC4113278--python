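"""Topology measures against brute-force oracles; hub screening rules."""

import networkx as nx
import numpy as np
import pytest

from oracles import (
    brute_betweenness,
    brute_closeness,
    brute_k_values,
    brute_median,
    random_graph_edges,
    to_adjacency,
)

from netpharm.synthetic import SimConfig, gen_ppi_network
from netpharm.topology import (
    betweenness,
    closeness,
    identify_hubs,
    identify_major_hubs,
    k_core,
    node_topology_table,
)


class TestBetweenness:
    def test_star_center(self):
        graph = nx.star_graph(4)
        values = betweenness(graph)
        assert values[0].raw == 6.0          # all C(4,2) leaf pairs
        assert values[0].normalized == 1.0
        assert all(values[leaf].raw == 0.0 for leaf in range(1, 5))

    def test_path_middle_node(self):
        graph = nx.path_graph(3)
        assert betweenness(graph)[1].raw == 1.0

    def test_disconnected_pairs_contribute_nothing(self):
        graph = nx.Graph([(0, 1), (2, 3)])
        assert all(v.raw == 0.0 for v in betweenness(graph).values())


class TestCloseness:
    def test_path_middle_is_half(self):
        graph = nx.path_graph(3)
        assert closeness(graph)[1].literal == 0.5

    def test_dyad_nodes_are_one(self):
        graph = nx.path_graph(2)
        values = closeness(graph)
        assert values[0].literal == 1.0 and values[0].scaled == 1.0

    def test_isolated_node_is_zero(self):
        graph = nx.Graph()
        graph.add_node("x")
        assert closeness(graph)["x"] == (0.0, 0.0)


class TestKCore:
    def test_triangle_with_pendant(self):
        graph = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])
        values = k_core(graph)
        assert values[0] == values[1] == values[2] == 2
        assert values[3] == 1

    def test_tree_is_one_core(self):
        tree = nx.random_labeled_tree(10, seed=5)
        assert set(k_core(tree).values()) == {1}

    def test_singleton_is_zero(self):
        graph = nx.Graph()
        graph.add_node(0)
        assert k_core(graph)[0] == 0


class TestOracleAgreement:
    def test_measures_match_brute_force_on_random_graphs(self):
        """Exhaustive-enumeration agreement over all edge densities."""
        rng = np.random.default_rng(20240901)
        for trial in range(60):
            n = int(rng.integers(2, 9))
            p = float(rng.random())
            edges, nodes = random_graph_edges(rng, n, p)
            adj = to_adjacency(edges, nodes)
            graph = nx.Graph()
            graph.add_nodes_from(nodes)
            graph.add_edges_from(edges)

            btw = betweenness(graph)
            for node, expected in brute_betweenness(adj).items():
                assert btw[node].raw == pytest.approx(expected, abs=1e-9)
            cls = closeness(graph)
            for node, expected in brute_closeness(adj).items():
                assert cls[node].literal == pytest.approx(expected, abs=1e-12)
            assert k_core(graph) == brute_k_values(adj)

    def test_degree_sum_and_invariant_bounds(self):
        rng = np.random.default_rng(7)
        edges, nodes = random_graph_edges(rng, 8, 0.4)
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        graph.add_edges_from(edges)
        assert sum(d for _, d in graph.degree()) == 2 * graph.number_of_edges()
        table = node_topology_table(graph)
        assert ((table["betweenness_norm"] >= 0)
                & (table["betweenness_norm"] <= 1)).all()
        assert (table["k_value"] <= table["degree"]).all()

    def test_k_core_monotone_under_edge_addition(self):
        graph = nx.path_graph(6)
        before = k_core(graph)
        graph.add_edge(0, 2)
        graph.add_edge(3, 5)
        after = k_core(graph)
        assert all(after[n] >= before[n] for n in graph.nodes)


class TestHubRules:
    def test_star_center_is_only_hub(self):
        screen = identify_hubs(nx.star_graph(4))
        assert screen.median_degree == 1
        assert screen.hubs == {0}

    def test_three_path_has_no_hubs(self):
        assert identify_hubs(nx.path_graph(3)).hubs == set()

    def test_strictness_at_exactly_twice_median(self):
        # degrees 1,1,1,1,2,2: median 1; degree 2 is not > 2
        graph = nx.Graph([(0, 1), (2, 3), (4, 0), (4, 2)])
        assert identify_hubs(graph).hubs == set()

    def test_planted_hubs_recovered_on_scale_free_graph(self):
        config = SimConfig(seed=11, n_proteins=500, planted_hub_count=4)
        graph, manifest = gen_ppi_network(config)
        screen = identify_hubs(graph, config.hub_factor)
        assert set(manifest["planted_hubs"]) <= screen.hubs

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            identify_hubs(nx.Graph())


class TestMajorHubRules:
    def test_dominating_node_is_major_hub(self):
        # triangle (0,1,2) plus pendants on 0: node 0 strictly exceeds
        # the median on degree, betweenness, closeness and k value
        graph = nx.Graph(
            [(0, 1), (1, 2), (2, 0), (0, 3), (0, 4), (0, 5)]
        )
        screen = identify_major_hubs(graph, screen=set(graph.nodes))
        assert screen.major_hubs == {0}

    def test_identical_metrics_yield_no_major_hubs(self):
        graph = nx.cycle_graph(6)  # all four measures identical
        screen = identify_major_hubs(graph, screen=set(graph.nodes))
        assert screen.major_hubs == set()

    def test_major_hubs_subset_of_hubs(self):
        graph = nx.barabasi_albert_graph(120, 2, seed=3)
        screen = identify_major_hubs(graph)
        assert screen.major_hubs <= screen.hubs

    def test_matches_exhaustive_median_evaluation(self):
        """12-node hub subgraph: four-median rule checked by hand."""
        rng = np.random.default_rng(99)
        edges, nodes = random_graph_edges(rng, 12, 0.35)
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        graph.add_edges_from(edges)
        hubs = set(nodes)
        screen = identify_major_hubs(
            graph, screen=hubs,
            betweenness_variant="raw", closeness_variant="literal",
        )
        adj = to_adjacency(edges, nodes)
        metrics = {
            node: (
                len(adj[node]),
                brute_betweenness(adj)[node],
                brute_closeness(adj)[node],
                brute_k_values(adj)[node],
            )
            for node in nodes
        }
        medians = tuple(
            brute_median([m[i] for m in metrics.values()]) for i in range(4)
        )
        expected = {
            node
            for node, values in metrics.items()
            if all(v > m for v, m in zip(values, medians))
        }
        assert screen.major_hubs == expected

    def test_literal_threshold_overrides(self):
        graph = nx.barabasi_albert_graph(60, 2, seed=1)
        screen = identify_major_hubs(
            graph, thresholds={"degree": 3, "k_value": 3}
        )
        assert screen.thresholds["degree"] == 3
        for node in screen.major_hubs:
            assert screen.hub_table.at[node, "degree"] > 3
            assert screen.hub_table.at[node, "k_value"] > 3

    def test_empty_hub_set_empty_result(self):
        screen = identify_major_hubs(nx.path_graph(3), screen=set())
        assert screen.major_hubs == set()
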