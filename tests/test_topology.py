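"""Topology statistics: density convention, neighbours, paths, fits, hubs."""

import math

import networkx as nx
import numpy as np
import pytest

from bowtiemap.model import TypedEdge
from bowtiemap.synth import GeneratorConfig, generate_network
from bowtiemap.topology import (
    DegreeDistribution,
    UndefinedStatisticError,
    degree_distribution,
    fit_power_law,
    identify_hubs,
    mean_distinct_neighbors,
    network_density,
    report_row,
    round_half_up,
    shortest_path_stats,
    topology_report,
)

from conftest import build_graph

# printed (N, E, density) rows whose density is consistent with 2E/(N(N-1))
# under round-half-up at 3 decimals
DENSITY_BATTERY = [
    (776, 886, 0.003),   # whole map
    (12, 16, 0.242),     # module-scale
    (11, 11, 0.2),
    (4, 4, 0.667),
    (20, 23, 0.121),
    (53, 59, 0.043),
    (6, 6, 0.4),
    (450, 428, 0.004),   # tissue-scale
    (50, 30, 0.024),
    (301, 236, 0.005),
    (16, 10, 0.083),
]


class TestDensity:
    @pytest.mark.parametrize("n,e,expected", DENSITY_BATTERY)
    def test_reproduces_printed_values(self, n, e, expected):
        assert round_half_up(network_density(n, e), 3) == expected

    def test_saturated_pair(self):
        assert network_density(2, 1) == 1.0

    def test_undefined_below_two_nodes(self):
        with pytest.raises(UndefinedStatisticError):
            network_density(1, 0)


class TestNeighbors:
    def test_no_reciprocal_pairs_equals_mean_degree(self):
        g, _ = generate_network(GeneratorConfig(seed=3, n_species=60))
        got = mean_distinct_neighbors(g)
        assert got == pytest.approx(2 * g.edge_count / g.node_count)

    def test_reciprocal_pair_counts_once(self):
        g = build_graph(edges=[("A", "B"), ("B", "A")])
        assert mean_distinct_neighbors(g) == 1.0

    def test_star_hand_count(self):
        g = build_graph(edges=[("C", f"L{i}") for i in range(5)])
        assert mean_distinct_neighbors(g) == pytest.approx(10 / 6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_never_exceeds_mean_total_degree(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(12)]
        edges = [(nodes[i], nodes[j]) for i in range(12) for j in range(12)
                 if i != j and rng.random() < 0.3]
        g = build_graph(edges=edges, nodes=nodes)
        assert mean_distinct_neighbors(g) <= 2 * g.edge_count / g.node_count + 1e-12


class TestPaths:
    def test_directed_path_hand_enumeration(self):
        g = build_graph(edges=[("A", "B"), ("B", "C")])
        mean, var, dia = shortest_path_stats(g)
        assert mean == pytest.approx(4 / 3)
        assert dia == 2

    def test_three_cycle_bfs_oracle(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "A")])
        mean, var, dia = shortest_path_stats(g)
        assert mean == pytest.approx(1.5)
        assert dia == 2

    def test_unreachable_pairs_excluded(self):
        g = build_graph(edges=[("A", "B"), ("C", "D")])
        mean, var, dia = shortest_path_stats(g)
        assert mean == 1.0 and dia == 1

    def test_no_reachable_pair_is_error(self):
        g = build_graph(nodes=["A", "B"])
        with pytest.raises(UndefinedStatisticError):
            shortest_path_stats(g)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_diameter_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(40)]
        edges = [(nodes[i], nodes[j]) for i in range(40) for j in range(40)
                 if i != j and rng.random() < 0.06]
        g = build_graph(edges=edges, nodes=nodes)
        nxg = nx.DiGraph(edges)
        oracle = max(
            d for _, ls in nx.all_pairs_shortest_path_length(nxg)
            for d in ls.values()
        )
        mean, _, dia = shortest_path_stats(g)
        assert dia == oracle
        assert dia >= math.ceil(mean) - 1


class TestPowerLaw:
    @pytest.mark.parametrize("gamma", [1.5, 2.0, 3.0])
    def test_exact_on_noiseless_input(self, gamma):
        # degrees 4^i with base 4096 keep f(k) = 4096 k^-gamma integral
        points = tuple((k, int(4096 * k ** -gamma)) for k in (1, 4, 16))
        dist = DegreeDistribution(direction="out", points=points)
        fit = fit_power_law(dist)
        assert fit.exponent == pytest.approx(gamma, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_point_absent(self):
        dist = DegreeDistribution(direction="in", points=((3, 7),))
        assert fit_power_law(dist) is None

    def test_zero_degree_nodes_never_enter(self):
        g = build_graph(edges=[("A", "B")], nodes=["Iso1", "Iso2"])
        dist = degree_distribution(g, "out")
        assert dist.zero_degree_count == 3  # B, Iso1, Iso2
        assert all(k >= 1 for k, _ in dist.points)

    def test_generator_target_recovered(self):
        g, truth = generate_network(
            GeneratorConfig(seed=42, n_species=2000, gamma_target=2.5))
        fit = fit_power_law(degree_distribution(g, "out", species_only=True))
        assert abs(fit.exponent - 2.5) <= 0.4


class TestHubs:
    def test_star_center_found(self):
        g = build_graph(edges=[("C", f"L{i}") for i in range(5)])
        assert identify_hubs(g, "out", 3) == ["C"]

    def test_all_below_threshold_empty(self):
        g = build_graph(edges=[("A", "B"), ("B", "C")])
        assert identify_hubs(g, "out", 3) == []

    def test_reaction_nodes_excluded(self):
        g = build_graph(edges=[("re1", f"L{i}") for i in range(5)])
        assert identify_hubs(g, "out", 3) == []

    def test_planted_hub_recovered(self):
        g, truth = generate_network(
            GeneratorConfig(seed=8, n_species=300, max_out_degree=3,
                            n_hubs=1, hub_out_degree=10))
        assert identify_hubs(g, "out", 3) == truth.planted_hubs


class TestReport:
    def test_four_node_cycle_row(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        rep = topology_report(g)
        assert (rep.n_nodes, rep.n_edges, rep.components) == (4, 4, 1)
        assert round_half_up(rep.density, 3) == 0.667
        row = report_row(rep, "Mod 8")
        assert row["Den"] == "0.667"
        assert row["Din"] == "na" and row["Rout"] == "na"

    def test_empty_graph_all_absent(self):
        g = build_graph()
        rep = topology_report(g)
        assert rep.n_nodes == 0 and rep.density is None and rep.fit_in is None

    def test_synthetic_row_matches_generator_bookkeeping(self):
        g, truth = generate_network(GeneratorConfig(seed=13, n_species=150))
        rep = topology_report(g)
        assert rep.n_nodes == g.node_count
        # structural out-degrees survive reaction expansion
        out_deg = {
            nid: sum(1 for e in g.edges.values() if e.source == nid)
            for nid in g.species_ids()
        }
        assert out_deg == truth.out_degree_sequence
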