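"""Relevant cycles against a minimum-cycle-basis matroid oracle.

Oracle route: enumerate all simple cycles, then use the matroid fact that an
element belongs to some minimum-weight basis iff the minimum-weight basis
forced to contain it matches the global minimum weight.  The implementation
route (graded independence against strictly shorter cycles) never appears in
the oracle.
"""

import networkx as nx
import numpy as np
import pytest

from bowtiemap.bowtie import classify_bowtie
from bowtiemap.cycles import (
    cycles_for_center,
    relevant_cycle_set,
    undirected_projection,
)

from conftest import build_graph


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------

def _edge_vectors(ug):
    idx = {frozenset(e): i for i, e in enumerate(ug.edges())}
    vecs = []
    for walk in nx.simple_cycles(ug):
        v = 0
        for i in range(len(walk)):
            v |= 1 << idx[frozenset((walk[i], walk[(i + 1) % len(walk)]))]
        vecs.append((bin(v).count("1"), v))
    return sorted(vecs)


def _greedy_weight(cycles_sorted, nu, forced=None):
    """Weight of a minimum cycle basis, optionally forced to contain one cycle."""
    rows = {}
    weight = 0
    rank = 0

    def insert(vec):
        nonlocal weight, rank
        w, v = vec
        while v:
            piv = v.bit_length() - 1
            if piv in rows:
                v ^= rows[piv]
            else:
                rows[piv] = v
                weight += w
                rank += 1
                return True
        return False

    if forced is not None and not insert(forced):
        return None
    for vec in cycles_sorted:
        if rank == nu:
            break
        insert(vec)
    return weight if rank == nu else None


def oracle_relevant_cycles(ug):
    """Edge-vector set of the union of all minimum cycle bases."""
    cycles = _edge_vectors(ug)
    nu = ug.number_of_edges() - ug.number_of_nodes() + \
        nx.number_connected_components(ug)
    if nu == 0:
        return set()
    best = _greedy_weight(cycles, nu)
    out = set()
    for wv in cycles:
        if _greedy_weight(cycles, nu, forced=wv) == best:
            out.add(wv[1])
    return out


def _implementation_vectors(ug):
    idx = {frozenset(e): i for i, e in enumerate(ug.edges())}
    out = set()
    for rec in relevant_cycle_set(ug):
        v = 0
        for e in rec.edges:
            v |= 1 << idx[e]
        out.add(v)
    return out


# ---------------------------------------------------------------------------
# examples
# ---------------------------------------------------------------------------

class TestExamples:
    def test_triangle_single_cycle(self):
        ug = nx.cycle_graph(3)
        recs = relevant_cycle_set(ug)
        assert len(recs) == 1 and recs[0].length == 3

    def test_two_triangles_sharing_edge_exclude_perimeter(self):
        ug = nx.Graph([(0, 1), (1, 2), (2, 0), (1, 3), (3, 2)])
        recs = relevant_cycle_set(ug)
        assert sorted(r.length for r in recs) == [3, 3]

    def test_k4_all_four_triangles_relevant(self):
        recs = relevant_cycle_set(nx.complete_graph(4))
        assert sorted(r.length for r in recs) == [3, 3, 3, 3]

    def test_theta_graph_all_three_faces(self):
        # two hubs joined by internally disjoint paths of 2, 2 and 3 edges
        ug = nx.Graph([("u", "a"), ("a", "v"), ("u", "b"), ("b", "v"),
                       ("u", "c"), ("c", "d"), ("d", "v")])
        recs = relevant_cycle_set(ug)
        assert sorted(r.length for r in recs) == [4, 5, 5]
        assert _implementation_vectors(ug) == oracle_relevant_cycles(ug)

    def test_acyclic_input_empty(self):
        assert relevant_cycle_set(nx.path_graph(5)) == []

    def test_deterministic_ordering(self):
        ug = nx.complete_graph(5)
        first = relevant_cycle_set(ug)
        second = relevant_cycle_set(ug)
        assert [r.nodes for r in first] == [r.nodes for r in second]
        lengths = [r.length for r in first]
        assert lengths == sorted(lengths)

    def test_count_at_least_cyclomatic_number(self):
        for ug in (nx.complete_graph(5), nx.petersen_graph(),
                   nx.circular_ladder_graph(4)):
            nu = ug.number_of_edges() - ug.number_of_nodes() + 1
            assert len(relevant_cycle_set(ug)) >= nu


class TestProjection:
    def test_antiparallel_pair_collapses(self):
        g = build_graph(edges=[("A", "B"), ("B", "A")])
        ug = undirected_projection(g)
        assert ug.number_of_edges() == 1

    def test_directed_triangle_projects_to_triangle(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "A")])
        ug = undirected_projection(g)
        assert nx.is_isomorphic(ug, nx.cycle_graph(3))

    def test_self_loop_dropped(self):
        g = build_graph(edges=[("A", "A"), ("A", "B"), ("B", "A")])
        ug = undirected_projection(g)
        assert not list(nx.selfloop_edges(ug))


class TestCyclesForCenter:
    def test_single_triangle_center(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "A"), ("X", "A")])
        bt = classify_bowtie(g)
        recs = cycles_for_center(g, bt)
        assert len(recs) == 1 and recs[0].node_set() == {"A", "B", "C"}

    def test_disjoint_sccs_tagged(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "A"),
                               ("X", "Y"), ("Y", "Z"), ("Z", "X")])
        recs = cycles_for_center(g, bt := classify_bowtie(g))
        assert len(recs) == 2
        assert sorted(r.scc_index for r in recs) == [0, 1]


def test_oracle_agreement_named_graphs():
    """Union of all minimum cycle bases on a battery of structured graphs."""
    graphs = [
        nx.complete_graph(4),
        nx.complete_graph(5),
        nx.complete_bipartite_graph(2, 3),
        nx.complete_bipartite_graph(3, 3),
        nx.cycle_graph(6),
        nx.circular_ladder_graph(3),
        nx.cubical_graph(),
        nx.wheel_graph(5),
        nx.lollipop_graph(4, 3),
    ]
    for ug in graphs:
        assert _implementation_vectors(ug) == oracle_relevant_cycles(ug)


@pytest.mark.parametrize("batch", range(4))
def test_oracle_agreement_random_graphs(batch):
    """Seeded random graphs with <= 9 nodes and <= 14 edges."""
    rng = np.random.default_rng(777 + batch)
    done = 0
    while done < 40:
        n = int(rng.integers(4, 10))
        m = int(rng.integers(n, 15))
        g = nx.gnm_random_graph(n, min(m, n * (n - 1) // 2),
                                seed=int(rng.integers(2**31)))
        if g.number_of_edges() - n + nx.number_connected_components(g) < 1:
            continue
        assert _implementation_vectors(g) == oracle_relevant_cycles(g)
        done += 1
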