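"""Cycle-core merging, periphery attachment and the residual module."""

import itertools

import pytest

from bowtiemap.bowtie import classify_bowtie
from bowtiemap.cycles import CycleRecord, cycles_for_center
from bowtiemap.model import relabel
from bowtiemap.modules import (
    assemble_modules,
    attach_periphery,
    membership_frame,
    merge_cycle_cores,
    partition_labels,
    residual_module,
)
from bowtiemap.synth import GeneratorConfig, generate_network

from conftest import build_graph


def cycle(*nodes):
    edges = frozenset(
        frozenset((nodes[i], nodes[(i + 1) % len(nodes)]))
        for i in range(len(nodes))
    )
    return CycleRecord(nodes=tuple(nodes), edges=edges)


def oracle_merge(node_sets, frac=0.5):
    """Transitive closure of the pairwise overlap rule."""
    groups = [set([i]) for i in range(len(node_sets))]

    def linked(i, j):
        inter = len(node_sets[i] & node_sets[j])
        return inter / min(len(node_sets[i]), len(node_sets[j])) > frac

    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if any(linked(i, j) for i in groups[a] for j in groups[b]):
                groups[a] |= groups[b]
                del groups[b]
                changed = True
                break
    return sorted(
        sorted(frozenset().union(*(node_sets[i] for i in g)) for g in groups),
        key=len,
    )


class TestMergeCores:
    def test_overlap_above_half_merges(self):
        cores = merge_cycle_cores([cycle("A", "B", "C", "D"),
                                   cycle("B", "C", "D", "E")])
        assert len(cores) == 1
        assert cores[0].core_nodes == {"A", "B", "C", "D", "E"}

    def test_overlap_exactly_half_does_not_merge(self):
        cores = merge_cycle_cores([cycle("A", "B", "C", "D"),
                                   cycle("C", "D", "E", "F")])
        assert len(cores) == 2

    def test_transitive_chain_merges_all(self):
        c1 = cycle("A", "B", "C", "D")
        c2 = cycle("C", "D", "A", "E")   # shares 3/4 with c1
        c3 = cycle("E", "A", "C", "F")   # shares 3/4 with c2, 3/4 with c1
        got = merge_cycle_cores([c1, c2, c3])
        sets = [c.node_set() for c in (c1, c2, c3)]
        expected = oracle_merge(sets)
        assert sorted(sorted(m.core_nodes) for m in got) == \
               sorted(sorted(s) for s in expected)

    def test_denominator_config_changes_outcome(self):
        small = cycle("A", "B", "C")
        big = cycle("A", "B", "D", "E", "F", "G")
        assert len(merge_cycle_cores([small, big], denominator="min")) == 1
        assert len(merge_cycle_cores([small, big], denominator="max")) == 2

    def test_cores_sorted_by_descending_size(self):
        cores = merge_cycle_cores([cycle("A", "B", "C"),
                                   cycle("P", "Q", "R", "S", "T")])
        assert [len(c.core_nodes) for c in cores] == [5, 3]
        assert [c.module_id for c in cores] == [1, 2]


class TestAttachPeriphery:
    def _setup(self, extra_edges):
        base = [("A", "B"), ("B", "C"), ("C", "A"),         # core 1 (triangle)
                ("X", "Y"), ("Y", "Z"), ("Z", "W"), ("W", "X")]  # core 2 (square)
        g = build_graph(edges=base + extra_edges)
        bt = classify_bowtie(g)
        cores = merge_cycle_cores(cycles_for_center(g, bt))
        return g, bt, attach_periphery(cores, g, bt)

    def test_chain_joins_its_only_core(self):
        g, bt, mods = self._setup([("P1", "P2"), ("P2", "A")])
        by_size = {frozenset(m.core_nodes): m for m in mods}
        tri = by_size[frozenset({"A", "B", "C"})]
        assert {"P1", "P2"} <= tri.all_nodes

    def test_majority_of_linking_nodes_wins(self):
        # component {P1,P2,P3}: P1,P2 touch the triangle, P3 touches the square
        g, bt, mods = self._setup([
            ("P1", "P2"), ("P2", "P3"),
            ("P1", "A"), ("P2", "B"), ("P3", "X"),
        ])
        tri = next(m for m in mods if m.core_nodes == {"A", "B", "C"})
        assert {"P1", "P2", "P3"} <= tri.all_nodes

    def test_tie_goes_to_largest_core(self):
        # one linking node to each core; square core is larger
        g, bt, mods = self._setup([("P1", "P2"), ("P1", "A"), ("P2", "X")])
        square = next(m for m in mods if m.core_nodes == {"X", "Y", "Z", "W"})
        assert {"P1", "P2"} <= square.all_nodes


class TestResidual:
    def test_fully_assigned_graph_empty_residual(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "A")])
        bt = classify_bowtie(g)
        mods = assemble_modules(g, bt, cycles_for_center(g, bt))
        assert mods[-1].is_residual and not mods[-1].all_nodes

    def test_isolated_nodes_counted(self):
        g = build_graph(edges=[("A", "B"), ("B", "C"), ("C", "A")],
                        nodes=["I1", "I2"])
        bt = classify_bowtie(g)
        mods = assemble_modules(g, bt, cycles_for_center(g, bt))
        res = mods[-1]
        assert res.all_nodes == {"I1", "I2"}
        assert res.n_components == 2 and res.n_isolated == 2

    def test_planted_off_bowtie_components(self):
        g, truth = generate_network(
            GeneratorConfig(seed=11, n_species=80, n_residual_components=3,
                            n_isolated=2))
        bt = classify_bowtie(g)
        mods = assemble_modules(g, bt, cycles_for_center(g, bt))
        res = mods[-1]
        # 3 planted chains + 2 isolated = 5 weak components off the bow tie
        assert res.n_components == 5
        assert res.n_isolated == 2


class TestPartition:
    @pytest.mark.parametrize("seed", [0, 4])
    def test_every_node_in_exactly_one_module(self, seed):
        g, _ = generate_network(GeneratorConfig(seed=seed, n_species=120))
        bt = classify_bowtie(g)
        mods = assemble_modules(g, bt, cycles_for_center(g, bt))
        frame = membership_frame(mods)
        assert set(frame["id"]) == set(g.nodes)
        assert not frame["id"].duplicated().any()

    def test_invariant_to_species_relabeling(self):
        g, _ = generate_network(GeneratorConfig(seed=9, n_species=60))
        mapping = {nid: f"Z{nid}" for nid in g.species_ids()}
        h = relabel(g, mapping)

        def partition(graph):
            bt = classify_bowtie(graph)
            mods = assemble_modules(graph, bt, cycles_for_center(graph, bt))
            return partition_labels(mods)

        pg, ph = partition(g), partition(h)
        for nid in g.species_ids():
            assert pg[nid] == ph[mapping[nid]]

    def test_residual_after_empty_module_list(self):
        g = build_graph(edges=[("A", "B")])
        res = residual_module(g, [])
        assert res.all_nodes == {"A", "B"} and res.module_id == 1
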