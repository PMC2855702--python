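"""Relevant-cycle enumeration inside the central cyclic layer.

A *relevant cycle* is a cycle that is not the GF(2) sum of strictly shorter
cycles — equivalently, a cycle that belongs to at least one minimum cycle
basis of the cycle space.  The cycle space is taken on the undirected
projection of each strongly connected component (antiparallel arcs collapse,
self-loops are dropped).

The enumeration is exact: all simple cycles of the projection are listed and
filtered by a graded GF(2) independence test (a cycle of length L is relevant
iff it is independent of the span of all cycles shorter than L).  Central
SCCs of interaction maps are small and sparse, so exhaustive enumeration is
cheap; the cyclomatic number per SCC is assumed to be modest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .bowtie import BowTieDecomposition
from .model import InteractionGraph

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleRecord:
    """A simple cycle: ordered closed node walk plus its undirected edge set."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    scc_index: int = 0

    @property
    def length(self) -> int:
        return len(self.edges)

    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)


def undirected_projection(scc_subgraph: InteractionGraph) -> nx.Graph:
    """Collapse antiparallel arcs, drop self-loops (logged), keep all nodes."""
    g = nx.Graph()
    g.add_nodes_from(scc_subgraph.nodes)
    for e in scc_subgraph.edges.values():
        if e.source == e.target:
            log.warning("self-loop on %s dropped in undirected projection",
                        e.source)
            continue
        g.add_edge(e.source, e.target)
    return g


def _canonical_walk(cycle: list[str]) -> tuple[str, ...]:
    """Rotate/reflect a closed walk so equal cycles compare equal.

    Starts at the lexicographically smallest node and walks towards its
    smaller neighbour.
    """
    n = len(cycle)
    i = min(range(n), key=lambda k: cycle[k])
    fwd = [cycle[(i + k) % n] for k in range(n)]
    bwd = [cycle[(i - k) % n] for k in range(n)]
    return tuple(fwd) if fwd[1:] <= bwd[1:] else tuple(bwd)


def relevant_cycle_set(ugraph: nx.Graph) -> list[CycleRecord]:
    """All relevant cycles of a simple undirected graph.

    Deterministic output order: by length, then lexicographic canonical walk.
    Acyclic input yields an empty list.
    """
    edge_index = {frozenset(e): i for i, e in enumerate(ugraph.edges())}
    if not edge_index:
        return []

    cycles: list[tuple[tuple[str, ...], frozenset[frozenset[str]], int]] = []
    for walk in nx.simple_cycles(ugraph):
        canon = _canonical_walk(list(walk))
        eset = frozenset(
            frozenset((canon[i], canon[(i + 1) % len(canon)]))
            for i in range(len(canon))
        )
        vec = 0
        for e in eset:
            vec |= 1 << edge_index[e]
        cycles.append((canon, eset, vec))
    cycles.sort(key=lambda c: (len(c[1]), c[0]))

    # graded GF(2) elimination: relevant iff independent of strictly shorter
    relevant: list[CycleRecord] = []
    basis: dict[int, int] = {}          # pivot bit -> reduced vector
    i = 0
    while i < len(cycles):
        length = len(cycles[i][1])
        group = []
        while i < len(cycles) and len(cycles[i][1]) == length:
            group.append(cycles[i])
            i += 1
        for canon, eset, vec in group:
            if _reduce(vec, basis) != 0:
                relevant.append(CycleRecord(nodes=canon, edges=eset))
        for _, _, vec in group:
            _insert(vec, basis)
    return relevant


def _reduce(vec: int, basis: dict[int, int]) -> int:
    while vec:
        pivot = vec.bit_length() - 1
        row = basis.get(pivot)
        if row is None:
            return vec
        vec ^= row
    return 0


def _insert(vec: int, basis: dict[int, int]) -> None:
    vec = _reduce(vec, basis)
    if vec:
        basis[vec.bit_length() - 1] = vec


def cycles_for_center(graph: InteractionGraph,
                      bowtie: BowTieDecomposition) -> list[CycleRecord]:
    """Relevant cycles of every centre SCC, tagged with the SCC index."""
    records: list[CycleRecord] = []
    for scc_i, scc in enumerate(bowtie.center_sccs):
        proj = undirected_projection(graph.subgraph(scc))
        for rec in relevant_cycle_set(proj):
            records.append(CycleRecord(nodes=rec.nodes, edges=rec.edges,
                                       scc_index=scc_i))
    return records


def cycles_to_frame(records: list[CycleRecord]) -> pd.DataFrame:
    rows = [
        {
            "cycle_id": i + 1,
            "scc_index": r.scc_index,
            "length": r.length,
            "nodes": ";".join(r.nodes),
        }
        for i, r in enumerate(records)
    ]
    return pd.DataFrame(rows, columns=["cycle_id", "scc_index", "length", "nodes"])
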