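"""Bow-tie classification of a directed interaction graph.

A directed network decomposes into a central cyclic layer (the union of its
non-trivial strongly connected components), an IN layer of nodes from which
the centre can be reached, an OUT layer of nodes reachable from the centre,
and a remainder (OTHER).  Tendrils and tubes that bypass the centre fall into
OTHER.  The centre may contain several disjoint SCCs; IN/OUT membership is
relative to their union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .model import InteractionGraph

log = logging.getLogger(__name__)


@dataclass
class BowTieDecomposition:
    center_sccs: list[frozenset[str]] = field(default_factory=list)
    in_set: frozenset[str] = frozenset()
    out_set: frozenset[str] = frozenset()
    other_set: frozenset[str] = frozenset()

    @property
    def center_set(self) -> frozenset[str]:
        out: set[str] = set()
        for scc in self.center_sccs:
            out |= scc
        return frozenset(out)

    def node_class(self, nid: str) -> str:
        if nid in self.center_set:
            return "CENTER"
        if nid in self.in_set:
            return "IN"
        if nid in self.out_set:
            return "OUT"
        return "OTHER"

    def scc_index(self, nid: str) -> int | None:
        for i, scc in enumerate(self.center_sccs):
            if nid in scc:
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scc_i, scc in enumerate(self.center_sccs):
            for nid in sorted(scc):
                rows.append({"id": nid, "bowtie_class": "CENTER", "scc_index": scc_i})
        for nid in sorted(self.in_set):
            rows.append({"id": nid, "bowtie_class": "IN", "scc_index": -1})
        for nid in sorted(self.out_set):
            rows.append({"id": nid, "bowtie_class": "OUT", "scc_index": -1})
        for nid in sorted(self.other_set):
            rows.append({"id": nid, "bowtie_class": "OTHER", "scc_index": -1})
        return pd.DataFrame(rows, columns=["id", "bowtie_class", "scc_index"])


def strongly_connected_components(graph: InteractionGraph) -> list[frozenset[str]]:
    """All maximal SCCs, sorted by smallest member id for determinism."""
    g = graph.to_networkx()
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    return sorted(comps, key=lambda c: min(c))


def _nontrivial(graph: InteractionGraph,
                sccs: list[frozenset[str]]) -> list[frozenset[str]]:
    """SCCs of size >= 2, plus self-loop singletons (cycles of length 1)."""
    loops = {e.source for e in graph.edges.values() if e.source == e.target}
    keep = []
    for scc in sccs:
        if len(scc) >= 2:
            keep.append(scc)
        elif next(iter(scc)) in loops:
            log.info("self-loop singleton %s counted as a centre SCC",
                     next(iter(scc)))
            keep.append(scc)
    return keep


def classify_bowtie(graph: InteractionGraph) -> BowTieDecomposition:
    """Partition nodes into CENTER / IN / OUT / OTHER.

    IN is computed before OUT: a node reaching the centre is IN even if it is
    also reachable from the centre — but that situation would make it part of
    an SCC with the centre, which is asserted impossible.
    """
    g = graph.to_networkx()
    sccs = _nontrivial(graph, strongly_connected_components(graph))
    center: set[str] = set()
    for scc in sccs:
        center |= scc

    ancestors: set[str] = set()
    descendants: set[str] = set()
    if center:
        rev = g.reverse(copy=False)
        for layer, source_graph in ((ancestors, rev), (descendants, g)):
            seen = set(center)
            stack = list(center)
            while stack:
                u = stack.pop()
                for v in source_graph[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            layer |= seen - center

    # A node both reaching and reached by the centre is impossible when the
    # centre is a single SCC, but with several disjoint centre SCCs a "tube"
    # node can sit on a path from one SCC to another; IN precedence wins.
    in_set = frozenset(ancestors)
    out_set = frozenset(descendants - ancestors)
    other = frozenset(set(graph.nodes) - center - in_set - out_set)
    return BowTieDecomposition(
        center_sccs=sccs, in_set=in_set, out_set=out_set, other_set=other
    )
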