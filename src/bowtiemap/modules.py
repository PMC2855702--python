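"""Module assembly: merge relevant cycles into cores, attach periphery,
collect the residual module.

Cycles that share more than half of their nodes (denominator configurable;
default the smaller cycle) are merged transitively — connected components of
the pairwise-overlap graph become module cores.  Weakly connected periphery
components (nodes outside every core) join the core they touch; a component
touching several cores goes to the one linked by the most component nodes,
ties to the largest core, remaining ties to the lowest module id.  Whatever
stays unattached forms the residual module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .bowtie import BowTieDecomposition
from .cycles import CycleRecord
from .model import InteractionGraph

log = logging.getLogger(__name__)

OVERLAP_DENOMINATORS = ("min", "max", "union")


@dataclass
class ModuleRecord:
    module_id: int
    core_nodes: frozenset[str] = frozenset()
    all_nodes: frozenset[str] = frozenset()
    core_cycles: tuple[int, ...] = ()
    is_residual: bool = False
    n_components: int = 0
    n_isolated: int = 0


def _overlap(a: frozenset[str], b: frozenset[str], denominator: str) -> float:
    inter = len(a & b)
    if denominator == "min":
        d = min(len(a), len(b))
    elif denominator == "max":
        d = max(len(a), len(b))
    elif denominator == "union":
        d = len(a | b)
    else:
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    return inter / d if d else 0.0


def merge_cycle_cores(cycles: list[CycleRecord], frac: float = 0.5,
                      denominator: str = "min") -> list[ModuleRecord]:
    """Merge cycles sharing strictly more than ``frac`` of their nodes.

    Merging is transitive: connected components of the pairwise-overlap graph
    become one core each (union of member cycles' nodes).  Cores are sorted
    by descending size (ties by smallest member id) and numbered from 1.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(cycles)))
    node_sets = [c.node_set() for c in cycles]
    for i in range(len(cycles)):
        for j in range(i + 1, len(cycles)):
            if _overlap(node_sets[i], node_sets[j], denominator) > frac:
                overlap.add_edge(i, j)

    cores = []
    for comp in nx.connected_components(overlap):
        members = sorted(comp)
        nodes: set[str] = set()
        for i in members:
            nodes |= node_sets[i]
        cores.append((frozenset(nodes), tuple(m + 1 for m in members)))
    cores.sort(key=lambda c: (-len(c[0]), min(c[0])))
    return [
        ModuleRecord(module_id=i + 1, core_nodes=nodes, all_nodes=nodes,
                     core_cycles=cycle_ids)
        for i, (nodes, cycle_ids) in enumerate(cores)
    ]


def attach_periphery(cores: list[ModuleRecord], graph: InteractionGraph,
                     bowtie: BowTieDecomposition) -> list[ModuleRecord]:
    """Attach IN/OUT/OTHER periphery components to the cores they touch.

    Assignment of a component linked to several cores: most linking component
    nodes first, then largest core, then lowest module id.  A node that sits
    in several cores stays with the lowest-id core for partition purposes.
    """
    core_nodes: set[str] = set()
    for m in cores:
        core_nodes |= m.core_nodes
    periphery = set(graph.nodes) - core_nodes

    und = graph.to_networkx_undirected()
    assigned: dict[int, set[str]] = {m.module_id: set(m.core_nodes) for m in cores}

    for comp in nx.connected_components(und.subgraph(periphery)):
        votes: dict[int, int] = {}
        for m in cores:
            linked = sum(
                1 for u in comp
                if any(v in m.core_nodes for v in und[u])
            )
            if linked:
                votes[m.module_id] = linked
        if not votes:
            continue
        best = max(votes.values())
        tied = [mid for mid, v in votes.items() if v == best]
        if len(tied) > 1:
            sizes = {m.module_id: len(m.core_nodes) for m in cores}
            biggest = max(sizes[mid] for mid in tied)
            tied = [mid for mid in tied if sizes[mid] == biggest]
        assigned[min(tied)] |= set(comp)

    return [
        ModuleRecord(
            module_id=m.module_id,
            core_nodes=m.core_nodes,
            all_nodes=frozenset(assigned[m.module_id]),
            core_cycles=m.core_cycles,
        )
        for m in cores
    ]


def residual_module(graph: InteractionGraph,
                    modules: list[ModuleRecord]) -> ModuleRecord:
    """Collect nodes in no module; report component and isolated counts."""
    covered: set[str] = set()
    for m in modules:
        covered |= m.all_nodes
    left = set(graph.nodes) - covered
    und = graph.to_networkx_undirected().subgraph(left)
    comps = list(nx.connected_components(und))
    isolated = sum(1 for c in comps if len(c) == 1)
    return ModuleRecord(
        module_id=max((m.module_id for m in modules), default=0) + 1,
        all_nodes=frozenset(left),
        is_residual=True,
        n_components=len(comps),
        n_isolated=isolated,
    )


def assemble_modules(graph: InteractionGraph, bowtie: BowTieDecomposition,
                     cycles: list[CycleRecord], frac: float = 0.5,
                     denominator: str = "min") -> list[ModuleRecord]:
    """Full assembly: cores, periphery, residual.  Residual always appended."""
    cores = merge_cycle_cores(cycles, frac=frac, denominator=denominator) \
        if cycles else []
    modules = attach_periphery(cores, graph, bowtie) if cores else []
    modules.append(residual_module(graph, modules))
    return modules


def membership_frame(modules: list[ModuleRecord]) -> pd.DataFrame:
    """Node -> module table; a node in several modules keeps the lowest id."""
    seen: set[str] = set()
    rows = []
    for m in sorted(modules, key=lambda m: m.module_id):
        for nid in sorted(m.all_nodes):
            if nid in seen:
                continue
            seen.add(nid)
            rows.append({
                "id": nid,
                "module_id": m.module_id,
                "in_core": nid in m.core_nodes,
            })
    return pd.DataFrame(rows, columns=["id", "module_id", "in_core"])


def partition_labels(modules: list[ModuleRecord]) -> dict[str, int]:
    df = membership_frame(modules)
    return dict(zip(df["id"], df["module_id"]))
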