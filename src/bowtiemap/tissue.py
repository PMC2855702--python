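"""Tissue-specific sub-maps, cross-tissue overlap, neighbourhood agreement.

Species carry tissue tags; a tissue sub-map is the induced graph on species
with the tag plus reaction nodes all of whose species participants carry the
tag (a reaction cannot occur in a tissue missing one participant; an
``any``-participant relaxation is available).  Shared species are classified
by whether their species-level neighbourhoods (two steps through reaction
nodes) agree across the sub-maps that contain them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import InteractionGraph, ReactionNode, SpeciesNode
from .topology import TopologyReport, topology_report


class UnknownTissueError(ValueError):
    pass


class NotShardedError(ValueError):
    """Node is not present in at least two sub-maps."""


@dataclass
class TissueSubmap:
    tissue: str
    graph: InteractionGraph
    report: TopologyReport


def known_tags(graph: InteractionGraph) -> set[str]:
    tags: set[str] = set()
    for node in graph.nodes.values():
        if isinstance(node, SpeciesNode):
            tags |= node.tissue_tags
    return tags


def extract_submap(graph: InteractionGraph, tag: str,
                   reaction_rule: str = "all") -> TissueSubmap:
    """Induced sub-map for one tissue tag.

    ``reaction_rule='all'`` keeps a reaction node only when every species it
    touches carries the tag; ``'any'`` keeps it when at least one does.
    """
    vocabulary = known_tags(graph)
    if tag not in vocabulary:
        raise UnknownTissueError(
            f"unknown tissue tag {tag!r}; known tags: {sorted(vocabulary)}"
        )
    tagged = {
        nid for nid, node in graph.nodes.items()
        if isinstance(node, SpeciesNode) and tag in node.tissue_tags
    }
    und = graph.to_networkx_undirected()
    keep = set(tagged)
    species = set(graph.species_ids())
    for nid, node in graph.nodes.items():
        if not isinstance(node, ReactionNode):
            continue
        participants = {v for v in und[nid] if v in species}
        participants |= {s for s, _ in node.regulators}
        if not participants:
            continue
        if reaction_rule == "all" and participants <= tagged:
            keep.add(nid)
        elif reaction_rule == "any" and participants & tagged:
            keep.add(nid)
            keep |= participants & tagged
    sub = graph.subgraph(keep)
    return TissueSubmap(tissue=tag, graph=sub, report=topology_report(sub))


def extract_all_submaps(graph: InteractionGraph,
                        reaction_rule: str = "all") -> list[TissueSubmap]:
    return [extract_submap(graph, t, reaction_rule)
            for t in sorted(known_tags(graph))]


@dataclass
class OverlapMatrix:
    tissues: list[str]
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.tissues,
                            columns=self.tissues)


def overlap_matrix(submaps: list[TissueSubmap]) -> OverlapMatrix:
    """counts[i][j] = species carrying both tags; diagonal = per-tissue size.

    Untagged species never enter (they are in no sub-map).
    """
    if len(submaps) < 2:
        raise ValueError("need at least two sub-maps")
    sets = [
        {nid for nid in sm.graph.species_ids()} for sm in submaps
    ]
    k = len(submaps)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            counts[i, j] = len(sets[i] & sets[j])
    return OverlapMatrix(tissues=[sm.tissue for sm in submaps], counts=counts)


def species_neighbors(graph: InteractionGraph, nid: str) -> frozenset[str]:
    """Distinct species adjacent to ``nid``: direct edges either direction,
    or two steps through a reaction node."""
    und = graph.to_networkx_undirected()
    if nid not in und:
        return frozenset()
    species = set(graph.species_ids())
    out: set[str] = set()
    for v in und[nid]:
        if v in species:
            out.add(v)
        else:
            out |= {w for w in und[v] if w in species}
    out.discard(nid)
    return frozenset(out)


def neighborhood_agreement(nid: str, submaps: list[TissueSubmap]) -> str:
    """'identical' / 'different' / 'isolated_everywhere' for a shared node.

    Isolated-everywhere (empty neighbour set in every containing sub-map) is
    a sub-class of identical and is reported under identical in summaries.
    """
    containing = [sm for sm in submaps if nid in sm.graph.nodes]
    if len(containing) < 2:
        raise NotShardedError(f"{nid!r} is present in fewer than two sub-maps")
    sets = [species_neighbors(sm.graph, nid) for sm in containing]
    if all(not s for s in sets):
        return "isolated_everywhere"
    return "identical" if all(s == sets[0] for s in sets) else "different"


def classify_shared_nodes(submaps: list[TissueSubmap]) -> pd.DataFrame:
    """Classification table for every species present in >= 2 sub-maps."""
    membership: dict[str, list[str]] = {}
    for sm in submaps:
        for nid in sm.graph.species_ids():
            membership.setdefault(nid, []).append(sm.tissue)
    rows = []
    for nid in sorted(membership):
        tissues = membership[nid]
        if len(tissues) < 2:
            continue
        rows.append({
            "id": nid,
            "tissues": ";".join(sorted(tissues)),
            "class": neighborhood_agreement(nid, submaps),
        })
    return pd.DataFrame(rows, columns=["id", "tissues", "class"])
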