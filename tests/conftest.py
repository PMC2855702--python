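"""Shared fixtures: tiny graph builders used across the suite."""

from __future__ import annotations

import pytest

from bowtiemap.model import InteractionGraph, ReactionNode, SpeciesNode, TypedEdge


def build_graph(edges=(), nodes=(), relation="st") -> InteractionGraph:
    """Graph from species-id edge pairs; ``reNNN`` ids become reaction nodes."""
    g = InteractionGraph()

    def ensure(nid: str) -> None:
        if nid in g.nodes:
            return
        if nid.startswith("re") and nid[2:].isdigit():
            g.add_node(ReactionNode(id=nid))
        else:
            g.add_node(SpeciesNode(id=nid, name=nid))

    for nid in nodes:
        ensure(nid)
    for u, v in edges:
        ensure(u)
        ensure(v)
        g.add_edge(TypedEdge(u, v, "plain", relation, self_loop=u == v))
    return g


@pytest.fixture
def graph_builder():
    return build_graph
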