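"""Domain model for species/reaction interaction graphs.

The substrate of every analysis stage is a directed graph whose nodes are
either chemical *species* (proteins, genes, RNAs, small molecules, complexes)
or *reactions* (state transitions, transcription, translation, transport,
association/dissociation).  Reactions are first-class nodes — an interaction
between two species is always routed through a reaction node, so two species
that interact sit at directed distance 2.  Edges are typed by the role they
play in a reaction (reactant, product, regulator) or are ``plain`` species
level links imported from interchange formats that have not been
reaction-expanded yet.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx

log = logging.getLogger(__name__)

ENTITY_CLASSES = frozenset(
    {"protein", "gene", "rna", "antisense_rna", "simple_molecule", "ion", "complex"}
)
COMPARTMENTS = frozenset(
    {
        "cytoplasm",
        "membrane",
        "nucleus",
        "extracellular",
        "mitochondrion",
        "cytosol",
        "endoplasmic_reticulum",
        "golgi",
        "unknown",
    }
)
REACTION_TYPES = frozenset(
    {
        "state_transition",
        "transcription",
        "translation",
        "transport",
        "association",
        "dissociation",
        "known_transition_omitted",
        "unknown_transition",
    }
)
EDGE_ROLES = frozenset({"reactant", "product", "regulator", "plain"})

_RE_ID = re.compile(r"^re\d+$")


class GraphValidationError(ValueError):
    """Raised when a graph or one of its components violates an invariant."""


@dataclass(frozen=True)
class SpeciesNode:
    """A chemical species (molecule in a given state and compartment)."""

    id: str
    name: str = ""
    entity_class: str = "protein"
    state_mods: frozenset[str] = frozenset()
    compartment: str = "unknown"
    tissue_tags: frozenset[str] = frozenset()
    complex_members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("species id must be non-empty")
        if self.entity_class not in ENTITY_CLASSES:
            raise GraphValidationError(
                f"unknown entity class {self.entity_class!r} for species {self.id!r}"
            )
        if self.compartment not in COMPARTMENTS:
            raise GraphValidationError(
                f"unknown compartment {self.compartment!r} for species {self.id!r}"
            )
        if self.id in self.complex_members:
            raise GraphValidationError(
                f"complex {self.id!r} lists itself among its members"
            )


@dataclass(frozen=True)
class ReactionNode:
    """A reaction/regulation event, id prefixed ``re``."""

    id: str
    reaction_type: str = "state_transition"
    regulators: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not _RE_ID.match(self.id):
            raise GraphValidationError(
                f"reaction id {self.id!r} does not match the pattern re[0-9]+"
            )
        if self.reaction_type not in REACTION_TYPES:
            raise GraphValidationError(
                f"unknown reaction type {self.reaction_type!r} for {self.id!r}"
            )


@dataclass(frozen=True)
class TypedEdge:
    """One directed typed edge.  ``relation`` keeps the raw interchange label."""

    source: str
    target: str
    edge_role: str = "plain"
    relation: str = ""
    self_loop: bool = False

    def __post_init__(self) -> None:
        if self.edge_role not in EDGE_ROLES:
            raise GraphValidationError(f"unknown edge role {self.edge_role!r}")
        if self.source == self.target and not self.self_loop:
            raise GraphValidationError(
                f"self-loop {self.source!r}->{self.target!r} must be flagged"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.source, self.target, self.edge_role, self.relation)


@dataclass
class InteractionGraph:
    """Directed graph over species and reaction nodes with typed edges.

    Duplicate edges (same source, target, role and relation label) collapse to
    one; self-loops are kept but must be flagged on the edge.
    """

    nodes: dict[str, SpeciesNode | ReactionNode] = field(default_factory=dict)
    edges: dict[tuple[str, str, str, str], TypedEdge] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_node(self, node: SpeciesNode | ReactionNode) -> None:
        existing = self.nodes.get(node.id)
        if existing is not None and existing != node:
            raise GraphValidationError(f"conflicting redefinition of node {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: TypedEdge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise GraphValidationError(
                    f"edge endpoint {endpoint!r} is not a node of the graph"
                )
        self.edges[edge.key] = edge

    # -- counts -----------------------------------------------------------
    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    # -- views ------------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [i for i, n in self.nodes.items() if isinstance(n, SpeciesNode)]

    def reaction_ids(self) -> list[str]:
        return [i for i, n in self.nodes.items() if isinstance(n, ReactionNode)]

    def to_networkx(self) -> nx.DiGraph:
        """Simple directed view: parallel typed edges collapse to one arc."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges.values():
            g.add_edge(e.source, e.target)
        return g

    def to_networkx_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges.values():
            if e.source != e.target:
                g.add_edge(e.source, e.target)
        return g

    def subgraph(self, node_ids) -> "InteractionGraph":
        """Induced subgraph on ``node_ids`` (ids must exist)."""
        keep = set(node_ids)
        missing = keep - set(self.nodes)
        if missing:
            raise GraphValidationError(f"unknown node ids: {sorted(missing)}")
        sub = InteractionGraph()
        for nid in keep:
            sub.add_node(self.nodes[nid])
        for e in self.edges.values():
            if e.source in keep and e.target in keep:
                sub.add_edge(e)
        return sub

    def copy(self) -> "InteractionGraph":
        g = InteractionGraph()
        g.nodes = dict(self.nodes)
        g.edges = dict(self.edges)
        return g

    def validate(self) -> None:
        for e in self.edges.values():
            if e.source not in self.nodes or e.target not in self.nodes:
                raise GraphValidationError(f"dangling edge {e.key}")

    def fresh_reaction_id(self, counter: itertools.count | None = None) -> str:
        """Smallest unused ``reNNN`` id (or next from an explicit counter)."""
        if counter is not None:
            while True:
                rid = f"re{next(counter)}"
                if rid not in self.nodes:
                    return rid
        used = {
            int(nid[2:]) for nid in self.nodes if _RE_ID.match(nid)
        }
        k = 1
        while k in used:
            k += 1
        return f"re{k}"


def expand_reactions(graph: InteractionGraph) -> InteractionGraph:
    """Replace every direct species->species edge by species->re->species.

    Interchange formats (SIF in particular) carry species-level arcs; the
    analyses assume reactions are nodes of their own, so that the shortest
    path between two interacting species is exactly 2.  Idempotent: a graph
    with no species-species edge is returned unchanged (as a copy).
    One fresh reaction node is created per species-species edge, so a
    reciprocal pair A<->B yields two distinct reaction nodes.
    """
    out = InteractionGraph()
    out.nodes = dict(graph.nodes)
    counter = itertools.count(1)
    species = set(graph.species_ids())
    for e in graph.edges.values():
        if e.source in species and e.target in species:
            rid = out.fresh_reaction_id(counter)
            rtype = e.relation if e.relation in REACTION_TYPES else "state_transition"
            out.add_node(ReactionNode(id=rid, reaction_type=rtype))
            out.add_edge(
                TypedEdge(e.source, rid, "reactant", e.relation,
                          self_loop=e.source == rid)
            )
            out.add_edge(
                TypedEdge(rid, e.target, "product", e.relation,
                          self_loop=rid == e.target)
            )
        else:
            out.add_edge(e)
    return out


def is_bipartite_expanded(graph: InteractionGraph) -> bool:
    """True iff no edge joins two species directly."""
    species = set(graph.species_ids())
    return not any(
        e.source in species and e.target in species for e in graph.edges.values()
    )


def census(graph: InteractionGraph) -> dict[str, dict[str, int]]:
    """Counts of species by compartment and entity class, reactions by type."""
    by_compartment: dict[str, int] = {}
    by_class: dict[str, int] = {}
    by_reaction_type: dict[str, int] = {}
    for node in graph.nodes.values():
        if isinstance(node, SpeciesNode):
            by_compartment[node.compartment] = by_compartment.get(node.compartment, 0) + 1
            by_class[node.entity_class] = by_class.get(node.entity_class, 0) + 1
        else:
            by_reaction_type[node.reaction_type] = (
                by_reaction_type.get(node.reaction_type, 0) + 1
            )
    return {
        "compartment": by_compartment,
        "entity_class": by_class,
        "reaction_type": by_reaction_type,
    }


def relabel(graph: InteractionGraph, mapping: dict[str, str]) -> InteractionGraph:
    """Return a copy with node ids renamed by ``mapping`` (must be injective)."""
    if len(set(mapping.values())) != len(mapping):
        raise GraphValidationError("relabel mapping is not injective")
    out = InteractionGraph()
    for nid, node in graph.nodes.items():
        new = mapping.get(nid, nid)
        if isinstance(node, SpeciesNode):
            out.add_node(replace(node, id=new))
        else:
            out.add_node(replace(node, id=new))
    for e in graph.edges.values():
        out.add_edge(
            replace(e, source=mapping.get(e.source, e.source),
                    target=mapping.get(e.target, e.target))
        )
    return out
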