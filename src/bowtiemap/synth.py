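"""Seeded generator of species/reaction interaction maps with ground truth.

The generator emulates the statistical shape of a curated disease interaction
map: a few hundred species alternating with reaction nodes, a small central
cyclic core (planted directed cycles, optionally sharing an arc), sparse
scale-free periphery, a handful of high-out-degree hubs, five partially
overlapping tissue tags, compartment/entity-class labels with census-like
proportions, and annotation terms including one term concentrated in a
planted module.

Structure is grown as a DAG outside the planted cycles (new periphery nodes
are pure sources, OUT-side nodes pure sinks), so the planted cycles are
exactly the non-trivial strongly connected components — that is the ground
truth the recovery tests rely on.  All randomness flows through one
``numpy.random.Generator`` seeded from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    InteractionGraph,
    ReactionNode,
    SpeciesNode,
    TypedEdge,
    census as graph_census,
    expand_reactions,
)

# census-like proportions of a curated map: 348 species over 8 compartments,
# 255 reactions over 8 kinds, 384 molecules over 6 entity classes
DEFAULT_COMPARTMENT_PROBS = {
    "cytoplasm": 248, "membrane": 44, "nucleus": 21, "extracellular": 25,
    "mitochondrion": 4, "cytosol": 1, "endoplasmic_reticulum": 4, "golgi": 1,
}
DEFAULT_CLASS_PROBS = {
    "protein": 273, "gene": 58, "rna": 46, "simple_molecule": 5,
    "ion": 1, "antisense_rna": 1,
}
DEFAULT_REACTION_TYPE_PROBS = {
    "state_transition": 160, "transcription": 47, "translation": 10,
    "transport": 7, "association": 24, "dissociation": 3,
    "known_transition_omitted": 2, "unknown_transition": 2,
}
DEFAULT_TISSUE_TAGS = {
    "blood_pbmc": 0.45, "synovial_fibroblast": 0.30, "cartilage": 0.12,
    "blood_pbmc_pmn": 0.05, "synovial_pmn": 0.08,
}
# most species carry one tag, a minority two, three-way sharing is rare
DEFAULT_TAG_COUNT_PROBS = {0: 0.08, 1: 0.80, 2: 0.105, 3: 0.015}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_species: int = 348
    gamma_target: float = 2.5
    max_out_degree: int = 12
    n_center_cycles: int = 2
    cycle_length_range: tuple[int, int] = (6, 9)
    overlap_fraction: float = 0.0
    out_leaf_prob: float = 0.3
    n_hubs: int = 1
    hub_out_degree: int = 10
    n_residual_components: int = 3
    residual_component_size: tuple[int, int] = (2, 3)
    n_isolated: int = 4
    tissue_tags: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TAGS))
    tag_count_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TAG_COUNT_PROBS))
    compartment_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_PROBS))
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    reaction_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REACTION_TYPE_PROBS))
    n_terms: int = 20
    term_prob: float = 0.08
    enrichment_fold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.cycle_length_range
        if lo < 3 or hi < lo:
            raise ConfigError("cycle_length_range must satisfy 3 <= lo <= hi")
        if self.n_center_cycles < 1:
            raise ConfigError("at least one planted cycle is required")
        budget = (self.n_center_cycles * hi
                  + self.n_residual_components * self.residual_component_size[1]
                  + self.n_isolated)
        if self.n_species < budget + 2:
            raise ConfigError(
                f"n_species={self.n_species} too small for the planted "
                f"structure (needs > {budget})"
            )
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigError("overlap_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    planted_cycles: list[list[str]]
    module_assignment: dict[str, int]        # 0 = residual
    planted_hubs: list[str]
    tag_assignment: dict[str, frozenset[str]]
    census: dict[str, dict[str, int]]
    out_degree_sequence: dict[str, int]      # species-level structural degrees
    cycles_merged: bool
    term_memberships: dict[str, tuple[str, frozenset[str]]] = field(
        default_factory=dict)


def _choice(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    w = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _truncated_zipf(rng: np.random.Generator, gamma: float, cap: int) -> int:
    while True:
        k = int(rng.zipf(gamma))
        if k <= cap:
            return k


def generate_network(config: GeneratorConfig) -> tuple[InteractionGraph, GroundTruth]:
    """Build the species-level structure, expand reactions, attach labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = [f"S{i + 1:04d}" for i in range(config.n_species)]
    next_id = iter(ids)

    edges: set[tuple[str, str]] = set()
    label: dict[str, int] = {}
    in_deg: dict[str, int] = {}
    out_deg: dict[str, int] = {}

    def add_edge(u: str, v: str) -> None:
        if (u, v) not in edges:
            edges.add((u, v))
            out_deg[u] = out_deg.get(u, 0) + 1
            in_deg[v] = in_deg.get(v, 0) + 1

    # -- planted cycles ---------------------------------------------------
    lo, hi = config.cycle_length_range
    lengths = [int(rng.integers(lo, hi + 1))
               for _ in range(config.n_center_cycles)]
    cycles: list[list[str]] = []
    shared: list[str] = []
    for ci, length in enumerate(lengths):
        if ci == 0 or not shared:
            nodes = [next(next_id) for _ in range(length)]
        else:
            fresh = [next(next_id) for _ in range(length - len(shared))]
            nodes = shared + fresh
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            add_edge(a, b)
        for n in nodes:
            label.setdefault(n, ci + 1)
        cycles.append(nodes)
        if ci == 0 and config.overlap_fraction > 0 and config.n_center_cycles > 1:
            s = int(round(config.overlap_fraction * min(lengths)))
            shared = nodes[:s] if s >= 2 else []

    # merge bookkeeping on the reaction-expanded map the analyses see: a
    # shared arc of s species carries 2s-1 nodes, a cycle of length L has 2L
    min_len = min(lengths) if lengths else 0
    merged = bool(shared) and (2 * len(shared) - 1) / (2 * min_len) > 0.5
    if merged:
        for n in label:
            label[n] = 1

    connectable = [n for c in cycles for n in c]
    # dedup, preserve order
    connectable = list(dict.fromkeys(connectable))
    sinks: set[str] = set()

    # -- residual structure (never connected to the rest) -----------------
    residual_nodes: list[str] = []
    r_lo, r_hi = config.residual_component_size
    for _ in range(config.n_residual_components):
        size = int(rng.integers(r_lo, r_hi + 1))
        chain = [next(next_id) for _ in range(size)]
        for a, b in zip(chain, chain[1:]):
            add_edge(a, b)
        residual_nodes.extend(chain)
    for _ in range(config.n_isolated):
        residual_nodes.append(next(next_id))
    for n in residual_nodes:
        label[n] = 0

    # -- scale-free periphery ---------------------------------------------
    def preferential(pool: list[str]) -> str:
        w = np.array([in_deg.get(n, 0) + 1 for n in pool], dtype=float)
        return pool[rng.choice(len(pool), p=w / w.sum())]

    hub_candidates: list[str] = []
    for nid in next_id:
        if rng.random() < config.out_leaf_prob:
            pool = [n for n in connectable if n not in sinks
                    and out_deg.get(n, 0) < config.max_out_degree]
            if not pool:
                pool = [n for n in connectable if n not in sinks]
            src = preferential(pool)
            add_edge(src, nid)
            label[nid] = label[src]
            sinks.add(nid)
        else:
            d = min(_truncated_zipf(rng, config.gamma_target,
                                    config.max_out_degree), len(connectable))
            first = preferential(connectable)
            label[nid] = label[first]
            targets = {first}
            same_module = [n for n in connectable
                           if label[n] == label[first] and n not in targets]
            while len(targets) < d and same_module:
                t = preferential(same_module)
                targets.add(t)
                same_module.remove(t)
            for t in sorted(targets):
                add_edge(nid, t)
            hub_candidates.append(nid)
        connectable.append(nid)

    # -- planted hubs ------------------------------------------------------
    hubs: list[str] = []
    for nid in hub_candidates[: config.n_hubs]:
        pool = [n for n in connectable
                if n != nid and label[n] == label[nid]
                and (nid, n) not in edges]
        rng.shuffle(pool)
        deficit = max(0, config.hub_out_degree - out_deg.get(nid, 0))
        for t in pool[:deficit]:
            add_edge(nid, t)
        hubs.append(nid)

    # -- species attributes -----------------------------------------------
    tag_names = list(config.tissue_tags)
    tag_w = np.array([config.tissue_tags[t] for t in tag_names], dtype=float)
    tag_w = tag_w / tag_w.sum()
    tag_assignment: dict[str, frozenset[str]] = {}
    species_nodes: dict[str, SpeciesNode] = {}
    for nid in ids:
        compartment = _choice(rng, config.compartment_probs)
        entity_class = _choice(rng, config.class_probs)
        n_tags = int(_choice(rng, config.tag_count_probs))
        chosen = rng.choice(len(tag_names), size=min(n_tags, len(tag_names)),
                            replace=False, p=tag_w)
        tags = frozenset(tag_names[int(i)] for i in np.atleast_1d(chosen))
        tag_assignment[nid] = tags
        species_nodes[nid] = SpeciesNode(
            id=nid, name=nid, entity_class=str(entity_class),
            compartment=str(compartment), tissue_tags=tags,
        )

    species_graph = InteractionGraph()
    for nid in ids:
        species_graph.add_node(species_nodes[nid])
    for u, v in sorted(edges):
        species_graph.add_edge(TypedEdge(u, v, "plain", "interacts"))

    graph = expand_reactions(species_graph)

    # reaction types drawn census-like; module label inherited from the source
    module_assignment = dict(label)
    for rid in sorted(graph.reaction_ids(), key=lambda r: int(r[2:])):
        rtype = str(_choice(rng, config.reaction_type_probs))
        graph.nodes[rid] = replace(graph.nodes[rid], reaction_type=rtype)
        src = next(e.source for e in graph.edges.values()
                   if e.target == rid and e.edge_role == "reactant")
        module_assignment[rid] = label[src]

    truth = GroundTruth(
        planted_cycles=cycles,
        module_assignment=module_assignment,
        planted_hubs=hubs,
        tag_assignment=tag_assignment,
        census=graph_census(graph),
        out_degree_sequence={nid: out_deg.get(nid, 0) for nid in ids},
        cycles_merged=merged,
    )
    return graph, truth


def generate_annotation(config: GeneratorConfig, truth: GroundTruth,
                        background: frozenset[str] | set[str] | None = None,
                        ) -> dict[str, tuple[str, frozenset[str]]]:
    """Random annotation terms plus one term concentrated in planted module 1.

    Each random term includes each background species with probability
    ``term_prob``; the planted term uses ``enrichment_fold * term_prob``
    (capped at 1) inside module 1.  ``enrichment_fold=1`` makes the planted
    term indistinguishable from the random ones.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    if background is None:
        background = frozenset(truth.out_degree_sequence)
    universe = sorted(background)
    table: dict[str, tuple[str, frozenset[str]]] = {}

    def draw(p_by_node: dict[str, float]) -> frozenset[str]:
        members = {n for n in universe if rng.random() < p_by_node[n]}
        if not members:
            members = {universe[int(rng.integers(len(universe)))]}
        return frozenset(members)

    flat = {n: config.term_prob for n in universe}
    for t in range(config.n_terms):
        table[f"T{t + 1:03d}"] = (f"random term {t + 1}", draw(flat))

    module_one = {n for n in universe
                  if truth.module_assignment.get(n) == 1}
    p_in = min(1.0, config.enrichment_fold * config.term_prob)
    planted = {n: (p_in if n in module_one else config.term_prob)
               for n in universe}
    table["T_PLANTED"] = ("planted module term", draw(planted))
    truth.term_memberships = dict(table)
    return table
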