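"""Readers and writers: SIF, a CellDesigner-flavoured SBML subset, TSV tables.

SIF is whitespace-delimited ``source relation target`` (or a lone node id for
isolated nodes).  The SBML reader covers Level 2 core (species, compartments,
reactions with reactants/products/modifiers) plus best-effort CellDesigner
class annotations; full CellDesigner layout is out of scope.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .model import (
    COMPARTMENTS,
    ENTITY_CLASSES,
    REACTION_TYPES,
    GraphValidationError,
    InteractionGraph,
    ReactionNode,
    SpeciesNode,
    TypedEdge,
)

log = logging.getLogger(__name__)


class SifParseError(ValueError):
    pass


class SbmlFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def _ensure_node(graph: InteractionGraph, nid: str) -> None:
    if nid in graph.nodes:
        return
    if nid.startswith("re") and nid[2:].isdigit():
        graph.add_node(ReactionNode(id=nid))
    else:
        graph.add_node(SpeciesNode(id=nid, name=nid))


def read_sif(path: str | Path) -> InteractionGraph:
    """Read a SIF file into an :class:`InteractionGraph`.

    Each non-blank line is either ``source relation target`` or a lone node
    id.  Repeated triples collapse to one edge.  Node ids that look like
    reaction ids (``reNNN``) become reaction nodes, everything else a species.
    """
    graph = InteractionGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) == 1:
                _ensure_node(graph, fields[0])
            elif len(fields) == 3:
                src, rel, tgt = fields
                _ensure_node(graph, src)
                _ensure_node(graph, tgt)
                graph.add_edge(
                    TypedEdge(src, tgt, "plain", rel, self_loop=src == tgt)
                )
            else:
                raise SifParseError(
                    f"{path}: line {lineno}: expected 1 or 3 fields, "
                    f"got {len(fields)}"
                )
    return graph


def write_sif(graph: InteractionGraph, path: str | Path) -> None:
    """Write SIF; round-trips the node and edge sets exactly with read_sif."""
    connected: set[str] = set()
    lines: list[str] = []
    for key in sorted(graph.edges):
        e = graph.edges[key]
        rel = e.relation or e.edge_role
        lines.append(f"{e.source}\t{rel}\t{e.target}")
        connected.add(e.source)
        connected.add(e.target)
    for nid in sorted(set(graph.nodes) - connected):
        lines.append(nid)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# SBML subset (CellDesigner flavoured)
# ---------------------------------------------------------------------------

_CD_CLASS_MAP = {
    "PROTEIN": "protein",
    "GENE": "gene",
    "RNA": "rna",
    "ANTISENSE_RNA": "antisense_rna",
    "SIMPLE_MOLECULE": "simple_molecule",
    "ION": "ion",
    "COMPLEX": "complex",
}

_COMPARTMENT_ALIASES = {
    "default": "unknown",
    "extracellular_space": "extracellular",
    "er": "endoplasmic_reticulum",
    "golgi_apparatus": "golgi",
}


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_all(elem: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in elem.iter() if _strip(c.tag) == name]


def _normalise_compartment(raw: str) -> str:
    c = raw.strip().lower()
    c = _COMPARTMENT_ALIASES.get(c, c)
    if c not in COMPARTMENTS:
        log.warning("unknown compartment %r; defaulting to 'unknown'", raw)
        c = "unknown"
    return c


def read_celldesigner_subset(path: str | Path) -> InteractionGraph:
    """Read the SBML/CellDesigner subset into an interaction graph.

    One species node per SBML species; one reaction node per reaction with
    reactant->reaction and reaction->product edges plus regulator edges from
    modifiers.  Reaction ids are forced to the ``re`` prefix.  A reversible
    reaction keeps a single reaction node and adds the mirrored edge pair.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SbmlFormatError(f"{path}: XML parse failure: {exc}") from exc
    root = tree.getroot()
    if _strip(root.tag) != "sbml":
        raise SbmlFormatError(f"{path}: root element is not <sbml>")

    graph = InteractionGraph()
    declared: set[str] = set()

    for sp in _find_all(root, "species"):
        sid = sp.get("id")
        if not sid:
            raise SbmlFormatError(f"{path}: species without id")
        name = sp.get("name") or sid
        compartment = _normalise_compartment(sp.get("compartment", "unknown"))
        entity_class = "protein"
        for cls in _find_all(sp, "class"):
            mapped = _CD_CLASS_MAP.get((cls.text or "").strip().upper())
            if mapped:
                entity_class = mapped
            else:
                log.warning(
                    "species %s: unknown CellDesigner class %r; defaulting to "
                    "'protein'", sid, cls.text,
                )
        graph.add_node(
            SpeciesNode(id=sid, name=name, entity_class=entity_class,
                        compartment=compartment)
        )
        declared.add(sid)

    counter = 1
    for rx in _find_all(root, "reaction"):
        rid = rx.get("id") or f"re{counter}"
        if not (rid.startswith("re") and rid[2:].isdigit()):
            rid = graph.fresh_reaction_id()
        counter += 1
        rtype = "state_transition"
        for rt in _find_all(rx, "reactionType"):
            cand = (rt.text or "").strip().lower()
            if cand in REACTION_TYPES:
                rtype = cand

        reactants, products, modifiers = [], [], []
        for lo in rx:
            kind = _strip(lo.tag)
            if kind not in (
                "listOfReactants", "listOfProducts", "listOfModifiers"
            ):
                continue
            for ref in _find_all(lo, "speciesReference") + _find_all(
                lo, "modifierSpeciesReference"
            ):
                sid = ref.get("species")
                if sid is None:
                    continue
                {"listOfReactants": reactants,
                 "listOfProducts": products,
                 "listOfModifiers": modifiers}[kind].append(sid)

        undeclared = [s for s in reactants + products + modifiers
                      if s not in declared]
        if undeclared:
            raise GraphValidationError(
                f"{path}: reaction {rid} references undeclared species "
                f"{sorted(set(undeclared))}"
            )

        graph.add_node(
            ReactionNode(
                id=rid, reaction_type=rtype,
                regulators=tuple((m, "unknown") for m in modifiers),
            )
        )
        reversible = (rx.get("reversible", "false").lower() == "true")
        for s in reactants:
            graph.add_edge(TypedEdge(s, rid, "reactant", self_loop=s == rid))
            if reversible:
                graph.add_edge(TypedEdge(rid, s, "product", self_loop=s == rid))
        for s in products:
            graph.add_edge(TypedEdge(rid, s, "product", self_loop=s == rid))
            if reversible:
                graph.add_edge(TypedEdge(s, rid, "reactant", self_loop=s == rid))
        for s in modifiers:
            graph.add_edge(TypedEdge(s, rid, "regulator", self_loop=s == rid))
    return graph


# ---------------------------------------------------------------------------
# Attribute / annotation tables
# ---------------------------------------------------------------------------

def read_attributes(graph: InteractionGraph, path: str | Path) -> InteractionGraph:
    """Apply a node-attribute TSV (id, entity_class, compartment, tissue_tags).

    Tissue tags are semicolon separated; unknown classes/compartments fall
    back to defaults with a warning.  Returns a new graph.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = graph.copy()
    for _, row in df.iterrows():
        nid = row["id"]
        node = out.nodes.get(nid)
        if node is None or not isinstance(node, SpeciesNode):
            log.warning("attribute row for unknown species %r skipped", nid)
            continue
        cls = row.get("entity_class", "") or node.entity_class
        if cls not in ENTITY_CLASSES:
            log.warning("unknown entity class %r for %s; using 'protein'", cls, nid)
            cls = "protein"
        comp = _normalise_compartment(row.get("compartment", "") or node.compartment)
        tags = frozenset(t for t in row.get("tissue_tags", "").split(";") if t)
        out.nodes[nid] = replace(
            node, entity_class=cls, compartment=comp,
            tissue_tags=tags or node.tissue_tags,
        )
    return out


def write_attributes(graph: InteractionGraph, path: str | Path) -> None:
    rows = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if isinstance(node, SpeciesNode):
            rows.append(
                {
                    "id": nid,
                    "entity_class": node.entity_class,
                    "compartment": node.compartment,
                    "tissue_tags": ";".join(sorted(node.tissue_tags)),
                }
            )
    pd.DataFrame(rows, columns=["id", "entity_class", "compartment", "tissue_tags"]
                 ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a term table: term_id, term_name, semicolon-joined member ids."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    table: dict[str, tuple[str, frozenset[str]]] = {}
    for _, row in df.iterrows():
        members = frozenset(m for m in row["members"].split(";") if m)
        if not members:
            raise GraphValidationError(f"term {row['term_id']!r} has no members")
        table[row["term_id"]] = (row.get("term_name", row["term_id"]), members)
    return table


def write_annotations(table: dict[str, tuple[str, frozenset[str]]],
                      path: str | Path) -> None:
    rows = [
        {"term_id": tid, "term_name": name, "members": ";".join(sorted(members))}
        for tid, (name, members) in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["term_id", "term_name", "members"]).to_csv(
        path, sep="\t", index=False
    )
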