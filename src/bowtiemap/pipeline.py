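"""Pipeline orchestration: decompose / topology / tissues / enrich / simulate.

Each ``run_*`` function is a thin, file-oriented layer over the library
modules; the command-line interface and the analysis drivers both call these.
Every run logs the package version, a hash of the resolved configuration and
the seed, so an invocation is reproducible from its log line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .bowtie import classify_bowtie
from .cycles import cycles_for_center, cycles_to_frame
from .enrichment import enrich, enrichment_frame
from .graphio import (
    read_annotations,
    read_attributes,
    read_celldesigner_subset,
    read_sif,
    write_annotations,
    write_attributes,
    write_sif,
)
from .model import InteractionGraph, expand_reactions
from .modules import assemble_modules, membership_frame
from .synth import GeneratorConfig, generate_annotation, generate_network
from .tissue import classify_shared_nodes, extract_all_submaps, overlap_matrix
from .topology import report_row, reports_to_frame, topology_report

log = logging.getLogger(__name__)


def _log_config(stage: str, config: dict) -> None:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    log.info("%s | bowtiemap %s | config %s | %s", stage, __version__,
             digest, json.dumps(config, sort_keys=True, default=str))


def load_network(network: str | Path,
                 attrs: str | Path | None = None) -> InteractionGraph:
    """Read SIF or SBML (by extension), apply attributes, expand reactions."""
    path = Path(network)
    if path.suffix.lower() in (".xml", ".sbml"):
        graph = read_celldesigner_subset(path)
    else:
        graph = read_sif(path)
    if attrs:
        graph = read_attributes(graph, attrs)
    return expand_reactions(graph)


def run_decompose(network: str | Path, out_dir: str | Path,
                  attrs: str | Path | None = None, merge_frac: float = 0.5,
                  merge_denominator: str = "min", hub_direction: str = "out",
                  hub_threshold: int = 3) -> dict:
    """Full decomposition; writes per-module SIF, membership and summary TSV."""
    _log_config("decompose", {
        "network": network, "attrs": attrs, "merge_frac": merge_frac,
        "merge_denominator": merge_denominator,
        "hub_direction": hub_direction, "hub_threshold": hub_threshold,
    })
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = load_network(network, attrs)
    bowtie = classify_bowtie(graph)
    cycles = cycles_for_center(graph, bowtie)
    modules = assemble_modules(graph, bowtie, cycles, frac=merge_frac,
                               denominator=merge_denominator)

    bowtie.to_frame().to_csv(out / "bowtie.tsv", sep="\t", index=False)
    cycles_to_frame(cycles).to_csv(out / "cycles.tsv", sep="\t", index=False)
    membership_frame(modules).to_csv(out / "modules.tsv", sep="\t", index=False)

    rows = [report_row(topology_report(graph, hub_direction, hub_threshold),
                       "Main")]
    for m in modules:
        sub = graph.subgraph(m.all_nodes)
        write_sif(sub, out / f"module_{m.module_id}.sif")
        name = f"Mod {m.module_id}" + (" (residual)" if m.is_residual else "")
        if sub.node_count:
            rows.append(report_row(
                topology_report(sub, hub_direction, hub_threshold), name))
    summary = reports_to_frame(rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return {"graph": graph, "bowtie": bowtie, "cycles": cycles,
            "modules": modules, "summary": summary}


def run_topology(network: str | Path, out_dir: str | Path,
                 attrs: str | Path | None = None, hub_direction: str = "out",
                 hub_threshold: int = 3) -> dict:
    _log_config("topology", {"network": network, "attrs": attrs,
                             "hub_direction": hub_direction,
                             "hub_threshold": hub_threshold})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = load_network(network, attrs)
    report = topology_report(graph, hub_direction, hub_threshold)
    frame = reports_to_frame([report_row(report, "Main")])
    frame.to_csv(out / "topology.tsv", sep="\t", index=False)
    (out / "topology.json").write_text(json.dumps(
        dataclasses.asdict(report), indent=2, default=str) + "\n")
    (out / "hubs.tsv").write_text(
        "\n".join(report.hubs) + ("\n" if report.hubs else ""))
    return {"graph": graph, "report": report, "frame": frame}


def run_tissues(network: str | Path, out_dir: str | Path,
                attrs: str | Path | None = None,
                reaction_rule: str = "all") -> dict:
    _log_config("tissues", {"network": network, "attrs": attrs,
                            "reaction_rule": reaction_rule})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = load_network(network, attrs)
    submaps = extract_all_submaps(graph, reaction_rule)
    for sm in submaps:
        write_sif(sm.graph, out / f"tissue_{sm.tissue}.sif")
    rows = [report_row(sm.report, sm.tissue) for sm in submaps]
    reports_to_frame(rows).to_csv(out / "tissue_summary.tsv", sep="\t",
                                  index=False)
    result: dict = {"graph": graph, "submaps": submaps}
    if len(submaps) >= 2:
        ov = overlap_matrix(submaps)
        ov.to_frame().to_csv(out / "overlap.tsv", sep="\t")
        shared = classify_shared_nodes(submaps)
        shared.to_csv(out / "shared_nodes.tsv", sep="\t", index=False)
        result |= {"overlap": ov, "shared": shared}
    return result


def run_enrich(network: str | Path, annotations: str | Path,
               out_dir: str | Path, attrs: str | Path | None = None,
               query: set[str] | None = None, alpha: float = 0.01) -> dict:
    _log_config("enrich", {"network": network, "annotations": annotations,
                           "alpha": alpha})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = load_network(network, attrs)
    table = read_annotations(annotations)
    background = frozenset(graph.species_ids())
    if query is None:
        query = set(background)
    rows = enrich(query, table, background, alpha=alpha)
    frame = enrichment_frame(rows)
    frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {"graph": graph, "rows": rows, "frame": frame}


def run_simulate(out_dir: str | Path, seed: int = 0,
                 config: GeneratorConfig | None = None) -> dict:
    """Generate a fixture bundle: SIF + attribute TSV + annotations + truth."""
    if config is None:
        config = GeneratorConfig(seed=seed)
    elif config.seed != seed:
        config = dataclasses.replace(config, seed=seed)
    _log_config("simulate", dataclasses.asdict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, truth = generate_network(config)
    annotations = generate_annotation(config, truth)
    write_sif(graph, out / "network.sif")
    write_attributes(graph, out / "attributes.tsv")
    write_annotations(annotations, out / "annotations.tsv")
    truth_json = {
        "planted_cycles": truth.planted_cycles,
        "module_assignment": truth.module_assignment,
        "planted_hubs": truth.planted_hubs,
        "tag_assignment": {k: sorted(v) for k, v in
                           truth.tag_assignment.items()},
        "census": truth.census,
        "out_degree_sequence": truth.out_degree_sequence,
        "cycles_merged": truth.cycles_merged,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(truth_json, indent=2, sort_keys=True) + "\n")
    return {"graph": graph, "truth": truth, "annotations": annotations,
            "config": config}
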