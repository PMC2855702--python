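"""Topology statistics: counts, components, neighbours, paths, density,
degree distributions with log-log power-law fits, and hub identification.

Conventions (chosen to match NetworkAnalyzer-style reports on directed
interaction maps):

* density = 2E / (N(N-1));
* mean neighbours = average number of *distinct* adjacent nodes (either
  direction, reciprocal pairs once, self-loops excluded);
* path statistics over ordered reachable pairs only;
* power-law fit = ordinary least squares of log10(frequency) on log10(degree)
  over degrees >= 1 (zero-degree nodes never enter the fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd

from .model import InteractionGraph, SpeciesNode


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class DegreeDistribution:
    direction: str                       # "in" | "out" | "total"
    points: tuple[tuple[int, int], ...]  # (degree >= 1, frequency), increasing
    zero_degree_count: int = 0

    def __post_init__(self) -> None:
        degs = [k for k, _ in self.points]
        if any(k < 1 for k in degs) or degs != sorted(set(degs)):
            raise ValueError("degrees must be >= 1 and strictly increasing")
        if any(f <= 0 for _, f in self.points):
            raise ValueError("frequencies must be positive")


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    r2: float
    n_points: int


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    components: int
    mean_neighbors: float | None
    mean_path: float | None
    path_variance: float | None
    diameter: int | None
    density: float | None
    fit_in: PowerLawFit | None
    fit_out: PowerLawFit | None
    hubs: list[str]


def network_density(n_nodes: int, n_edges: int) -> float:
    """Density 2E/(N(N-1)); undefined for graphs with fewer than two nodes."""
    if n_nodes < 2:
        raise UndefinedStatisticError("density undefined for N < 2")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mean_distinct_neighbors(graph: InteractionGraph) -> float:
    """Average count of distinct adjacent nodes (either direction)."""
    if graph.node_count == 0:
        raise UndefinedStatisticError("no nodes")
    und = graph.to_networkx_undirected()   # drops self-loops, collapses pairs
    return sum(d for _, d in und.degree()) / graph.node_count


def degree_distribution(graph: InteractionGraph, direction: str,
                        species_only: bool = False) -> DegreeDistribution:
    """Histogram of in/out/total degrees over the simple directed view."""
    g = graph.to_networkx()
    if direction == "in":
        deg = dict(g.in_degree())
    elif direction == "out":
        deg = dict(g.out_degree())
    elif direction == "total":
        deg = dict(g.degree())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if species_only:
        keep = set(graph.species_ids())
        deg = {n: d for n, d in deg.items() if n in keep}
    freq: dict[int, int] = {}
    zero = 0
    for d in deg.values():
        if d == 0:
            zero += 1
        else:
            freq[d] = freq.get(d, 0) + 1
    return DegreeDistribution(
        direction=direction,
        points=tuple(sorted(freq.items())),
        zero_degree_count=zero,
    )


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit | None:
    """OLS of log10(frequency) on log10(degree); None when < 2 points."""
    if len(dist.points) < 2:
        return None
    x = np.log10([k for k, _ in dist.points])
    y = np.log10([f for _, f in dist.points])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(exponent=-float(slope), r2=r2, n_points=len(dist.points))


def shortest_path_stats(graph: InteractionGraph) -> tuple[float, float, int]:
    """(mean, variance, diameter) over ordered reachable pairs u != v."""
    g = graph.to_networkx()
    dists: list[int] = []
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        dists.extend(d for d in lengths.values() if d > 0)
    if not dists:
        raise UndefinedStatisticError("no ordered pair is reachable")
    arr = np.asarray(dists, dtype=float)
    return float(arr.mean()), float(arr.var()), int(arr.max())


def identify_hubs(graph: InteractionGraph, direction: str = "out",
                  min_degree: int = 3) -> list[str]:
    """Species nodes with degree strictly above ``min_degree``.

    Reaction nodes are excluded; result sorted by degree descending then id.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    g = graph.to_networkx()
    if direction == "in":
        deg = dict(g.in_degree())
    elif direction == "out":
        deg = dict(g.out_degree())
    elif direction == "total":
        deg = dict(g.degree())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    hubs = [
        nid for nid, node in graph.nodes.items()
        if isinstance(node, SpeciesNode) and deg.get(nid, 0) > min_degree
    ]
    return sorted(hubs, key=lambda nid: (-deg[nid], nid))


def topology_report(graph: InteractionGraph, hub_direction: str = "out",
                    hub_threshold: int = 3) -> TopologyReport:
    """Assemble the full statistic row for one graph."""
    n, e = graph.node_count, graph.edge_count
    if n == 0:
        return TopologyReport(0, 0, 0, None, None, None, None, None,
                              None, None, [])
    components = nx.number_connected_components(graph.to_networkx_undirected())
    density = network_density(n, e) if n >= 2 else None
    neighbors = mean_distinct_neighbors(graph)
    try:
        mean_path, path_var, diameter = shortest_path_stats(graph)
    except UndefinedStatisticError:
        mean_path = path_var = diameter = None
    fit_in = fit_power_law(degree_distribution(graph, "in"))
    fit_out = fit_power_law(degree_distribution(graph, "out"))
    hubs = identify_hubs(graph, hub_direction, hub_threshold)
    return TopologyReport(
        n_nodes=n, n_edges=e, components=components,
        mean_neighbors=neighbors, mean_path=mean_path,
        path_variance=path_var, diameter=diameter, density=density,
        fit_in=fit_in, fit_out=fit_out, hubs=hubs,
    )


# ---------------------------------------------------------------------------
# formatting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["Node", "Edge", "Comp", "Nei", "Path", "Dia", "Den",
                  "Din", "Dout", "Rin", "Rout"]


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Decimal round-half-up (0.0245 -> 0.025 at 3 digits)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(value: float | None, ndigits: int = 3) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "na"
    return f"{round_half_up(value, ndigits):g}"


def report_row(report: TopologyReport, name: str = "graph") -> dict[str, str]:
    """One report as a table row with the canonical column order."""
    return {
        "Network": name,
        "Node": str(report.n_nodes),
        "Edge": str(report.n_edges),
        "Comp": str(report.components),
        "Nei": _fmt(report.mean_neighbors, 2),
        "Path": _fmt(report.mean_path, 2),
        "Dia": "na" if report.diameter is None else str(report.diameter),
        "Den": _fmt(report.density, 3),
        "Din": _fmt(report.fit_in.exponent if report.fit_in else None),
        "Dout": _fmt(report.fit_out.exponent if report.fit_out else None),
        "Rin": _fmt(report.fit_in.r2 if report.fit_in else None, 2),
        "Rout": _fmt(report.fit_out.r2 if report.fit_out else None, 2),
    }


def reports_to_frame(rows: list[dict[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["Network"] + REPORT_COLUMNS)
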