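"""Arc-diagram data model for the synchronous-pair graph.

Nodes are grouped by brain region and sorted within each group by graph
degree (number of distinct SP partners, descending; ties broken by cell
id). Node radii scale linearly with degree. Export/import round-trips
through GraphML or an edge-list CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["ArcLayout", "degree_layout", "export_graph", "import_graph"]


@dataclass
class ArcLayout:
    order: list[str]  # region-grouped, degree-sorted node order
    region: dict[str, str]
    degree: dict[str, int]
    radius: dict[str, float]
    edges: list[tuple[str, str, int, bool, str]]  # a, b, co_count, sp_flag, scope


def _sp_degree(graph: nx.Graph, node: str, weight: str) -> int:
    """Number of SP partners (or total SP co-firing count)."""
    total = 0
    for _, nbr, d in graph.edges(node, data=True):
        if d.get("sp_flag", False):
            total += d["co_count"] if weight == "sp_count" else 1
    return total


def degree_layout(
    graph: nx.Graph,
    r_min: float = 0.5,
    r_max: float = 2.0,
    weight: str = "partners",
) -> ArcLayout:
    """Deterministic arc-diagram ordering and node radii.

    ``weight="partners"`` (default) uses the number of distinct SP
    partners as the degree; ``weight="sp_count"`` uses the summed SP
    co-firing counts instead. Radii interpolate linearly between r_min
    and r_max; a graph with max degree 0 gets all radii r_min.
    """
    if weight not in ("partners", "sp_count"):
        raise ValueError("weight must be 'partners' or 'sp_count'")
    regions = nx.get_node_attributes(graph, "region")
    degree = {n: _sp_degree(graph, n, weight) for n in graph.nodes}
    max_deg = max(degree.values(), default=0)
    radius = {
        n: r_min + (r_max - r_min) * (d / max_deg if max_deg else 0.0)
        for n, d in degree.items()
    }
    order = sorted(
        graph.nodes, key=lambda n: (regions.get(n, ""), -degree[n], n)
    )
    edges = [
        (
            min(a, b),
            max(a, b),
            int(d["co_count"]),
            bool(d.get("sp_flag", False)),
            str(d.get("scope", "")),
        )
        for a, b, d in graph.edges(data=True)
    ]
    edges.sort()
    return ArcLayout(
        order=order, region=dict(regions), degree=degree, radius=radius,
        edges=edges,
    )


def export_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the SP graph losslessly as GraphML or edge-list CSV.

    The CSV form writes two files: ``<path>`` with the edges and
    ``<path>`` + ``.nodes.csv`` with the node/region table, so isolated
    nodes survive the round-trip.
    """
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "csv":
        edges = pd.DataFrame(
            [
                (a, b, d["co_count"], d.get("sp_flag", False), d.get("scope", ""))
                for a, b, d in graph.edges(data=True)
            ],
            columns=["cell_a", "cell_b", "co_count", "sp_flag", "scope"],
        )
        edges.to_csv(path, index=False)
        nodes = pd.DataFrame(
            [(n, d.get("region", "")) for n, d in graph.nodes(data=True)],
            columns=["cell_id", "region"],
        )
        nodes.to_csv(f"{path}.nodes.csv", index=False)
    else:
        raise ValueError("fmt must be 'graphml' or 'csv'")


def import_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Inverse of :func:`export_graph`."""
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for _, _, d in g.edges(data=True):
            d["co_count"] = int(d["co_count"])
            d["sp_flag"] = bool(d["sp_flag"]) if not isinstance(
                d["sp_flag"], str
            ) else d["sp_flag"] == "True"
        return g
    if fmt == "csv":
        g = nx.Graph()
        nodes = pd.read_csv(f"{path}.nodes.csv")
        for _, row in nodes.iterrows():
            g.add_node(str(row["cell_id"]), region=str(row["region"]))
        edges = pd.read_csv(path)
        for _, row in edges.iterrows():
            g.add_edge(
                str(row["cell_a"]),
                str(row["cell_b"]),
                co_count=int(row["co_count"]),
                sp_flag=bool(row["sp_flag"]),
                scope="" if pd.isna(row["scope"]) else str(row["scope"]),
            )
        return g
    raise ValueError("fmt must be 'graphml' or 'csv'")
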