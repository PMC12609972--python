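"""Confidence filtering and hub detection on scored interaction graphs.

Edges carry a confidence score in [0, 1] (STRING convention); analysis
keeps only high-confidence interactions (score >= 0.700 by default,
inclusive) and reports hub genes — nodes whose degree on the filtered graph
reaches a cutoff (>= 10 by default) — along with the connected-component
size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .exceptions import ValidationError


def build_graph(edges: pd.DataFrame, nodes=None) -> nx.Graph:
    """Undirected simple graph from a ``node1, node2, score`` frame.

    ``nodes`` optionally adds isolated vertices (genes with no edge).
    Self-loops are rejected; duplicate pairs keep the maximum score.
    """
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for row in edges.itertuples(index=False):
        a, b, s = str(row.node1), str(row.node2), float(row.score)
        if a == b:
            raise ValidationError(f"self-loop on {a!r}")
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"score {s} outside [0, 1] on ({a}, {b})")
        if graph.has_edge(a, b):
            s = max(s, graph[a][b]["score"])
        graph.add_edge(a, b, score=s)
    return graph


def filter_edges(graph: nx.Graph, min_score: float = 0.700) -> nx.Graph:
    """Drop edges below ``min_score`` (inclusive threshold); keep all nodes.

    Isolated nodes survive with degree 0 so downstream reports can still
    name every input gene.
    """
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    out.add_edges_from(
        (a, b, d) for a, b, d in graph.edges(data=True)
        if d["score"] >= min_score
    )
    return out


@dataclass
class HubReport:
    """Degrees, hub flags, and component sizes of a filtered graph."""

    degrees: dict
    min_degree: int
    component_sizes: list = field(default_factory=list)

    @property
    def hubs(self) -> list:
        return sorted(
            g for g, d in self.degrees.items() if d >= self.min_degree
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.degrees),
                "degree": list(self.degrees.values()),
                "is_hub": [
                    d >= self.min_degree for d in self.degrees.values()
                ],
            }
        ).sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "PPI hub report",
            "=" * 40,
            f"nodes {len(self.degrees)}, edges "
            f"{sum(self.degrees.values()) // 2}",
            f"hubs (degree >= {self.min_degree}): {len(self.hubs)}",
        ]
        for g in self.hubs[:15]:
            lines.append(f"  {g:<12} degree {self.degrees[g]}")
        lines.append(
            "component sizes: "
            + ", ".join(map(str, sorted(self.component_sizes, reverse=True)[:10]))
        )
        lines.append("=" * 40)
        return "\n".join(lines)


def find_hubs(graph: nx.Graph, min_degree: int = 10) -> HubReport:
    """Hub genes of a (filtered) interaction graph.

    Degrees are computed on the graph as given — filter first with
    :func:`filter_edges` for the high-confidence convention.
    """
    degrees = {str(n): int(d) for n, d in graph.degree()}
    sizes = [len(c) for c in nx.connected_components(graph)]
    return HubReport(
        degrees=degrees, min_degree=min_degree, component_sizes=sizes
    )
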