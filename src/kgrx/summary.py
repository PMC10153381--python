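"""Whole-network summary statistics.

The conventions follow common graph-exploration tooling for directed
graphs: average degree is E/N (edges per node, counting each stored edge
once) and density is E/(N(N-1)), while diameter and average path length
ignore edge direction and are computed on the largest connected component.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx

from .model import KnowledgeGraph


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Edges per node, E/N."""
    if n_nodes <= 0:
        raise ValueError("average degree undefined for an empty graph")
    return n_edges / n_nodes


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Directed density E/(N(N-1)); 0 for graphs with fewer than 2 nodes."""
    if n_nodes <= 0:
        raise ValueError("density undefined for an empty graph")
    if n_nodes == 1:
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1))


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    net_diameter: int
    average_path_length: float
    graph_density: float

    def to_dict(self) -> dict:
        return asdict(self)


def network_summary(graph: KnowledgeGraph) -> GraphSummary:
    """Summarize a knowledge graph.

    ``net_diameter`` is the maximal shortest-path hop count over node pairs
    of the largest connected component (direction ignored);
    ``average_path_length`` is the mean over all connected ordered pairs of
    that component.  ``n_edges`` counts the stored edge multiset.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot summarize an empty graph")
    und = graph.to_undirected_simple()
    largest_cc = max(nx.connected_components(und), key=len)
    component = und.subgraph(largest_cc)
    if component.number_of_nodes() > 1:
        diameter = nx.diameter(component)
        apl = nx.average_shortest_path_length(component)
    else:
        diameter = 0
        apl = 0.0
    return GraphSummary(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        average_degree=average_degree(graph.n_nodes, graph.n_edges),
        net_diameter=diameter,
        average_path_length=apl,
        graph_density=graph_density(graph.n_nodes, graph.n_edges),
    )
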