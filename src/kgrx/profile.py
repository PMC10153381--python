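"""Disease-profile network extraction.

The profile network around a disease cluster is the union of fixed-radius
ego graphs centered on each seed disease: every node within ``radius``
undirected hops of a seed, with all source-graph edges induced on that node
set.  Hop distance ignores edge direction and traverses equivalence and
semantic edges alike, since cross-source equivalence links are exactly what
stitches a concept's records together.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .model import GraphValidationError, KnowledgeGraph


@dataclass
class ProfileNetwork:
    """Union of radius-``radius`` ego graphs around ``seed_nodes``."""

    graph: KnowledgeGraph
    seed_nodes: list[str]
    radius: int


def ego_graph(source: KnowledgeGraph, center: str, radius: int) -> KnowledgeGraph:
    """Induced subgraph on all nodes within ``radius`` undirected hops of ``center``."""
    if not source.has_node(center):
        raise GraphValidationError(f"ego center {center!r} not in graph")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    und = source.to_undirected_simple()
    reachable = nx.single_source_shortest_path_length(und, center, cutoff=radius)
    return source.induced_subgraph(reachable)


def union_subgraphs(
    subgraphs: list[KnowledgeGraph], seeds: list[str], radius: int
) -> ProfileNetwork:
    """Merge ego graphs into one profile network.

    Node attributes must agree across copies (they are slices of one source
    graph); an identical (source, target, predicate) edge appearing in
    several subgraphs is kept once.
    """
    if not subgraphs:
        raise ValueError("need at least one subgraph")
    merged = KnowledgeGraph(
        directed=subgraphs[0].directed,
        equivalence_predicates=subgraphs[0].equivalence_predicates,
    )
    for sub in subgraphs:
        for node in sub.nodes():
            if merged.has_node(node.node_id):
                if merged.node(node.node_id) != node:
                    raise GraphValidationError(
                        f"conflicting attributes for shared node {node.node_id!r}"
                    )
            else:
                merged.add_node(node.copy())
    seen: set[tuple[str, str, str]] = set()
    for sub in subgraphs:
        for edge in sub.edges():
            if edge.key not in seen:
                seen.add(edge.key)
                merged.add_edge(edge.source, edge.target, edge.predicate)
    return ProfileNetwork(graph=merged, seed_nodes=list(seeds), radius=radius)


def extract_profile(
    source: KnowledgeGraph, seeds: list[str], radius: int = 3
) -> ProfileNetwork:
    """Build the profile network from a source graph and seed disease ids."""
    subgraphs = [ego_graph(source, seed, radius) for seed in seeds]
    return union_subgraphs(subgraphs, seeds, radius)
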