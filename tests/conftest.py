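"""Shared fixtures and graph-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from kgrx import KGNode, KnowledgeGraph


def make_graph(
    node_ids: list[str],
    edges: list[tuple[str, str, str]],
    node_types: dict[str, str] | None = None,
) -> KnowledgeGraph:
    """Build a small graph with one-name nodes and explicit typed edges."""
    g = KnowledgeGraph(directed=True)
    node_types = node_types or {}
    for node_id in node_ids:
        g.add_node(
            KGNode(
                node_id=node_id,
                names=[f"name of {node_id}"],
                node_type=node_types.get(node_id, "other"),
            )
        )
    for source, target, predicate in edges:
        g.add_edge(source, target, predicate)
    return g


def random_semantic_graph(n: int, p: float, seed: int) -> KnowledgeGraph:
    """Erdos-Renyi graph with semantic edges only, for analysis-stage tests."""
    rng = np.random.default_rng(seed)
    ids = [f"n{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((ids[i], ids[j], "related_to"))
    return make_graph(ids, edges)


@pytest.fixture
def star_graph() -> KnowledgeGraph:
    """Hub with 4 leaves, semantic edges."""
    ids = ["hub", "leaf1", "leaf2", "leaf3", "leaf4"]
    return make_graph(ids, [("hub", leaf, "related_to") for leaf in ids[1:]])


@pytest.fixture
def two_triangles_bridge() -> KnowledgeGraph:
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d (7 edges)."""
    edges = [
        ("a", "b", "related_to"),
        ("b", "c", "related_to"),
        ("a", "c", "related_to"),
        ("d", "e", "related_to"),
        ("e", "f", "related_to"),
        ("d", "f", "related_to"),
        ("c", "d", "related_to"),
    ]
    return make_graph(list("abcdef"), edges)
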