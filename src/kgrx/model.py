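"""Core domain types for typed biomedical knowledge graphs.

A knowledge graph here is a directed, typed multigraph whose nodes are
biomedical records (diseases, genes, phenotypes, drugs) aggregated from
multiple source databases.  Edges carry a free-form predicate; predicates
drawn from a configurable *equivalence set* (``N_Name``, ``I_CODE``,
``R_equivalentClass``, ``R_exactMatch`` by default) declare that their two
endpoints describe the same underlying concept in different sources, while
all other predicates are ordinary semantic relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

#: Predicates that declare cross-source concept equivalence.  ``N_Name``
#: links records sharing a concept name, ``I_CODE`` records sharing an
#: external reference code; the ``R_*`` pair are ontology-adopted predicates.
DEFAULT_EQUIVALENCE_PREDICATES: frozenset[str] = frozenset(
    {"N_Name", "I_CODE", "R_equivalentClass", "R_exactMatch"}
)

NODE_TYPES = ("disease", "gene", "phenotype", "drug", "other")


class GraphValidationError(ValueError):
    """A graph violates a structural invariant (dangling edge, empty name, ...)."""


class GraphParseError(ValueError):
    """A serialized graph file could not be parsed."""


@dataclass
class KGNode:
    """One record in the knowledge graph.

    Parameters
    ----------
    node_id
        Opaque unique identifier within a graph.
    node_type
        One of ``disease``, ``gene``, ``phenotype``, ``drug``, ``other``.
    names
        Ordered display labels; the first entry is the canonical name.
    synonyms
        Alternative labels registered for this record.
    source_refs
        External reference codes (ontology CURIEs and the like).
    merged_from
        Original node ids condensed into this record; empty before
        condensation, size >= 2 afterwards.
    attributes
        Flat string key/value map for everything else.
    """

    node_id: str
    names: list[str]
    node_type: str = "other"
    synonyms: set[str] = field(default_factory=set)
    source_refs: set[str] = field(default_factory=set)
    merged_from: set[str] = field(default_factory=set)
    attributes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.names:
            raise GraphValidationError(f"node {self.node_id!r}: names must be non-empty")
        if self.node_type not in NODE_TYPES:
            raise GraphValidationError(
                f"node {self.node_id!r}: unknown node_type {self.node_type!r}"
            )
        if len(self.merged_from) == 1:
            raise GraphValidationError(
                f"node {self.node_id!r}: merged_from must be empty or of size >= 2"
            )

    def copy(self) -> "KGNode":
        return KGNode(
            node_id=self.node_id,
            names=list(self.names),
            node_type=self.node_type,
            synonyms=set(self.synonyms),
            source_refs=set(self.source_refs),
            merged_from=set(self.merged_from),
            attributes=dict(self.attributes),
        )


@dataclass(frozen=True)
class KGEdge:
    """A directed typed edge.  ``edge_class`` is derived, not stored."""

    source: str
    target: str
    predicate: str

    def edge_class(self, equivalence_predicates: Iterable[str]) -> str:
        return "equivalence" if self.predicate in set(equivalence_predicates) else "semantic"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.predicate)


class KnowledgeGraph:
    """Directed typed multigraph over :class:`KGNode` records.

    Parallel edges with distinct predicates are preserved; ``n_edges``
    counts the multiset.  The ``equivalence_predicates`` set decides which
    edges are equivalence edges (used by condensation and generators).
    """

    def __init__(
        self,
        directed: bool = True,
        equivalence_predicates: Iterable[str] = DEFAULT_EQUIVALENCE_PREDICATES,
    ) -> None:
        self.directed = directed
        self.equivalence_predicates = frozenset(equivalence_predicates)
        self._nodes: dict[str, KGNode] = {}
        self._edges: list[KGEdge] = []

    # -- construction -------------------------------------------------

    def add_node(self, node: KGNode) -> None:
        node.validate()
        if node.node_id in self._nodes:
            raise GraphValidationError(f"duplicate node_id {node.node_id!r}")
        self._nodes[node.node_id] = node

    def add_edge(self, source: str, target: str, predicate: str) -> None:
        for endpoint in (source, target):
            if endpoint not in self._nodes:
                raise GraphValidationError(
                    f"edge ({source!r}, {target!r}, {predicate!r}) references "
                    f"missing node {endpoint!r}"
                )
        self._edges.append(KGEdge(source, target, predicate))

    # -- access --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, node_id: str) -> KGNode:
        return self._nodes[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def nodes(self) -> Iterator[KGNode]:
        return iter(self._nodes.values())

    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def edges(self) -> Iterator[KGEdge]:
        return iter(self._edges)

    def edge_class(self, edge: KGEdge) -> str:
        return edge.edge_class(self.equivalence_predicates)

    def equivalence_edges(self) -> list[KGEdge]:
        return [e for e in self._edges if self.edge_class(e) == "equivalence"]

    def semantic_edges(self) -> list[KGEdge]:
        return [e for e in self._edges if self.edge_class(e) == "semantic"]

    # -- derived views -------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        """Faithful multigraph view, one nx edge per stored edge."""
        g = nx.MultiDiGraph()
        for node_id in self._nodes:
            g.add_node(node_id)
        for e in self._edges:
            g.add_edge(e.source, e.target, predicate=e.predicate)
        return g

    def to_undirected_simple(self) -> nx.Graph:
        """Simple undirected view used by all analysis stages.

        Parallel edges (and anti-parallel duplicates) collapse to a single
        undirected edge; self-loops are never produced by valid pipelines
        but would be dropped here.
        """
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(
            (e.source, e.target) for e in self._edges if e.source != e.target
        )
        return g

    # -- invariants and comparison ------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`GraphValidationError`."""
        dangling = [
            e.key
            for e in self._edges
            if e.source not in self._nodes or e.target not in self._nodes
        ]
        if dangling:
            raise GraphValidationError(f"dangling edges: {dangling}")
        for node in self._nodes.values():
            node.validate()

    def edge_multiset(self) -> dict[tuple[str, str, str], int]:
        counts: dict[tuple[str, str, str], int] = {}
        for e in self._edges:
            counts[e.key] = counts.get(e.key, 0) + 1
        return counts

    def content_equal(self, other: "KnowledgeGraph") -> bool:
        """Equality on node set (with all attributes) and edge multiset."""
        if set(self._nodes) != set(other._nodes):
            return False
        if self.edge_multiset() != other.edge_multiset():
            return False
        for node_id, node in self._nodes.items():
            if node != other._nodes[node_id]:
                return False
        return True

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph(self.directed, self.equivalence_predicates)
        for node in self._nodes.values():
            g._nodes[node.node_id] = node.copy()
        g._edges = list(self._edges)
        return g

    def induced_subgraph(self, node_ids: Iterable[str]) -> "KnowledgeGraph":
        """Subgraph on ``node_ids`` keeping every edge with both endpoints inside."""
        keep = set(node_ids)
        missing = keep - set(self._nodes)
        if missing:
            raise GraphValidationError(f"unknown node ids: {sorted(missing)}")
        sub = KnowledgeGraph(self.directed, self.equivalence_predicates)
        for node_id in self._nodes:
            if node_id in keep:
                sub._nodes[node_id] = self._nodes[node_id].copy()
        sub._edges = [e for e in self._edges if e.source in keep and e.target in keep]
        return sub

    def __repr__(self) -> str:  # pragma: no cover
        return f"<KnowledgeGraph n_nodes={self.n_nodes} n_edges={self.n_edges}>"
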