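"""Graph condensation: merge equivalence-linked records into singular nodes.

Records linked (transitively) by equivalence edges describe one concept in
different source databases.  Condensation contracts each connected
component of the equivalence subgraph into a single node under three rules:

1. attributes of merged records are concatenated (lists) or unioned (sets);
2. every edge whose endpoints are co-merged is dropped — this removes the
   equivalence edges themselves and any semantic edge between co-merged
   records;
3. edges between a merged group and the outside are reattached to the new
   node, preserving the predicate and the outside endpoint.

After reattachment, duplicate (source, target, predicate) edges collapse to
one and no self-loops remain.  A final pass filters synonym labels out of
the concatenated name lists, so a merged node keeps one canonical display
name per distinct concept label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .model import (
    DEFAULT_EQUIVALENCE_PREDICATES,
    GraphValidationError,
    KGNode,
    KnowledgeGraph,
)


@dataclass
class MergePlan:
    """Partition of node ids into merge groups.

    ``groups`` maps each group's representative id (lexicographically
    smallest member) to the sorted list of member ids; singletons included.
    """

    groups: dict[str, list[str]]

    @property
    def group_of(self) -> dict[str, str]:
        return {m: rep for rep, members in self.groups.items() for m in members}

    def n_merged_groups(self) -> int:
        return sum(1 for members in self.groups.values() if len(members) > 1)


def plan_merges(
    graph: KnowledgeGraph,
    equivalence_predicates: Iterable[str] = DEFAULT_EQUIVALENCE_PREDICATES,
) -> MergePlan:
    """Group nodes by connected components over equivalence edges.

    Full transitive closure, not just adjacent pairs: a star of records all
    equivalence-linked to one hub merges in a single step, independent of
    edge order.
    """
    predicates = set(equivalence_predicates)
    if not predicates:
        raise ValueError("equivalence predicate set must be non-empty")
    equiv = nx.Graph()
    equiv.add_nodes_from(graph.node_ids())
    for edge in graph.edges():
        if edge.predicate in predicates and edge.source != edge.target:
            equiv.add_edge(edge.source, edge.target)
    groups: dict[str, list[str]] = {}
    for component in nx.connected_components(equiv):
        members = sorted(component)
        groups[members[0]] = members
    return MergePlan(groups=groups)


def _merge_nodes(members: list[KGNode], representative: str) -> KGNode:
    """Rule 1: concatenate list attributes, union set attributes."""
    names: list[str] = []
    synonyms: set[str] = set()
    source_refs: set[str] = set()
    node_types: list[str] = []
    attributes: dict[str, str] = {}
    for node in members:
        names.extend(node.names)
        synonyms |= node.synonyms
        source_refs |= node.source_refs
        if node.node_type not in node_types:
            node_types.append(node.node_type)
        for key, value in node.attributes.items():
            attributes[key] = value if key not in attributes else attributes[key] + "|" + value
    merged = KGNode(
        node_id=representative,
        names=names,
        node_type=node_types[0],
        synonyms=synonyms,
        source_refs=source_refs,
        merged_from={n.node_id for n in members},
        attributes=attributes,
    )
    if len(node_types) > 1:
        merged.attributes["member_types"] = "|".join(node_types)
    return merged


def apply_merges(graph: KnowledgeGraph, plan: MergePlan) -> KnowledgeGraph:
    """Contract each merge group into its representative node (rules 1-3)."""
    group_of = plan.group_of
    unknown = set(group_of) - set(graph.node_ids())
    if unknown:
        raise GraphValidationError(f"merge plan references unknown nodes: {sorted(unknown)}")
    uncovered = set(graph.node_ids()) - set(group_of)
    if uncovered:
        raise GraphValidationError(f"merge plan misses nodes: {sorted(uncovered)}")

    condensed = KnowledgeGraph(
        directed=graph.directed, equivalence_predicates=graph.equivalence_predicates
    )
    for representative, member_ids in sorted(plan.groups.items()):
        members = [graph.node(m) for m in member_ids]
        if len(members) == 1:
            condensed.add_node(members[0].copy())
        else:
            condensed.add_node(_merge_nodes(members, representative))

    seen: set[tuple[str, str, str]] = set()
    for edge in graph.edges():
        source = group_of[edge.source]
        target = group_of[edge.target]
        if source == target:  # rule 2: intra-group edges vanish
            continue
        key = (source, target, edge.predicate)
        if key not in seen:  # duplicates after reattachment collapse
            seen.add(key)
            condensed.add_edge(source, target, edge.predicate)
    return condensed


def build_synonym_index(graph: KnowledgeGraph) -> dict[str, set[str]]:
    """Registry mapping each record's canonical name to its registered synonyms."""
    index: dict[str, set[str]] = {}
    for node in graph.nodes():
        if node.synonyms:
            index.setdefault(node.names[0], set()).update(node.synonyms)
    return index


def filter_synonyms(node: KGNode, synonym_index: Mapping[str, Iterable[str]]) -> KGNode:
    """Demote name labels that are registered synonyms of earlier labels.

    A label is moved from ``names`` to ``synonyms`` when the registry marks
    it (case-insensitively) as a synonym of any earlier-listed label —
    whether that earlier label was itself retained or demoted, so synonym
    chains collapse onto the first-listed canonical name.  The first name
    is always kept, and the operation is idempotent.
    """
    if not node.names:
        raise GraphValidationError(f"node {node.node_id!r} has no names")
    lowered_index: dict[str, set[str]] = {}
    for name, synonyms in synonym_index.items():
        lowered_index.setdefault(name.lower(), set()).update(
            s.lower() for s in synonyms
        )
    out = node.copy()
    retained: list[str] = []
    seen_lower: list[str] = []
    for i, name in enumerate(node.names):
        is_synonym = i > 0 and any(
            name.lower() in lowered_index.get(earlier, set()) for earlier in seen_lower
        )
        if is_synonym:
            out.synonyms.add(name)
        else:
            retained.append(name)
        seen_lower.append(name.lower())
    out.names = retained
    return out


def condense(
    graph: KnowledgeGraph,
    equivalence_predicates: Iterable[str] = DEFAULT_EQUIVALENCE_PREDICATES,
    synonym_index: Mapping[str, Iterable[str]] | None = None,
) -> tuple[KnowledgeGraph, MergePlan]:
    """Plan and apply merges, then filter synonyms from merged name labels."""
    plan = plan_merges(graph, equivalence_predicates)
    condensed = apply_merges(graph, plan)
    index = build_synonym_index(graph) if synonym_index is None else synonym_index
    for representative, members in plan.groups.items():
        if len(members) > 1:
            node = condensed.node(representative)
            condensed._nodes[representative] = filter_synonyms(node, index)
    return condensed, plan
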