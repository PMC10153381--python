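"""Readers and writers for knowledge graphs: GraphML and node/edge TSV pairs.

The TSV dialect is UTF-8, tab-separated with a header row.  List- and
set-valued fields are serialized with a ``|`` separator; literal ``|``,
tabs, newlines and backslashes inside values are backslash-escaped, so
round-trips are lossless.  Element order is deterministic: nodes sorted by
id, edges by (source, target, predicate).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import networkx as nx

from .model import (
    DEFAULT_EQUIVALENCE_PREDICATES,
    GraphParseError,
    KGEdge,
    KGNode,
    KnowledgeGraph,
)

NODE_COLUMNS = [
    "node_id",
    "node_type",
    "names",
    "synonyms",
    "source_refs",
    "merged_from",
    "attributes",
]
EDGE_COLUMNS = ["source", "target", "predicate"]

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "|": "\\|", "=": "\\="}
_UNESCAPES = {"\\": "\\", "t": "\t", "n": "\n", "|": "|", "=": "="}


def escape_field(value: str, *, keep: str = "") -> str:
    """Backslash-escape separator characters, except those listed in ``keep``."""
    out = []
    for ch in value:
        if ch in _ESCAPES and ch not in keep:
            out.append(_ESCAPES[ch])
        else:
            out.append(ch)
    return "".join(out)


def split_unescaped(text: str, sep: str) -> list[str]:
    """Split on ``sep`` occurrences that are not backslash-escaped, and unescape."""
    parts: list[str] = []
    current: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\":
            if i + 1 >= len(text):
                raise GraphParseError(f"trailing backslash in field {text!r}")
            nxt = text[i + 1]
            if nxt not in _UNESCAPES:
                raise GraphParseError(f"unknown escape \\{nxt} in field {text!r}")
            current.append(_UNESCAPES[nxt])
            i += 2
        elif ch == sep:
            parts.append("".join(current))
            current = []
            i += 1
        else:
            current.append(ch)
            i += 1
    parts.append("".join(current))
    return parts


def join_list(values: Iterable[str]) -> str:
    return "|".join(escape_field(v) for v in values)


def split_list(text: str) -> list[str]:
    if text == "":
        return []
    return split_unescaped(text, "|")


def _attributes_to_field(attributes: dict[str, str]) -> str:
    items = [
        f"{escape_field(k)}={escape_field(v)}" for k, v in sorted(attributes.items())
    ]
    return "|".join(items)


def _attributes_from_field(text: str) -> dict[str, str]:
    attributes: dict[str, str] = {}
    if text == "":
        return attributes
    i = 0
    # split on unescaped '|' first, then each item on its unescaped '='
    for item in _split_keep_escapes(text, "|"):
        kv = _split_keep_escapes(item, "=")
        if len(kv) != 2:
            raise GraphParseError(f"malformed attribute item {item!r}")
        attributes[_unescape(kv[0])] = _unescape(kv[1])
    return attributes


def _split_keep_escapes(text: str, sep: str) -> list[str]:
    """Split on unescaped ``sep`` without unescaping the pieces."""
    parts: list[str] = []
    current: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            current.append(text[i : i + 2])
            i += 2
        elif ch == sep:
            parts.append("".join(current))
            current = []
            i += 1
        else:
            current.append(ch)
            i += 1
    parts.append("".join(current))
    return parts


def _unescape(text: str) -> str:
    return split_unescaped(text, "\x00")[0]


# ---------------------------------------------------------------------------
# TSV pair
# ---------------------------------------------------------------------------


def _tsv_paths(prefix: str | os.PathLike[str]) -> tuple[Path, Path]:
    prefix = Path(prefix)
    return (
        prefix.with_name(prefix.name + ".nodes.tsv"),
        prefix.with_name(prefix.name + ".edges.tsv"),
    )


def _sorted_nodes(graph: KnowledgeGraph) -> list[KGNode]:
    return sorted(graph.nodes(), key=lambda n: n.node_id)


def _sorted_edges(graph: KnowledgeGraph) -> list[KGEdge]:
    return sorted(graph.edges(), key=lambda e: e.key)


def write_tsv_pair(graph: KnowledgeGraph, prefix: str | os.PathLike[str]) -> None:
    node_path, edge_path = _tsv_paths(prefix)
    with open(node_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for node in _sorted_nodes(graph):
            row = [
                escape_field(node.node_id),
                escape_field(node.node_type),
                join_list(node.names),
                join_list(sorted(node.synonyms)),
                join_list(sorted(node.source_refs)),
                join_list(sorted(node.merged_from)),
                _attributes_to_field(node.attributes),
            ]
            fh.write("\t".join(row) + "\n")
    with open(edge_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for edge in _sorted_edges(graph):
            fh.write(
                "\t".join(
                    escape_field(v) for v in (edge.source, edge.target, edge.predicate)
                )
                + "\n"
            )


def read_tsv_pair(
    prefix: str | os.PathLike[str],
    equivalence_predicates: Iterable[str] = DEFAULT_EQUIVALENCE_PREDICATES,
) -> KnowledgeGraph:
    node_path, edge_path = _tsv_paths(prefix)
    graph = KnowledgeGraph(directed=True, equivalence_predicates=equivalence_predicates)
    with open(node_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != NODE_COLUMNS:
            raise GraphParseError(f"{node_path}: unexpected node header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = _split_keep_escapes(line, "\t")
            if len(fields) != len(NODE_COLUMNS):
                raise GraphParseError(
                    f"{node_path}:{lineno}: expected {len(NODE_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            node_id, node_type, names, synonyms, source_refs, merged_from, attrs = fields
            graph.add_node(
                KGNode(
                    node_id=_unescape(node_id),
                    node_type=_unescape(node_type),
                    names=split_list(names),
                    synonyms=set(split_list(synonyms)),
                    source_refs=set(split_list(source_refs)),
                    merged_from=set(split_list(merged_from)),
                    attributes=_attributes_from_field(attrs),
                )
            )
    with open(edge_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGE_COLUMNS:
            raise GraphParseError(f"{edge_path}: unexpected edge header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = _split_keep_escapes(line, "\t")
            if len(fields) != 3:
                raise GraphParseError(
                    f"{edge_path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            source, target, predicate = (_unescape(f) for f in fields)
            graph.add_edge(source, target, predicate)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def write_graphml(graph: KnowledgeGraph, path: str | os.PathLike[str]) -> None:
    g = nx.MultiDiGraph()
    for node in _sorted_nodes(graph):
        g.add_node(
            node.node_id,
            node_type=node.node_type,
            names=join_list(node.names),
            synonyms=join_list(sorted(node.synonyms)),
            source_refs=join_list(sorted(node.source_refs)),
            merged_from=join_list(sorted(node.merged_from)),
            attributes=_attributes_to_field(node.attributes),
        )
    for edge in _sorted_edges(graph):
        g.add_edge(
            edge.source,
            edge.target,
            predicate=edge.predicate,
            edge_class=graph.edge_class(edge),
        )
    nx.write_graphml(g, path, encoding="utf-8")


def read_graphml(
    path: str | os.PathLike[str],
    equivalence_predicates: Iterable[str] = DEFAULT_EQUIVALENCE_PREDICATES,
) -> KnowledgeGraph:
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # nx raises a zoo of parse errors
        raise GraphParseError(f"{path}: {exc}") from exc
    graph = KnowledgeGraph(directed=True, equivalence_predicates=equivalence_predicates)
    for node_id, data in sorted(g.nodes(data=True)):
        graph.add_node(
            KGNode(
                node_id=str(node_id),
                node_type=data.get("node_type", "other"),
                names=split_list(data.get("names", "")) or [str(node_id)],
                synonyms=set(split_list(data.get("synonyms", ""))),
                source_refs=set(split_list(data.get("source_refs", ""))),
                merged_from=set(split_list(data.get("merged_from", ""))),
                attributes=_attributes_from_field(data.get("attributes", "")),
            )
        )
    for source, target, data in sorted(
        g.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("predicate", ""))
    ):
        graph.add_edge(str(source), str(target), data.get("predicate", "related_to"))
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Format dispatch
# ---------------------------------------------------------------------------


def read_graph(
    path: str | os.PathLike[str],
    format: str = "graphml",
    equivalence_predicates: Iterable[str] = DEFAULT_EQUIVALENCE_PREDICATES,
) -> KnowledgeGraph:
    """Read a knowledge graph from ``graphml`` or a ``tsv_pair`` prefix."""
    if format == "graphml":
        return read_graphml(path, equivalence_predicates)
    if format == "tsv_pair":
        return read_tsv_pair(path, equivalence_predicates)
    raise ValueError(f"unknown format {format!r}")


def write_graph(
    graph: KnowledgeGraph, path: str | os.PathLike[str], format: str = "graphml"
) -> None:
    """Write a knowledge graph as ``graphml`` or a ``tsv_pair`` prefix."""
    if format == "graphml":
        write_graphml(graph, path)
    elif format == "tsv_pair":
        write_tsv_pair(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")
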