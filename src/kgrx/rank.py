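"""Centrality-ensemble candidate ranking within communities.

For each top-ranked community the pipeline computes five centralities on
the community's induced subgraph (undirected, unweighted): degree,
closeness, betweenness, eigenvector and PageRank.  The top-k nodes per
measure are extracted; each measure's top-k scores are min-max rescaled to
[0, 1] (scikit-learn MinMaxScaler semantics) and every candidate — the
union of the five top-k lists — is scored on all five rescaled axes, with
values outside a measure's fitted range clipped into [0, 1].  The Total
Normalized Centrality Score (TNCS) of a node is the sum of its five
normalized scores, bounded by [0, 5]; the node with the highest TNCS in
each community is that community's repurposing candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from pydantic import BaseModel, Field
from sklearn.preprocessing import MinMaxScaler

from .communities import Community
from .model import KnowledgeGraph

MEASURES = ("degree", "closeness", "betweenness", "eigenvector", "pagerank")


class CentralityParams(BaseModel):
    """Eigenvector iteration count and PageRank damping/termination.

    Eigenvector centrality runs a fixed number of power-iteration steps
    with max-norm scaling rather than iterating to a tolerance; within
    50-200 iterations the ranking is insensitive to the exact count.
    """

    eigenvector_iterations: int = Field(default=100, ge=1)
    pagerank_damping: float = Field(default=0.85, gt=0, lt=1)
    pagerank_epsilon: float = Field(default=0.001, gt=0)
    #: fit min-max rescaling on the top-k scores per measure ("top_k") or on
    #: the whole community's scores ("all")
    normalization_fit: str = Field(default="top_k", pattern="^(top_k|all)$")


@dataclass
class CentralityVector:
    node_id: str
    degree: float
    closeness: float
    betweenness: float
    eigenvector: float
    pagerank: float

    def get(self, measure: str) -> float:
        if measure not in MEASURES:
            raise KeyError(f"unknown centrality measure {measure!r}")
        return getattr(self, measure)


@dataclass
class RankRecord:
    node_id: str
    community_index: int
    raw: dict[str, float]
    normalized: dict[str, float]
    tncs: float
    is_candidate: bool = False


def _eigenvector_centrality(graph: nx.Graph, iterations: int) -> dict[str, float]:
    """Power iteration for a fixed step count, max-norm scaled into [0, 1].

    Iterates the shifted operator A + I: same eigenvectors as the adjacency
    matrix A, but free of the period-2 oscillation plain power iteration
    exhibits on bipartite graphs (where +lambda_max and -lambda_max tie).
    """
    nodes = list(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    x = np.ones(len(nodes))
    for _ in range(iterations):
        x_next = a @ x + x
        top = x_next.max()
        if top <= 0:  # unreachable for a non-negative start; defensive
            x = np.zeros(len(nodes))
            break
        x = x_next / top
    if graph.number_of_edges() == 0:
        return {n: 0.0 for n in nodes}
    return dict(zip(nodes, x.tolist()))


def compute_centralities(
    community_subgraph: KnowledgeGraph, params: CentralityParams | None = None
) -> list[CentralityVector]:
    """Five centralities for every node of one community's induced subgraph.

    Degree is the raw incident-edge count; closeness uses the
    within-component convention (reachable nodes over summed distances,
    zero for isolates); betweenness is the normalized shortest-path
    fraction; PageRank iterates at the configured damping until the
    successive-vector change falls below epsilon.
    """
    params = params or CentralityParams()
    if community_subgraph.n_nodes == 0:
        raise ValueError("cannot compute centralities on an empty subgraph")
    g = community_subgraph.to_undirected_simple()
    degree = dict(g.degree)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    eigenvector = _eigenvector_centrality(g, params.eigenvector_iterations)
    if g.number_of_edges() > 0:
        pagerank = nx.pagerank(
            g, alpha=params.pagerank_damping, tol=params.pagerank_epsilon
        )
    else:
        pagerank = {n: 1.0 / g.number_of_nodes() for n in g.nodes}
    return [
        CentralityVector(
            node_id=n,
            degree=float(degree[n]),
            closeness=float(closeness[n]),
            betweenness=float(betweenness[n]),
            eigenvector=float(eigenvector[n]),
            pagerank=float(pagerank[n]),
        )
        for n in sorted(g.nodes)
    ]


def top_k_nodes(vectors: list[CentralityVector], measure: str, k: int) -> list[str]:
    """The k highest-scoring node ids on one measure, ties by node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(vectors, key=lambda v: (-v.get(measure), v.node_id))
    return [v.node_id for v in ordered[:k]]


def normalize_top_scores(
    vectors: list[CentralityVector],
    k: int,
    community_index: int = 0,
    params: CentralityParams | None = None,
) -> list[RankRecord]:
    """Min-max normalize candidates' scores and assemble their TNCS.

    Candidates are the union of top-k lists over the five measures.  With
    ``normalization_fit="top_k"`` (default) each measure's rescaling is fit
    on its own top-k scores and applied with clipping; with ``"all"`` it is
    fit on the whole community.  A zero-range measure normalizes to 0.
    """
    params = params or CentralityParams()
    if not vectors:
        raise ValueError("no centrality vectors given")
    by_id = {v.node_id: v for v in vectors}
    candidates = sorted(
        {n for measure in MEASURES for n in top_k_nodes(vectors, measure, k)}
    )
    normalized: dict[str, dict[str, float]] = {n: {} for n in candidates}
    for measure in MEASURES:
        if params.normalization_fit == "top_k":
            fit_ids = top_k_nodes(vectors, measure, k)
        else:
            fit_ids = [v.node_id for v in vectors]
        fit_scores = np.array([[by_id[n].get(measure)] for n in fit_ids])
        if np.ptp(fit_scores) == 0:
            for n in candidates:
                normalized[n][measure] = 0.0
            continue
        scaler = MinMaxScaler().fit(fit_scores)
        raw = np.array([[by_id[n].get(measure)] for n in candidates])
        scaled = np.clip(scaler.transform(raw), 0.0, 1.0).ravel()
        for n, value in zip(candidates, scaled.tolist()):
            normalized[n][measure] = value
    return [
        RankRecord(
            node_id=n,
            community_index=community_index,
            raw={measure: by_id[n].get(measure) for measure in MEASURES},
            normalized=normalized[n],
            tncs=tncs(normalized[n]),
        )
        for n in candidates
    ]


def tncs(normalized: dict[str, float]) -> float:
    """Total Normalized Centrality Score: sum over the five measures."""
    missing = [m for m in MEASURES if m not in normalized]
    if missing:
        raise ValueError(f"missing normalized measures: {missing}")
    return float(sum(normalized[m] for m in MEASURES))


def select_candidates(
    ranked_communities: list[Community],
    graph: KnowledgeGraph,
    params: CentralityParams | None = None,
    top_n_communities: int = 10,
    k: int = 5,
) -> list[RankRecord]:
    """Rank nodes inside each of the top communities and flag candidates.

    Returns the full per-community rank records (the top-k union per
    measure with normalized scores and TNCS); within each community the
    record with maximal TNCS (ties by node id) carries ``is_candidate``.
    Communities beyond ``top_n_communities`` are ignored; if fewer exist,
    all are used.
    """
    params = params or CentralityParams()
    records: list[RankRecord] = []
    for community in ranked_communities[:top_n_communities]:
        sub = graph.induced_subgraph(community.members)
        vectors = compute_centralities(sub, params)
        community_records = normalize_top_scores(
            vectors, k, community_index=community.index, params=params
        )
        best = min(community_records, key=lambda r: (-r.tncs, r.node_id))
        best.is_candidate = True
        records.extend(community_records)
    return records
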