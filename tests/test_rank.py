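"""Centrality computation, min-max normalization and TNCS candidate selection."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from kgrx import (
    CentralityParams,
    Community,
    compute_centralities,
    normalize_top_scores,
    select_candidates,
    tncs,
    top_k_nodes,
)
from kgrx.model import KnowledgeGraph

from conftest import make_graph, random_semantic_graph


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx)
# ---------------------------------------------------------------------------


def adjacency(graph):
    adj: dict[str, set[str]] = {n: set() for n in graph.node_ids()}
    for e in graph.edges():
        if e.source != e.target:
            adj[e.source].add(e.target)
            adj[e.target].add(e.source)
    return adj


def bfs_distances(adj, start):
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_closeness(graph):
    """(reachable - 1) / summed distance within the node's component."""
    adj = adjacency(graph)
    out = {}
    for n in adj:
        dist = bfs_distances(adj, n)
        total = sum(dist.values())
        out[n] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def count_shortest_paths(adj, dist, s, t):
    """Number of shortest s-t paths and, per intermediate node, how many
    pass through it — by explicit path enumeration on the BFS DAG."""
    if t not in dist:
        return 0, {}
    through: dict[str, int] = {}
    total = 0
    stack = [(t, [t])]
    while stack:
        u, path = stack.pop()
        if u == s:
            total += 1
            for v in path[1:-1]:
                through[v] = through.get(v, 0) + 1
            continue
        for v in adj[u]:
            if dist.get(v, -1) == dist[u] - 1:
                stack.append((v, path + [v]))
    return total, through


def brute_betweenness(graph):
    """Normalized betweenness by enumerating every shortest path."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            sigma, through = count_shortest_paths(adj, dist, s, t)
            if sigma == 0:
                continue
            for v, count in through.items():
                score[v] += count / sigma
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return {v: score[v] * scale for v in nodes}


def vectors_by_id(vectors):
    return {v.node_id: v for v in vectors}


# ---------------------------------------------------------------------------


class TestCentralities:
    def test_star_closed_forms(self, star_graph):
        by_id = vectors_by_id(compute_centralities(star_graph))
        hub = by_id["hub"]
        assert hub.degree == 4
        assert hub.betweenness == 1.0
        assert hub.closeness == 1.0
        assert hub.eigenvector == 1.0
        leaf = by_id["leaf1"]
        assert leaf.degree == 1
        assert leaf.betweenness == 0.0
        assert leaf.closeness == pytest.approx(4 / 7)

    def test_clique_closed_forms(self):
        import itertools

        ids = list("abcde")
        g = make_graph(ids, [(u, v, "x") for u, v in itertools.combinations(ids, 2)])
        for v in compute_centralities(g):
            assert v.degree == 4
            assert v.closeness == 1.0
            assert v.betweenness == 0.0
            assert v.eigenvector == pytest.approx(1.0)
            assert v.pagerank == pytest.approx(0.2, abs=1e-6)

    def test_single_edge_pagerank_symmetry(self):
        g = make_graph(["a", "b"], [("a", "b", "x")])
        by_id = vectors_by_id(compute_centralities(g))
        assert by_id["a"].pagerank == pytest.approx(0.5)
        assert by_id["b"].pagerank == pytest.approx(0.5)

    @pytest.mark.parametrize("n,p,seed", [(15, 0.2, 0), (30, 0.12, 1), (60, 0.08, 2)])
    def test_degree_closeness_betweenness_match_brute_force(self, n, p, seed):
        g = random_semantic_graph(n, p, seed)
        vectors = compute_centralities(g)
        closeness = brute_closeness(g)
        betweenness = brute_betweenness(g)
        adj = adjacency(g)
        for v in vectors:
            assert v.degree == len(adj[v.node_id])
            assert v.closeness == pytest.approx(closeness[v.node_id], abs=1e-9)
            assert v.betweenness == pytest.approx(betweenness[v.node_id], abs=1e-9)

    def test_eigenvector_matches_dominant_eigenvector(self):
        """100 power-iteration steps reach the adjacency operator's dominant
        eigenvector (max-norm scaled) on a well-connected graph."""
        import networkx as nx

        g = random_semantic_graph(30, 0.3, seed=6)
        und = g.to_undirected_simple()
        nodes = sorted(und.nodes)
        a = nx.to_numpy_array(und, nodelist=nodes)
        eigenvalues, eigenvectors = np.linalg.eigh(a)
        dominant = np.abs(eigenvectors[:, np.argmax(eigenvalues)])
        dominant /= dominant.max()
        by_id = vectors_by_id(compute_centralities(g))
        for node, expected in zip(nodes, dominant):
            assert by_id[node].eigenvector == pytest.approx(expected, abs=1e-6)

    def test_bounded_measures_stay_in_unit_interval(self):
        g = random_semantic_graph(40, 0.05, seed=8)  # sparse, possibly disconnected
        for v in compute_centralities(g):
            for value in (v.closeness, v.eigenvector, v.pagerank):
                assert 0.0 <= value <= 1.0
            assert v.betweenness >= 0.0

    def test_empty_subgraph_errors(self):
        with pytest.raises(ValueError):
            compute_centralities(KnowledgeGraph())


class TestTopK:
    def test_k_larger_than_community_returns_all(self, star_graph):
        vectors = compute_centralities(star_graph)
        assert len(top_k_nodes(vectors, "degree", 50)) == 5

    def test_star_degree_top1_is_hub(self, star_graph):
        vectors = compute_centralities(star_graph)
        assert top_k_nodes(vectors, "degree", 1) == ["hub"]

    def test_ties_break_lexicographically(self):
        g = make_graph(
            ["z", "y", "x", "w"],
            [("z", "y", "e"), ("y", "x", "e"), ("x", "w", "e"), ("w", "z", "e")],
        )  # 4-cycle: all degrees equal
        vectors = compute_centralities(g)
        explicit = sorted(v.node_id for v in vectors)[:3]
        assert top_k_nodes(vectors, "degree", 3) == explicit

    def test_unknown_measure_errors(self, star_graph):
        vectors = compute_centralities(star_graph)
        with pytest.raises(KeyError):
            top_k_nodes(vectors, "charisma", 2)


class TestNormalization:
    def test_max_maps_to_one_min_maps_to_zero(self):
        g = random_semantic_graph(20, 0.25, seed=3)
        vectors = compute_centralities(g)
        records = {r.node_id: r for r in normalize_top_scores(vectors, k=5)}
        for measure in ("degree", "closeness", "betweenness"):
            top5 = top_k_nodes(vectors, measure, 5)
            top_scores = [r for r in records.values() if r.node_id in top5]
            assert records[top5[0]].normalized[measure] == pytest.approx(1.0)
            assert min(r.normalized[measure] for r in top_scores) == pytest.approx(0.0)

    def test_dominant_node_scores_one_everywhere(self, star_graph):
        vectors = compute_centralities(star_graph)
        records = {r.node_id: r for r in normalize_top_scores(vectors, k=5)}
        assert all(v == 1.0 for v in records["hub"].normalized.values())

    def test_zero_range_measure_normalizes_to_zero(self):
        g = make_graph(
            ["a", "b", "c"], [("a", "b", "e"), ("b", "c", "e"), ("c", "a", "e")]
        )  # triangle: every measure constant
        records = normalize_top_scores(compute_centralities(g), k=3)
        for r in records:
            assert all(v == 0.0 for v in r.normalized.values())
            assert r.tncs == 0.0

    def test_scale_invariance(self):
        g = random_semantic_graph(25, 0.2, seed=5)
        vectors = compute_centralities(g)
        scaled = [
            type(v)(
                node_id=v.node_id,
                degree=v.degree * 37.5,  # rescaling one measure changes nothing
                closeness=v.closeness,
                betweenness=v.betweenness,
                eigenvector=v.eigenvector,
                pagerank=v.pagerank,
            )
            for v in vectors
        ]
        original = {r.node_id: r.normalized for r in normalize_top_scores(vectors, k=5)}
        rescaled = {r.node_id: r.normalized for r in normalize_top_scores(scaled, k=5)}
        for node_id in original:
            for m in original[node_id]:
                assert original[node_id][m] == pytest.approx(rescaled[node_id][m])

    def test_fit_on_all_community_scores_option(self):
        g = random_semantic_graph(20, 0.25, seed=7)
        vectors = compute_centralities(g)
        params = CentralityParams(normalization_fit="all")
        records = normalize_top_scores(vectors, k=5, params=params)
        assert all(0.0 <= v <= 1.0 for r in records for v in r.normalized.values())


class TestTNCS:
    def test_sum_of_normalized_values(self):
        assert tncs(
            dict(degree=1, closeness=0.5, betweenness=0.25, eigenvector=1, pagerank=0.5)
        ) == pytest.approx(3.25)

    def test_missing_measure_errors(self):
        with pytest.raises(ValueError, match="missing"):
            tncs({"degree": 1.0})

    def test_bounds_on_random_communities(self):
        for seed in range(5):
            g = random_semantic_graph(30, 0.15, seed=seed)
            for r in normalize_top_scores(compute_centralities(g), k=5):
                assert 0.0 <= r.tncs <= 5.0


class TestSelectCandidates:
    def test_star_center_selected_with_full_score(self, star_graph):
        community = Community(
            index=0, members=set(star_graph.node_ids()), L_c=4, k_c=8, score=0.1
        )
        records = select_candidates([community], star_graph, top_n_communities=1, k=5)
        candidates = [r for r in records if r.is_candidate]
        assert len(candidates) == 1
        assert candidates[0].node_id == "hub"
        assert candidates[0].tncs == 5.0

    def test_one_candidate_per_community(self):
        g = random_semantic_graph(80, 0.06, seed=10)
        from kgrx import detect_communities, rank_communities

        ranked = rank_communities(detect_communities(g), min_size=4)
        records = select_candidates(ranked, g, top_n_communities=3, k=5)
        candidates = [r for r in records if r.is_candidate]
        assert len(candidates) == min(3, len(ranked))
        indices = {r.community_index for r in candidates}
        assert len(indices) == len(candidates)
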