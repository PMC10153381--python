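# Methods

## Graph model and conventions

A knowledge graph is stored as a directed typed multigraph: nodes carry an
ordered name list (first entry canonical), synonym and external-reference
sets, and a flat attribute map; edges carry a free-form predicate. Edges
whose predicate belongs to the configurable equivalence set (`N_Name`,
`I_CODE`, `R_equivalentClass`, `R_exactMatch` by default) are *equivalence*
edges declaring cross-source concept identity; all others are *semantic*.
Parallel edges with distinct predicates are preserved in storage and counted
by `n_edges`.

All analysis stages — hop distance for ego graphs, community detection,
centralities — view the graph as simple and undirected: direction is a
storage convention of the source databases, Louvain and the centrality
ensemble are defined on undirected graphs, and after condensation duplicate
(source, target, predicate) edges have already collapsed, so each remaining
link counts once.

Summary statistics intentionally mix conventions, matching common
graph-exploration tooling for directed graphs: average degree is E/N and
density E/(N(N−1)) on the stored (directed multiset) counts, while diameter
and average path length are undirected and restricted to the largest
connected component, so they are defined for disconnected inputs. At
N = 1,466 and E = 107,423 these conventions give 73.276 and 0.050; the
undirected alternatives (2E/N, 2E/(N(N−1))) would give 146.55 and 0.100.

## Synthetic generator

The generator emulates a multi-source rare-disease knowledge graph well
enough to exercise and validate every pipeline stage against planted truth:

- **Duplication.** Each concept is emitted as 1–4 records with default
  weights {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1} — singleton-heavy, reflecting
  that most concepts in an aggregated KG come from a single database while a
  minority are widely cross-referenced. Records of one concept are linked by
  a random spanning tree of equivalence edges plus occasional extra pairs
  (probability 0.25): connected components without forcing cliques.
  Equivalence edges never cross concepts, so condensation has an exact
  ground truth.
- **Synonyms.** With probability `synonym_rate` (default 0.5) a duplicate
  record carries a synonym label instead of the canonical name; the
  canonical record registers those labels in its `synonyms` field, which is
  what the post-merge synonym filter consults.
- **Community structure.** Semantic edges follow a stochastic block model
  over concepts: blocks are assigned round-robin within each node type
  (balanced composition), an edge is drawn with `p_intra` = 0.08 inside a
  block and `p_inter` = 0.005 across, then attached between uniformly chosen
  records of the two concepts. Predicates come from a small fixed vocabulary
  keyed by the endpoint types (disease–gene `associated_with`,
  drug–disease `indicated_for`, ...).
- **Scale.** Defaults (400 diseases, 200 genes, 150 phenotypes, 100 drugs,
  4 blocks, 92 seed diseases drawn from the disease-richest block) yield
  ≈1.7k records and ≈9.5k edges — the same node order as a condensed
  real-world disease profile, at a density that keeps a full run near ten
  seconds.

What the generator does **not** emulate: heavy-tailed degree distributions,
hub diseases, type-dependent edge density, noisy or wrong equivalence links,
and overlapping communities. Passing tests therefore demonstrate
correctness of the algorithms (exact concept recovery, planted-block
recovery, determinism), not performance claims about any particular
production knowledge graph.

Everything is driven by one `numpy` generator seeded with `rng_seed`;
identical parameters give byte-identical outputs.

## Condensation

Merge groups are the connected components of the equivalence subgraph
(transitive closure) — a star of records equivalence-linked to one hub
merges in a single step, independent of edge order. The representative id is
the lexicographically smallest member, for reproducibility. Merging
concatenates name lists in member-id order and unions the set-valued fields
(lossless); intra-group edges vanish; boundary edges are reattached,
inheriting predicate and outside endpoint; reattachment duplicates collapse.
Reattachment is also where inference enters: records merged through a shared
hub inherit each other's neighborhoods. Condensing an already-condensed
graph is the identity.

The synonym filter is first-occurrence-wins: scanning the merged name list
in order, a label is demoted to the synonym set when the registry marks it
(case-insensitively) as a synonym of *any earlier-listed* label, whether that
label was itself retained or demoted. Checking against demoted labels too
makes synonym chains (C synonym of B, B synonym of A) collapse onto the
canonical first name in one pass and makes the operation idempotent; the
first name is always kept. The registry is built from the in-graph
`synonyms` attributes; no external resources are consulted.

## Community detection and scoring

Louvain at resolution γ (default 1.0) with a fixed RNG seed; community
indices are relabeled by decreasing size (ties by smallest member id) so
labels are stable across runs. Each community is scored by its modularity
contribution L_c/m − γ(k_c/2m)²; at γ = 1 the scores sum to Newman–Girvan
modularity, which the tests verify against an independent implementation to
1e-12. Communities need more than three nodes to be ranked (`min_size` = 4):
smaller classes cannot support a meaningful five-measure ranking. Ranking
ties break toward the larger community, then the smaller index.

## Centralities and TNCS

On each community's induced subgraph (undirected, unweighted):

- **degree** — raw incident-edge count;
- **closeness** — within-component convention, reachable nodes over summed
  distances, 0 for isolates (keeps the value in [0, 1] on disconnected
  communities);
- **betweenness** — normalized shortest-path fraction;
- **eigenvector** — power iteration for exactly `eigenvector_iterations`
  (default 100) steps with max-norm scaling. The iterated operator is
  A + I rather than A: identical eigenvectors, but immune to the period-2
  oscillation plain power iteration exhibits on bipartite subgraphs (a
  star community is the canonical failure case), and within 50–200
  iterations the resulting ranking is insensitive to the exact count;
- **PageRank** — damping 0.85, iterated until the successive-vector change
  drops below epsilon = 0.001.

Per measure, the top-5 nodes are extracted (ties broken by node id); min-max
rescaling is fit on those top-5 scores and applied, with clipping to [0, 1],
to every *candidate* — the union of the five top-5 lists. Fitting on the
top-k keeps the TNCS of a candidate outside some measure's top-5 bounded;
the alternative of fitting on the whole community is available via
`CentralityParams(normalization_fit="all")`. A measure whose fitted scores
have zero range normalizes to 0 for everyone (the lower-bound convention of
a min-max rescaler on constant data) — consequently the analytic TNCS = 5
ceiling certifies a node that *strictly* dominates each measure's fitted
range. TNCS is the plain sum of the five normalized values, in [0, 5]; the
highest-TNCS node per community (ties by node id) is flagged as that
community's candidate.

## Pipeline and reproducibility

A run is configured by one validated document naming exactly one input
source (stored graph + seed list, or generator parameters). Stages execute
in order with node/edge counts logged after each; outputs are the condensed
profile network, its summary, the community table, the ranking table, the
candidate table, a merge audit and a manifest holding the configuration,
the seed nodes and SHA-256 digests of every output. All randomness (the
generator and Louvain) flows from configured seeds, and writers emit
deterministically ordered records, so identical configurations produce
byte-identical outputs. A stage failure aborts the run with the stage name
and removes partial outputs.

## Limitations

- Merge quality is only as good as the equivalence edges: one wrong
  equivalence link fuses two concepts irreversibly (no fuzzy matching, no
  identifier resolution, no conflict handling beyond recording member
  types).
- The per-community modularity score depends on the global edge count m, so
  scores are comparable within one network but not across networks.
- Candidate selection is purely structural; no literature or clinical
  evidence enters the ranking.
- Test problem sizes (tens to hundreds of concepts per graph, 20 generator
  seeds for recovery checks, random graphs up to 200 nodes for modularity
  and 60 for centrality oracles) were chosen to make the full suite run in
  seconds while still exercising disconnected, tied and degenerate cases.
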