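"""Synthetic multi-source knowledge-graph generator.

Emulates a rare-disease knowledge graph aggregated from several source
databases: each underlying biomedical *concept* (a disease, gene, phenotype
or drug) appears as 1-4 duplicate records — one per contributing source —
pairwise linked by equivalence edges (``N_Name``, ``I_CODE``,
``R_equivalentClass``, ``R_exactMatch``).  Semantic relations between
concepts follow a planted stochastic block model: concepts are assigned to
blocks, and an edge between two concepts is drawn with probability
``p_intra`` inside a block and ``p_inter`` across blocks, then attached
between uniformly chosen records of the two concepts.  A designated cluster
of seed diseases is drawn from a single block, standing in for an
externally supplied disease cluster.

Generation is fully deterministic under ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import DEFAULT_EQUIVALENCE_PREDICATES, KGNode, KnowledgeGraph

#: Semantic predicate vocabulary keyed by (source type, target type).  Pairs
#: listed here fix the edge direction; unlisted pairs fall back to
#: ``related_to`` in generation order.
SEMANTIC_PREDICATES: dict[tuple[str, str], str] = {
    ("disease", "gene"): "associated_with",
    ("disease", "phenotype"): "has_phenotype",
    ("disease", "disease"): "related_to",
    ("drug", "disease"): "indicated_for",
    ("drug", "gene"): "targets",
    ("drug", "phenotype"): "modulates",
    ("drug", "drug"): "related_to",
    ("gene", "phenotype"): "influences",
    ("gene", "gene"): "interacts_with",
    ("phenotype", "phenotype"): "related_to",
}


class SynthParams(BaseModel):
    """Generator configuration.

    Defaults target a desk-scale graph of the same order as a condensed
    disease-profile network (~1.5k records): enough diseases that a 92-seed
    cluster fits inside one block, sparse semantic density, and a
    singleton-heavy duplication profile typical of multi-source aggregation
    where most concepts come from one database.
    """

    n_concepts_per_type: dict[str, int] = Field(
        default={"disease": 400, "gene": 200, "phenotype": 150, "drug": 100}
    )
    duplication_weights: dict[int, float] = Field(
        default={1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        description="Distribution of records per concept over {1..4}.",
    )
    equivalence_predicate_weights: dict[str, float] = Field(
        default={
            "N_Name": 0.35,
            "I_CODE": 0.35,
            "R_equivalentClass": 0.15,
            "R_exactMatch": 0.15,
        }
    )
    n_blocks: int = 4
    p_intra: float = 0.08
    p_inter: float = 0.005
    seed_cluster_size: int = 92
    synonym_rate: float = 0.5
    extra_equivalence_rate: float = 0.25
    rng_seed: int = 0

    @field_validator("n_concepts_per_type")
    @classmethod
    def _positive_counts(cls, v: dict[str, int]) -> dict[str, int]:
        if not v or any(c < 0 for c in v.values()):
            raise ValueError("concept counts must be non-negative and non-empty")
        return v

    @field_validator("duplication_weights")
    @classmethod
    def _duplication_domain(cls, v: dict[int, float]) -> dict[int, float]:
        if not set(v) <= {1, 2, 3, 4}:
            raise ValueError("duplication counts must lie in {1..4}")
        if sum(v.values()) <= 0 or any(w < 0 for w in v.values()):
            raise ValueError("duplication weights must be non-negative, sum > 0")
        return v

    @model_validator(mode="after")
    def _check_probabilities(self) -> "SynthParams":
        if not (0 <= self.p_inter < self.p_intra <= 1):
            raise ValueError("require 0 <= p_inter < p_intra <= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0 <= self.synonym_rate <= 1:
            raise ValueError("synonym_rate must be a probability")
        if self.seed_cluster_size < 1:
            raise ValueError("seed_cluster_size must be >= 1")
        if not set(self.equivalence_predicate_weights) <= DEFAULT_EQUIVALENCE_PREDICATES:
            raise ValueError(
                "equivalence predicates must come from "
                f"{sorted(DEFAULT_EQUIVALENCE_PREDICATES)}"
            )
        return self


@dataclass
class GroundTruth:
    """Planted structure of a generated graph."""

    concept_of: dict[str, str]  # node_id -> concept_id
    block_of: dict[str, int]  # concept_id -> block index
    seed_diseases: list[str] = field(default_factory=list)
    canonical_record: dict[str, str] = field(default_factory=dict)  # concept -> node_id

    def concept_type(self, concept_id: str) -> str:
        return concept_id.split(":", 1)[0]


def _concept_ids(params: SynthParams) -> list[str]:
    out = []
    for node_type in sorted(params.n_concepts_per_type):
        for i in range(params.n_concepts_per_type[node_type]):
            out.append(f"{node_type}:{i:04d}")
    return out


def generate_kg(params: SynthParams) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a synthetic knowledge graph and its planted ground truth.

    Every concept's records form a connected equivalence component (a random
    spanning tree plus occasional extra links — connectivity without forcing
    a clique); no equivalence edge ever crosses concepts.  Duplicate records
    carry a synonym label with probability ``synonym_rate``, and the
    canonical record registers those labels in its ``synonyms`` field.
    """
    rng = np.random.default_rng(params.rng_seed)
    graph = KnowledgeGraph(directed=True)
    concepts = _concept_ids(params)

    # block assignment: round-robin within each type, so every block holds
    # a near-equal share of each node type
    block_of: dict[str, int] = {}
    for node_type in sorted(params.n_concepts_per_type):
        for i in range(params.n_concepts_per_type[node_type]):
            block_of[f"{node_type}:{i:04d}"] = i % params.n_blocks

    concept_of: dict[str, str] = {}
    canonical_record: dict[str, str] = {}
    records_of: dict[str, list[str]] = {}

    dup_values = sorted(params.duplication_weights)
    dup_weights = np.array([params.duplication_weights[v] for v in dup_values], float)
    dup_weights /= dup_weights.sum()
    pred_values = sorted(params.equivalence_predicate_weights)
    pred_weights = np.array(
        [params.equivalence_predicate_weights[p] for p in pred_values], float
    )
    pred_weights /= pred_weights.sum()

    for concept_id in concepts:
        node_type = concept_id.split(":", 1)[0]
        canonical_name = f"{node_type.capitalize()} {concept_id.split(':', 1)[1]}"
        n_records = int(rng.choice(dup_values, p=dup_weights))
        record_ids = [f"{concept_id}.r{j}" for j in range(n_records)]
        records_of[concept_id] = record_ids
        canonical_record[concept_id] = record_ids[0]
        shared_ref = f"XREF:{concept_id}"

        synonym_labels: list[str] = []
        nodes: list[KGNode] = []
        for j, record_id in enumerate(record_ids):
            concept_of[record_id] = concept_id
            if j > 0 and rng.random() < params.synonym_rate:
                label = f"{canonical_name} (syn {j})"
                synonym_labels.append(label)
            else:
                label = canonical_name
            nodes.append(
                KGNode(
                    node_id=record_id,
                    node_type=node_type,
                    names=[label],
                    source_refs={shared_ref, f"SRC{j}:{concept_id}"},
                    attributes={"source": f"SRC{j}"},
                )
            )
        nodes[0].synonyms.update(synonym_labels)
        for node in nodes:
            graph.add_node(node)

        # equivalence spanning tree (random recursive tree) + optional extras
        for j in range(1, n_records):
            parent = int(rng.integers(0, j))
            predicate = str(rng.choice(pred_values, p=pred_weights))
            graph.add_edge(record_ids[j], record_ids[parent], predicate)
        if n_records >= 3 and rng.random() < params.extra_equivalence_rate:
            a, b = rng.choice(n_records, size=2, replace=False)
            predicate = str(rng.choice(pred_values, p=pred_weights))
            graph.add_edge(record_ids[int(a)], record_ids[int(b)], predicate)

    # semantic edges: stochastic block model over concepts
    n = len(concepts)
    blocks = np.array([block_of[c] for c in concepts])
    same_block = blocks[:, None] == blocks[None, :]
    prob = np.where(same_block, params.p_intra, params.p_inter)
    draw = rng.random((n, n)) < prob
    ii, jj = np.where(np.triu(draw, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ca, cb = concepts[i], concepts[j]
        ta, tb = ca.split(":", 1)[0], cb.split(":", 1)[0]
        if (ta, tb) in SEMANTIC_PREDICATES:
            predicate = SEMANTIC_PREDICATES[(ta, tb)]
        elif (tb, ta) in SEMANTIC_PREDICATES:
            ca, cb = cb, ca
            predicate = SEMANTIC_PREDICATES[(tb, ta)]
        else:
            predicate = "related_to"
        rec_a = records_of[ca][int(rng.integers(0, len(records_of[ca])))]
        rec_b = records_of[cb][int(rng.integers(0, len(records_of[cb])))]
        graph.add_edge(rec_a, rec_b, predicate)

    truth = GroundTruth(
        concept_of=concept_of,
        block_of=block_of,
        canonical_record=canonical_record,
    )
    truth.seed_diseases = select_seed_cluster(truth, params)
    return graph, truth


def select_seed_cluster(truth: GroundTruth, params: SynthParams) -> list[str]:
    """Pick ``seed_cluster_size`` canonical disease records from one block.

    The block holding the most disease concepts is used (smallest index on
    ties); the draw within it is deterministic under ``rng_seed``.
    """
    per_block: dict[int, list[str]] = {}
    for concept_id, block in sorted(truth.block_of.items()):
        if truth.concept_type(concept_id) == "disease":
            per_block.setdefault(block, []).append(concept_id)
    if not per_block:
        raise ValueError("no disease concepts in the generated graph")
    block = max(per_block, key=lambda b: (len(per_block[b]), -b))
    pool = per_block[block]
    if len(pool) < params.seed_cluster_size:
        raise ValueError(
            f"block {block} holds {len(pool)} disease concepts, "
            f"fewer than seed_cluster_size={params.seed_cluster_size}"
        )
    rng = np.random.default_rng(params.rng_seed)
    chosen = rng.choice(len(pool), size=params.seed_cluster_size, replace=False)
    return [truth.canonical_record[pool[int(i)]] for i in sorted(chosen)]
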