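"""End-to-end orchestration: generate/load -> extract -> condense -> detect
-> rank, with a reproducible run manifest.

A run is configured by a single validated document (YAML or JSON).  Exactly
one input source is given: a stored knowledge graph plus a seed list, or
synthetic-generator parameters (in which case the planted seed cluster is
used).  All outputs land in the configured directory together with a
manifest recording the configuration, the seed nodes and a SHA-256 digest
of every output file; re-running an identical configuration reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .communities import Community, CommunityParams, detect_communities, rank_communities
from .condense import condense
from .io import join_list, read_graph, split_list, write_graph
from .model import DEFAULT_EQUIVALENCE_PREDICATES, KnowledgeGraph
from .profile import extract_profile
from .rank import CentralityParams, RankRecord, select_candidates
from .summary import network_summary
from .synth import SynthParams, generate_kg

logger = logging.getLogger("kgrx")

RANKING_COLUMNS = [
    "community_index",
    "node_id",
    "names",
    "degree",
    "closeness",
    "betweenness",
    "eigenvector",
    "pagerank",
    "norm_degree",
    "norm_closeness",
    "norm_betweenness",
    "norm_eigenvector",
    "norm_pagerank",
    "tncs",
    "is_candidate",
]


class PipelineConfig(BaseModel):
    input_graph: str | None = None
    input_format: str = Field(default="graphml", pattern="^(graphml|tsv_pair)$")
    seeds_file: str | None = None
    synth: SynthParams | None = None
    radius: int = Field(default=3, ge=0)
    equivalence_predicates: list[str] = Field(
        default_factory=lambda: sorted(DEFAULT_EQUIVALENCE_PREDICATES)
    )
    community: CommunityParams = Field(default_factory=CommunityParams)
    centrality: CentralityParams = Field(default_factory=CentralityParams)
    top_n_communities: int = Field(default=10, ge=1)
    k: int = Field(default=5, ge=1)
    output_dir: str = "kgrx_out"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        has_graph = self.input_graph is not None
        has_synth = self.synth is not None
        if has_graph == has_synth:
            raise ValueError(
                "provide exactly one input source: input_graph (+ seeds_file) "
                "or synth parameters"
            )
        if has_graph and self.seeds_file is None:
            raise ValueError("input_graph requires seeds_file")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def communities_to_frame(communities: list[Community]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "community_index": [c.index for c in communities],
            "n_nodes": [c.size for c in communities],
            "L_c": [c.L_c for c in communities],
            "k_c": [c.k_c for c in communities],
            "score": [c.score for c in communities],
            "members": [join_list(sorted(c.members)) for c in communities],
        }
    )


def communities_from_frame(frame: pd.DataFrame) -> list[Community]:
    return [
        Community(
            index=int(row.community_index),
            members=set(split_list(row.members)),
            L_c=int(row.L_c),
            k_c=int(row.k_c),
            score=float(row.score),
        )
        for row in frame.itertuples()
    ]


def rankings_to_frame(records: list[RankRecord], graph: KnowledgeGraph) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "community_index": r.community_index,
            "node_id": r.node_id,
            "names": join_list(graph.node(r.node_id).names) if graph.has_node(r.node_id) else "",
        }
        row.update({m: r.raw[m] for m in r.raw})
        row.update({f"norm_{m}": r.normalized[m] for m in r.normalized})
        row["tncs"] = r.tncs
        row["is_candidate"] = r.is_candidate
        rows.append(row)
    return pd.DataFrame(rows, columns=RANKING_COLUMNS)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk).

    Any stage failure aborts the run with the stage name and removes the
    partial outputs written so far.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    stages: dict[str, dict] = {}

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        stage = "input"
        if config.synth is not None:
            source, truth = generate_kg(config.synth)
            seeds = list(truth.seed_diseases)
            emit("source_kg.graphml", lambda p: write_graph(source, p, "graphml"))
            emit(
                "ground_truth.json",
                lambda p: p.write_text(
                    json.dumps(
                        {
                            "concept_of": truth.concept_of,
                            "block_of": truth.block_of,
                            "seed_diseases": truth.seed_diseases,
                        },
                        indent=1,
                        sort_keys=True,
                    ),
                    encoding="utf-8",
                ),
            )
        else:
            source = read_graph(
                config.input_graph, config.input_format, config.equivalence_predicates
            )
            seeds = [
                s.strip()
                for s in Path(config.seeds_file).read_text(encoding="utf-8").splitlines()
                if s.strip()
            ]
        stages["input"] = {"n_nodes": source.n_nodes, "n_edges": source.n_edges}
        logger.info("input graph: %d nodes, %d edges, %d seeds",
                    source.n_nodes, source.n_edges, len(seeds))

        stage = "profile_extraction"
        profile = extract_profile(source, seeds, config.radius)
        stages[stage] = {
            "n_nodes": profile.graph.n_nodes,
            "n_edges": profile.graph.n_edges,
        }
        logger.info("profile network (radius %d): %d nodes, %d edges",
                    config.radius, profile.graph.n_nodes, profile.graph.n_edges)

        stage = "condense"
        condensed, plan = condense(profile.graph, config.equivalence_predicates)
        stages[stage] = {
            "n_nodes": condensed.n_nodes,
            "n_edges": condensed.n_edges,
            "n_merged_nodes": plan.n_merged_groups(),
        }
        logger.info("condensed profile: %d nodes (%d merged), %d edges",
                    condensed.n_nodes, plan.n_merged_groups(), condensed.n_edges)
        emit("gbpn.graphml", lambda p: write_graph(condensed, p, "graphml"))
        audit = pd.DataFrame(
            {
                "new_id": list(plan.groups),
                "member_ids": [join_list(m) for m in plan.groups.values()],
                "n_members": [len(m) for m in plan.groups.values()],
            }
        ).sort_values("new_id")
        emit("merge_audit.tsv", lambda p: audit.to_csv(p, sep="\t", index=False))

        stage = "summary"
        summary = network_summary(condensed)
        emit(
            "summary.json",
            lambda p: p.write_text(
                json.dumps(summary.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
            ),
        )

        stage = "community_detection"
        partition = detect_communities(condensed, config.community)
        ranked = rank_communities(partition, config.community.min_size)
        stages[stage] = {
            "n_communities": len(partition.communities),
            "n_ranked": len(ranked),
        }
        logger.info("%d communities (%d ranked with >= %d nodes)",
                    len(partition.communities), len(ranked), config.community.min_size)
        emit(
            "communities.tsv",
            lambda p: communities_to_frame(partition.communities).to_csv(
                p, sep="\t", index=False
            ),
        )

        stage = "influence_ranking"
        records = select_candidates(
            ranked,
            condensed,
            config.centrality,
            config.top_n_communities,
            config.k,
        )
        rankings = rankings_to_frame(records, condensed)
        emit("rankings.tsv", lambda p: rankings.to_csv(p, sep="\t", index=False))
        candidates = rankings[rankings.is_candidate]
        emit("candidates.tsv", lambda p: candidates.to_csv(p, sep="\t", index=False))
        stages[stage] = {"n_records": len(rankings), "n_candidates": len(candidates)}
        logger.info("ranked %d nodes, %d candidates", len(rankings), len(candidates))

        stage = "manifest"
        manifest = {
            "config": json.loads(config.model_dump_json()),
            "seeds": seeds,
            "stages": stages,
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
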