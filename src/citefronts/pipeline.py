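"""End-to-end orchestration: filter → graph → LCC → cluster → sub-cluster →
keywords → report, with one top-level seed and deterministic artifacts.

All randomness flows from the single configured seed through stage-name-keyed
child seeds (SHA-256 of ``"<seed>:<stage>"``, truncated below 2^31), so one
integer reproduces the whole run.  Large clusters — those holding at least
``subcluster_min_frac`` of the LCC — are decomposed a second time by Louvain
on their induced subgraphs; their children are profiled among themselves
(the ICF denominator for child keywords is the number of children of that
parent), mirroring how sub-clusters are reported alongside their parents.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from . import clustering, corpus, graph, keywords, reporting

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "child_seed", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def child_seed(seed: int, stage: str) -> int:
    """Stage-keyed seed derivation, stable across platforms, < 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    input_path: str = ""
    input_format: str = "jsonl"
    query: str | None = None
    seed: int = 0
    resolution: float = 1.0
    max_passes: int = 50
    token: keywords.TokenConfig = field(default_factory=keywords.TokenConfig)
    top_k_keywords: int = 20
    top_k_clusters: int = 20
    subcluster_min_frac: float = 0.10
    out_dir: str = "citefronts_out"
    log_level: str = "INFO"

    def content_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        log level excluded, so reruns into different directories compare)."""
        payload = {
            "input_format": self.input_format,
            "query": self.query,
            "seed": self.seed,
            "resolution": self.resolution,
            "max_passes": self.max_passes,
            "ngram_max": self.token.ngram_max,
            "min_token_len": self.token.min_token_len,
            "keep_hyphenated": self.token.keep_hyphenated,
            "stopwords": sorted(self.token.stopwords),
            "top_k_keywords": self.top_k_keywords,
            "top_k_clusters": self.top_k_clusters,
            "subcluster_min_frac": self.subcluster_min_frac,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig,
    records: list[corpus.PublicationRecord] | None = None,
) -> dict:
    """Run the full analysis and write artifacts; returns the run manifest.

    *records* may be passed directly (already-validated corpus) to skip the
    read stage; otherwise ``config.input_path`` is read.
    """
    os.makedirs(config.out_dir, exist_ok=True)

    if records is None:
        records = _stage("read_corpus")(corpus.read_corpus)(
            config.input_path, config.input_format
        )
    n_input = len(records)
    if config.query:
        records = _stage("filter_corpus")(corpus.filter_corpus)(records, config.query)
    n_filtered = len(records)

    g = _stage("build_citation_graph")(graph.build_citation_graph)(records)
    lcc = _stage("largest_connected_component")(graph.largest_connected_component)(g)
    frac = graph.lcc_fraction(n_filtered, lcc.number_of_nodes())

    louvain_cfg = clustering.LouvainConfig(
        seed=child_seed(config.seed, "louvain"),
        resolution=config.resolution,
        max_passes=config.max_passes,
    )
    partition = _stage("louvain")(clustering.louvain)(lcc, louvain_cfg)
    ranked = clustering.rank_clusters(partition)

    # sub-cluster every cluster holding >= subcluster_min_frac of the LCC
    threshold = config.subcluster_min_frac * lcc.number_of_nodes()
    subpartitions: dict[str, clustering.Partition] = {}
    refined = partition
    for label, size in ranked:
        if size < threshold or size < 2:
            continue
        sub = lcc.subgraph(partition.members(label))
        if sub.number_of_edges() == 0:
            logger.warning("cluster %s has an edgeless induced subgraph; not sub-clustered", label)
            continue
        sub_cfg = clustering.LouvainConfig(
            seed=child_seed(config.seed, f"subcluster:{label}"),
            resolution=config.resolution,
            max_passes=config.max_passes,
        )
        refined = _stage("subcluster")(clustering.subcluster)(
            lcc, refined, label, sub_cfg
        )
        groups: dict[str, set] = {}
        for node in partition.members(label):
            groups.setdefault(refined.assignment[node], set()).add(node)
        subpartitions[label] = clustering.Partition.from_communities(
            groups.values(), prefix=label
        )

    lcc_records = [r for r in records if r.id in partition.assignment]
    stats = _stage("term_cluster_counts")(keywords.term_cluster_counts)(
        lcc_records, partition, config.token
    )
    scores = _stage("tficf_scores")(keywords.tficf_scores)(stats)
    profiles = _stage("cluster_profiles")(reporting.cluster_profiles)(
        lcc_records, partition, scores, top_k=config.top_k_keywords
    )

    # child profiles: scored among the children of their own parent
    child_profiles: dict[str, list[reporting.ClusterProfile]] = {}
    for label, subpart in subpartitions.items():
        sub_records = [r for r in lcc_records if r.id in subpart.assignment]
        sub_stats = keywords.term_cluster_counts(sub_records, subpart, config.token)
        sub_scores = keywords.tficf_scores(sub_stats)
        child_profiles[label] = reporting.cluster_profiles(
            sub_records, subpart, sub_scores, top_k=config.top_k_keywords
        )

    report_rows: list[reporting.ClusterProfile] = []
    for prof in profiles:
        report_rows.append(prof)
        report_rows.extend(child_profiles.get(prof.label, []))

    top_k = min(config.top_k_clusters, len(partition.labels))
    cov = _stage("coverage")(reporting.coverage)(partition, top_k)

    paths = {
        "partition": os.path.join(config.out_dir, "partition.tsv"),
        "keywords": os.path.join(config.out_dir, "keywords.tsv"),
        "report_tsv": os.path.join(config.out_dir, "report.tsv"),
        "report_md": os.path.join(config.out_dir, "report.md"),
        "profiles_json": os.path.join(config.out_dir, "profiles.json"),
        "manifest": os.path.join(config.out_dir, "manifest.json"),
    }
    clustering.write_partition_tsv(refined, paths["partition"])
    with open(paths["keywords"], "w", encoding="utf-8") as fh:
        fh.write("cluster\trank\tterm\ttficf\n")
        for prof in report_rows:
            for i, (term, score) in enumerate(prof.keywords, 1):
                fh.write(f"{prof.label}\t{i}\t{term}\t{score:.6f}\n")
    with open(paths["report_tsv"], "w", encoding="utf-8") as fh:
        fh.write(reporting.render_report(report_rows, "tsv"))
    with open(paths["report_md"], "w", encoding="utf-8") as fh:
        fh.write(reporting.render_report(report_rows, "markdown"))
    with open(paths["profiles_json"], "w", encoding="utf-8") as fh:
        fh.write(reporting.profiles_json(report_rows))

    manifest = {
        "corpus_size": n_input,
        "filtered_size": n_filtered,
        "lcc_size": lcc.number_of_nodes(),
        "lcc_edges": lcc.number_of_edges(),
        "lcc_fraction": frac,
        "n_clusters": len(partition.labels),
        "cluster_sizes": [size for _, size in ranked],
        "subclustered": sorted(subpartitions),
        "coverage_top_k": top_k,
        "coverage": cov,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "artifacts": paths,
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "pipeline done: %d records, LCC %d (%.1f%%), %d clusters, coverage %.1f%%",
        n_filtered, lcc.number_of_nodes(), frac, len(partition.labels), cov,
    )
    return manifest
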