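"""Cluster profiles and report rendering.

A profile row mirrors the summary table of a horizon-scanning analysis:
rank, cluster label, paper count, average publication year, and the top-k
TF-ICF keywords.  Average year is the arithmetic mean over members with a
known year, rendered rounded half-up to an integer (the real value is kept
in machine output); records without a year are excluded from the mean and
logged.  The coverage statistic is the percentage of clustered papers held
by the top-k clusters, with the clustered (LCC) node count as denominator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .clustering import Partition, rank_clusters
from .corpus import PublicationRecord
from .keywords import KeywordScore, top_keywords

logger = logging.getLogger(__name__)

__all__ = ["ClusterProfile", "cluster_profiles", "coverage", "render_report", "profiles_json"]


@dataclass
class ClusterProfile:
    label: str
    rank: int
    size: int
    average_year: float | None  # full-precision mean; None if no member has a year
    average_year_int: int | None  # half-up integer rendering for reports
    keywords: list[tuple[str, float]]


def _mean_year(years: list[int]) -> tuple[float | None, int | None]:
    if not years:
        return None, None
    exact = Decimal(sum(years)) / Decimal(len(years))
    return float(exact), int(exact.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cluster_profiles(
    records: Iterable[PublicationRecord],
    partition: Partition,
    scores: Iterable[KeywordScore],
    top_k: int = 20,
) -> list[ClusterProfile]:
    """One profile per partition label in rank order."""
    scores = list(scores)
    scored_clusters = {s.cluster for s in scores}
    years_by_label: dict[str, list[int]] = {lab: [] for lab in partition.labels}
    n_missing_year = 0
    for rec in records:
        lab = partition.assignment.get(rec.id)
        if lab is None:
            continue
        if rec.year is None:
            n_missing_year += 1
        else:
            years_by_label[lab].append(rec.year)
    if n_missing_year:
        logger.info("%d record(s) without a year excluded from average-year", n_missing_year)
    sizes = partition.sizes()
    profiles = []
    for rank, (label, size) in enumerate(rank_clusters(partition), 1):
        mean, mean_int = _mean_year(years_by_label[label])
        kws = (
            top_keywords(scores, label, k=top_k) if label in scored_clusters else []
        )
        assert size == sizes[label]
        profiles.append(
            ClusterProfile(
                label=label,
                rank=rank,
                size=size,
                average_year=mean,
                average_year_int=mean_int,
                keywords=kws,
            )
        )
    return profiles


def coverage(partition: Partition, top_k: int) -> float:
    """Percentage of clustered papers in the top_k ranked clusters, rounded
    half-up to one decimal."""
    ranked = rank_clusters(partition)
    if not 1 <= top_k <= len(ranked):
        raise ValueError(f"top_k must lie in [1, {len(ranked)}], got {top_k}")
    total = len(partition.assignment)
    covered = sum(size for _, size in ranked[:top_k])
    pct = Decimal(100 * covered) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_report(profiles: list[ClusterProfile], format: str = "tsv") -> str:
    """Deterministic text table: rank, label, size, average year, keywords."""
    header = ("rank", "cluster", "papers", "average_year", "top_keywords")
    rows = []
    for p in profiles:
        year = "NA" if p.average_year_int is None else str(p.average_year_int)
        kws = ", ".join(term for term, _ in p.keywords)
        rows.append((str(p.rank), p.label, str(p.size), year, kws))
    if format == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if format == "markdown":
        lines = [
            "| " + " | ".join(header) + " |",
            "| " + " | ".join("---" for _ in header) + " |",
        ]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}; expected 'tsv' or 'markdown'")


def profiles_json(profiles: list[ClusterProfile]) -> str:
    """Machine-readable profiles with full numeric precision."""
    payload = [
        {
            "label": p.label,
            "rank": p.rank,
            "size": p.size,
            "average_year": p.average_year,
            "average_year_int": p.average_year_int,
            "keywords": [{"term": t, "tficf": s} for t, s in p.keywords],
        }
        for p in profiles
    ]
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
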