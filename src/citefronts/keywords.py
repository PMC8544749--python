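"""Cluster-characteristic keyword scoring by TF-ICF.

The score of term i in cluster j is

    TFICF(i, j) = tf_ij * log(N / cf_i)

where tf_ij is the raw occurrence count of the term in the concatenated
titles+abstracts of cluster j, cf_i the number of clusters containing the
term at least once, and N the number of clusters (natural log; rankings are
base-invariant).  Terms present in every cluster score exactly 0 — the
inverse-cluster-frequency factor strips vocabulary that is generic across
the whole corpus, leaving what is characteristic of one research front.

tf is deliberately unnormalized (the score as defined carries no length
correction), which biases absolute scores toward large clusters; rankings
*within* a cluster are unaffected.

Tokenization: lowercase, NFKC-normalized words (internal hyphens kept by
default, so "pd-1" survives), stopword and minimum-length filtering, then
contiguous 1..ngram_max-grams within sentence boundaries — multi-word
keywords such as "immune checkpoint inhibitor" emerge as 3-grams.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from .corpus import split_words

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import Partition
    from .corpus import PublicationRecord

__all__ = [
    "TokenConfig",
    "TermStats",
    "KeywordScore",
    "DEFAULT_STOPWORDS",
    "tokenize",
    "term_cluster_counts",
    "tficf_scores",
    "top_keywords",
]

DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been being but by can could did do does for from
    had has have he her his however if in into is it its may might more most
    no nor not of on or other our shall she should such than that the their
    them then there these they this those through to upon was we were what
    when which while will with would""".split()
)

_SENTENCE_SPLIT = re.compile(r"[.!?;\n]+")


@dataclass
class TokenConfig:
    """Tokenizer knobs: n-gram ceiling, stopword set, minimum token length,
    and whether internal hyphens are preserved."""

    ngram_max: int = 3
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    min_token_len: int = 2
    keep_hyphenated: bool = True

    def __post_init__(self) -> None:
        if self.ngram_max < 1:
            raise ValueError("ngram_max must be >= 1")
        if self.min_token_len < 1:
            raise ValueError("min_token_len must be >= 1")


def tokenize(text: str, config: TokenConfig | None = None) -> Counter:
    """Multiset of 1..ngram_max-gram terms over the filtered word stream,
    formed within sentence boundaries."""
    if config is None:
        config = TokenConfig()
    terms: Counter = Counter()
    for sentence in _SENTENCE_SPLIT.split(text):
        words = [
            w
            for w in split_words(sentence, keep_hyphenated=config.keep_hyphenated)
            if len(w) >= config.min_token_len and w not in config.stopwords
        ]
        for n in range(1, config.ngram_max + 1):
            for i in range(len(words) - n + 1):
                terms[" ".join(words[i : i + n])] += 1
    return terms


@dataclass
class TermStats:
    """Per-(term, cluster) frequencies plus per-term cluster frequencies.

    cf(term) is derived: the number of clusters with tf(term, c) > 0.
    n_sentences supports the alternative ICF denominator (see tficf_scores).
    """

    tf: dict[tuple[str, str], int]
    cf: dict[str, int]
    clusters: list[str]
    n_sentences: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def term_cluster_counts(
    records: Iterable["PublicationRecord"],
    partition: "Partition",
    config: TokenConfig | None = None,
) -> TermStats:
    """Accumulate term counts over each cluster's titles+abstracts.

    Every record id must be assigned in *partition*; a missing assignment is
    an error (the partition is meant to cover the scored corpus exactly).
    """
    if config is None:
        config = TokenConfig()
    tf: dict[tuple[str, str], int] = {}
    n_sentences = 0
    for rec in records:
        try:
            cluster = partition.assignment[rec.id]
        except KeyError:
            raise KeyError(f"record {rec.id!r} is not assigned in the partition")
        text = rec.title + ". " + rec.abstract
        n_sentences += sum(1 for s in _SENTENCE_SPLIT.split(text) if s.strip())
        for term, count in tokenize(text, config).items():
            key = (term, cluster)
            tf[key] = tf.get(key, 0) + count
    cf: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for (term, cluster), count in tf.items():
        if count > 0 and (term, cluster) not in seen:
            seen.add((term, cluster))
            cf[term] = cf.get(term, 0) + 1
    return TermStats(tf=tf, cf=cf, clusters=list(partition.labels), n_sentences=n_sentences)


@dataclass(frozen=True)
class KeywordScore:
    term: str
    cluster: str
    tficf: float


def tficf_scores(stats: TermStats, icf_n_mode: str = "clusters") -> list[KeywordScore]:
    """Score every (term, cluster) with tf > 0 as tf * ln(N / cf).

    icf_n_mode selects the N in the ICF factor: "clusters" (default, the
    internally consistent reading of inverse *cluster* frequency) or
    "sentences" (total sentence count, for fidelity experiments).
    """
    if icf_n_mode == "clusters":
        n = stats.n_clusters
    elif icf_n_mode == "sentences":
        n = stats.n_sentences
    else:
        raise ValueError("icf_n_mode must be 'clusters' or 'sentences'")
    if n < 1:
        raise ValueError("need at least one cluster (or sentence) to score")
    scores = []
    for (term, cluster), count in stats.tf.items():
        if count == 0:
            continue
        cf = stats.cf.get(term, 0)
        if cf == 0:
            raise ValueError(f"inconsistent stats: tf > 0 but cf = 0 for {term!r}")
        scores.append(KeywordScore(term=term, cluster=cluster, tficf=count * math.log(n / cf)))
    return scores


def top_keywords(
    scores: Iterable[KeywordScore],
    cluster: str,
    k: int = 20,
    vocabulary_filter: set[str] | None = None,
) -> list[tuple[str, float]]:
    """The k highest-scoring terms of one cluster, descending score, ties
    broken alphabetically; optionally restricted to a vocabulary first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = list(scores)
    if cluster not in {s.cluster for s in scores}:
        raise KeyError(f"unknown cluster {cluster!r}")
    pool = [s for s in scores if s.cluster == cluster]
    if vocabulary_filter is not None:
        pool = [s for s in pool if s.term in vocabulary_filter]
    pool.sort(key=lambda s: (-s.tficf, s.term))
    return [(s.term, s.tficf) for s in pool[:k]]
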