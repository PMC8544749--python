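"""Citation-network construction and largest-connected-component extraction.

The citation graph is undirected, unweighted and simple: publications are
nodes and a link joins u and v when either cites the other (direction is
discarded; reciprocal citations collapse to one edge).  Only within-corpus
citations create edges — a reference to an id outside the corpus contributes
nothing, so the node universe is exactly the retrieved set.  The analysis
universe downstream is the largest connected component (LCC).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .corpus import PublicationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "build_citation_graph",
    "connected_components",
    "largest_connected_component",
    "lcc_fraction",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "write_graphml",
]


def build_citation_graph(records: list[PublicationRecord]) -> nx.Graph:
    """Undirected simple graph over record ids; {u, v} is an edge iff either
    record's references contain the other and both are in the corpus."""
    g = nx.Graph()
    ids = {r.id for r in records}
    g.add_nodes_from(r.id for r in records)
    n_external = 0
    for rec in records:
        for ref in rec.references:
            if ref == rec.id:
                continue
            if ref in ids:
                g.add_edge(rec.id, ref)
            else:
                n_external += 1
    if n_external:
        logger.info("ignored %d reference(s) to ids outside the corpus", n_external)
    return g


def connected_components(graph: nx.Graph) -> list[set]:
    """Components sorted by decreasing size, ties by smallest contained id."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (ties by smallest id)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no largest connected component")
    comps = connected_components(graph)
    return graph.subgraph(comps[0]).copy()


def lcc_fraction(total_count: int, lcc_count: int) -> float:
    """Percentage of records landing in the citation network's LCC,
    rounded half-up to one decimal (e.g. 134361 records, 92731 in the
    LCC → 69.0)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= lcc_count <= total_count:
        raise ValueError("lcc_count must lie in [0, total_count]")
    pct = Decimal(100 * lcc_count) / Decimal(total_count)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_edgelist_tsv(graph: nx.Graph, path: str) -> None:
    """Two-column TSV, one edge per line, lexicographically smaller id first,
    lines sorted for byte determinism."""
    lines = sorted(tuple(sorted((str(u), str(v)))) for u, v in graph.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")


def read_edgelist_tsv(path: str) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"edge list line {lineno}: expected 2 columns")
            g.add_edge(parts[0], parts[1])
    return g


def write_graphml(graph: nx.Graph, path: str) -> None:
    nx.write_graphml(graph, path)
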