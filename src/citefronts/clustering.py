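"""Community detection by Louvain modularity maximization.

Modularity of a partition C of an undirected simple graph with m edges is

    Q = (1/2m) * sum_ij [ A_ij - gamma * k_i k_j / (2m) ] * delta(c_i, c_j)

over ordered node pairs, with gamma the resolution (1.0 by default).  The
Louvain heuristic alternates (1) local moving — each node greedily joins the
neighboring community with the largest modularity gain — and (2) aggregation
of communities into weighted super-nodes, until a pass makes no move.

Determinism contract: node visit order is a seeded uniform shuffle per
local-moving round; candidate communities tied in gain (within
``min_move_gain``) resolve to the current community if tied, else the
community with the smallest label, a community's label being the smallest
node id it contains.  Super-nodes created by aggregation are named after the
smallest original member id, so labels stay comparable across passes.  For a
fixed seed two runs produce identical assignments.

``exhaustive_best_partition`` enumerates every set partition (Bell-number
search) of a small graph and is the oracle against which the heuristic is
bounded in tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator

import networkx as nx

__all__ = [
    "Partition",
    "LouvainConfig",
    "EdgelessGraphError",
    "modularity",
    "louvain",
    "exhaustive_best_partition",
    "subcluster",
    "rank_clusters",
    "write_partition_tsv",
    "read_partition_tsv",
]


class EdgelessGraphError(ValueError):
    """Modularity is undefined on a graph with no edges (m = 0)."""


@dataclass
class LouvainConfig:
    """Free parameters of the Louvain heuristic.

    seed: shuffles the node visit order each round.
    resolution: gamma in the modularity quality function; >1 favors smaller
        communities, <1 larger ones.
    max_passes: cap on move/aggregate passes.
    min_move_gain: minimum modularity improvement for a move; absorbs
        floating-point noise and prevents oscillation.
    """

    seed: int = 0
    resolution: float = 1.0
    max_passes: int = 50
    min_move_gain: float = 1e-12

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.min_move_gain < 0:
            raise ValueError("min_move_gain must be >= 0")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


@dataclass
class Partition:
    """Total assignment of nodes to cluster labels.

    ``labels`` is the rank order: strictly non-increasing member count, ties
    by smallest member id.  Hierarchical labels ("1-3") mark sub-clusters.
    """

    assignment: dict[Hashable, str]
    labels: list[str]
    q_history: list[float] | None = field(default=None, compare=False)

    @classmethod
    def from_communities(
        cls,
        communities: Iterable[set],
        prefix: str = "",
        q_history: list[float] | None = None,
    ) -> "Partition":
        """Rank communities by (descending size, smallest member id) and label
        them "1".."k", or "<prefix>-1".."<prefix>-k" when *prefix* is given."""
        comms = [set(c) for c in communities if c]
        comms.sort(key=lambda c: (-len(c), min(c)))
        assignment: dict[Hashable, str] = {}
        labels = []
        for k, comm in enumerate(comms, 1):
            label = f"{prefix}-{k}" if prefix else str(k)
            labels.append(label)
            for node in comm:
                assignment[node] = label
        return cls(assignment=assignment, labels=labels, q_history=q_history)

    def members(self, label: str) -> set:
        return {n for n, lab in self.assignment.items() if lab == label}

    def communities(self) -> list[set]:
        by_label: dict[str, set] = {lab: set() for lab in self.labels}
        for n, lab in self.assignment.items():
            by_label[lab].add(n)
        return [by_label[lab] for lab in self.labels]

    def sizes(self) -> dict[str, int]:
        out = {lab: 0 for lab in self.labels}
        for lab in self.assignment.values():
            out[lab] += 1
        return out


def rank_clusters(partition: Partition) -> list[tuple[str, int]]:
    """(label, size) pairs in rank order: descending size, ties by smallest
    member id; ranks are the 1-based list positions."""
    by_label: dict[str, set] = {lab: set() for lab in partition.labels}
    for n, lab in partition.assignment.items():
        by_label[lab].add(n)
    ordered = sorted(by_label, key=lambda lab: (-len(by_label[lab]), min(by_label[lab])))
    return [(lab, len(by_label[lab])) for lab in ordered]


# --- modularity ---------------------------------------------------------------


def _check_cover(graph: nx.Graph, partition: Partition) -> None:
    if set(partition.assignment) != set(graph.nodes):
        raise ValueError("partition does not cover exactly the graph's nodes")


def modularity(graph: nx.Graph, partition: Partition, resolution: float = 1.0) -> float:
    """Newman modularity Q of *partition* at the given *resolution*."""
    _check_cover(graph, partition)
    m = graph.number_of_edges()
    if m == 0:
        raise EdgelessGraphError("modularity undefined: graph has no edges")
    label_of = partition.assignment
    internal: dict[str, int] = {}
    degsum: dict[str, int] = {}
    for u, v in graph.edges():
        if label_of[u] == label_of[v]:
            internal[label_of[u]] = internal.get(label_of[u], 0) + 1
    for n, d in graph.degree():
        lab = label_of[n]
        degsum[lab] = degsum.get(lab, 0) + d
    q = 0.0
    two_m = 2.0 * m
    for lab in partition.labels:
        lc = internal.get(lab, 0)
        dc = degsum.get(lab, 0)
        q += lc / m - resolution * (dc / two_m) ** 2
    return q


def _mod_from_labels(
    edges: list[tuple], degrees: dict, m: int, label_of: dict, resolution: float
) -> float:
    # fast path used by the exhaustive search; no validation
    internal: dict = {}
    degsum: dict = {}
    for u, v in edges:
        if label_of[u] == label_of[v]:
            internal[label_of[u]] = internal.get(label_of[u], 0) + 1
    for n, d in degrees.items():
        degsum[label_of[n]] = degsum.get(label_of[n], 0) + d
    two_m = 2.0 * m
    return sum(
        internal.get(lab, 0) / m - resolution * (degsum[lab] / two_m) ** 2
        for lab in degsum
    )


# --- Louvain ------------------------------------------------------------------


def _local_move(
    nodes: list,
    adj: dict,
    k: dict,
    m: float,
    comm: dict,
    members: dict,
    tot: dict,
    rng: random.Random,
    gamma: float,
    tol: float,
) -> bool:
    """One local-moving phase on the (possibly aggregated) weighted graph;
    mutates comm/members/tot in place.  Returns True iff any node moved."""
    improved = False
    moved_in_round = True
    while moved_in_round:
        moved_in_round = False
        order = list(nodes)
        rng.shuffle(order)
        for i in order:
            ki = k[i]
            if ki == 0:
                continue  # isolated super-node: stays its own community
            cur = comm[i]
            # detach i
            members[cur].discard(i)
            tot[cur] -= ki
            nbr_w: dict = {cur: 0.0}
            for j, w in adj[i].items():
                if j == i:
                    continue
                cj = comm[j]
                nbr_w[cj] = nbr_w.get(cj, 0.0) + w
            gains = {
                c: w / m - gamma * ki * tot[c] / (2.0 * m * m)
                for c, w in nbr_w.items()
            }
            best = max(gains.values())
            eligible = [c for c, g in gains.items() if g >= best - tol]
            if cur in eligible:
                target = cur
            else:
                # smallest community label = smallest member id it contains
                target = min(eligible, key=lambda c: min(members[c]))
            members[target].add(i)
            tot[target] += ki
            comm[i] = target
            if target != cur:
                improved = True
                moved_in_round = True
                if not members[cur]:
                    del members[cur], tot[cur]
    return improved


def louvain(graph: nx.Graph, config: LouvainConfig | None = None) -> Partition:
    """Louvain community detection; returns the ranked :class:`Partition`
    with the per-pass modularity trace in ``q_history``."""
    if config is None:
        config = LouvainConfig()
    m = graph.number_of_edges()
    if m == 0:
        raise EdgelessGraphError("Louvain undefined: graph has no edges")
    rng = random.Random(config.seed)
    gamma = config.resolution
    tol = config.min_move_gain

    # aggregated state: super-node -> weighted neighbors / self-loop weight,
    # and the original members it represents
    nodes = sorted(graph.nodes)
    adj: dict = {u: {} for u in nodes}
    for u, v in graph.edges():
        adj[u][v] = adj[u].get(v, 0.0) + 1.0
        adj[v][u] = adj[v].get(u, 0.0) + 1.0
    loop: dict = {u: 0.0 for u in nodes}
    members_orig: dict = {u: frozenset([u]) for u in nodes}

    q_history: list[float] = []
    final_comms: list[set] = [set(s) for s in members_orig.values()]

    for _ in range(config.max_passes):
        k = {u: sum(adj[u].values()) + 2.0 * loop[u] for u in nodes}
        comm = {u: u for u in nodes}
        members = {u: {u} for u in nodes}
        tot = {u: k[u] for u in nodes}
        improved = _local_move(
            nodes, adj, k, float(m), comm, members, tot, rng, gamma, tol
        )
        final_comms = [
            set().union(*(members_orig[u] for u in mem)) for mem in members.values()
        ]
        part = Partition.from_communities(final_comms)
        q_history.append(modularity(graph, part, resolution=gamma))
        if not improved:
            break
        # aggregation: each community becomes a super-node named after its
        # smallest member id (itself a smallest original id)
        name_of = {c: min(mem) for c, mem in members.items()}
        new_nodes = sorted(name_of.values())
        new_adj: dict = {s: {} for s in new_nodes}
        new_loop: dict = {s: 0.0 for s in new_nodes}
        new_members: dict = {s: set() for s in new_nodes}
        for c, mem in members.items():
            s = name_of[c]
            for u in mem:
                new_members[s] |= members_orig[u]
                new_loop[s] += loop[u]
        seen = set()
        for u in nodes:
            su = name_of[comm[u]]
            for v, w in adj[u].items():
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                sv = name_of[comm[v]]
                if su == sv:
                    new_loop[su] += w
                else:
                    new_adj[su][sv] = new_adj[su].get(sv, 0.0) + w
                    new_adj[sv][su] = new_adj[sv].get(su, 0.0) + w
        nodes = new_nodes
        adj, loop = new_adj, new_loop
        members_orig = {s: frozenset(mem) for s, mem in new_members.items()}

    return Partition.from_communities(final_comms, q_history=q_history)


# --- exhaustive oracle --------------------------------------------------------


def _set_partitions(items: list) -> Iterator[list[set]]:
    """All set partitions, in a deterministic recursive order."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield [{first}] + part


def exhaustive_best_partition(
    graph: nx.Graph, max_nodes: int = 12, resolution: float = 1.0
) -> tuple[Partition, float]:
    """Globally optimal partition by brute force over all set partitions of
    the nodes; feasible only for tiny graphs (Bell(12) ≈ 4.2e6)."""
    n = graph.number_of_nodes()
    if n > max_nodes:
        raise ValueError(f"graph has {n} nodes; exhaustive search capped at {max_nodes}")
    if graph.number_of_edges() == 0:
        raise EdgelessGraphError("modularity undefined: graph has no edges")
    nodes = sorted(graph.nodes)
    edges = list(graph.edges())
    degrees = dict(graph.degree())
    m = graph.number_of_edges()
    best_q = float("-inf")
    best: list[set] | None = None
    for part in _set_partitions(nodes):
        label_of = {}
        for idx, comm in enumerate(part):
            for node in comm:
                label_of[node] = idx
        q = _mod_from_labels(edges, degrees, m, label_of, resolution)
        if q > best_q:
            best_q = q
            best = part
    assert best is not None
    return Partition.from_communities(best), best_q


# --- sub-clustering -----------------------------------------------------------


def subcluster(
    graph: nx.Graph,
    partition: Partition,
    parent_label: str,
    config: LouvainConfig | None = None,
) -> Partition:
    """Re-run Louvain on the induced subgraph of one parent cluster.

    Returns the refined partition: the parent's members carry child labels
    "<parent>-<k>" (k = 1-based rank by descending child size), all other
    nodes keep their labels.
    """
    if parent_label not in partition.labels:
        raise KeyError(f"unknown parent label {parent_label!r}")
    members = partition.members(parent_label)
    if len(members) < 2:
        raise ValueError(f"cluster {parent_label!r} has fewer than 2 members")
    sub = graph.subgraph(members)
    if sub.number_of_edges() == 0:
        raise EdgelessGraphError(
            f"induced subgraph of cluster {parent_label!r} has no edges"
        )
    child = louvain(sub, config)
    child_ranked = Partition.from_communities(child.communities(), prefix=parent_label)
    assignment = dict(partition.assignment)
    assignment.update(child_ranked.assignment)
    by_label: dict[str, set] = {}
    for node, lab in assignment.items():
        by_label.setdefault(lab, set()).add(node)
    ordered = sorted(by_label, key=lambda lab: (-len(by_label[lab]), min(by_label[lab])))
    return Partition(assignment=assignment, labels=ordered)


# --- partition I/O ------------------------------------------------------------


def write_partition_tsv(partition: Partition, path: str) -> None:
    """Two columns: node id, hierarchical cluster label; rows sorted by id."""
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(partition.assignment, key=str):
            fh.write(f"{node}\t{partition.assignment[node]}\n")


def read_partition_tsv(path: str) -> Partition:
    assignment: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"partition line {lineno}: expected 2 columns")
            assignment[parts[0]] = parts[1]
    by_label: dict[str, set] = {}
    for node, lab in assignment.items():
        by_label.setdefault(lab, set()).add(node)
    ordered = sorted(by_label, key=lambda lab: (-len(by_label[lab]), min(by_label[lab])))
    return Partition(assignment=assignment, labels=ordered)
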