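"""Modularity, the Louvain heuristic, the exhaustive oracle, and sub-clustering."""

import networkx as nx
import networkx.algorithms.community as nxc
import pytest

from citefronts import (
    EdgelessGraphError,
    LouvainConfig,
    Partition,
    exhaustive_best_partition,
    louvain,
    modularity,
    rank_clusters,
    subcluster,
)


def _partition_of(groups):
    return Partition.from_communities(groups)


def _whole(g):
    return Partition({n: "1" for n in g.nodes}, ["1"])


# --- modularity ---------------------------------------------------------------


def test_single_community_has_zero_modularity(two_triangles, k4, path3):
    for g in (two_triangles, k4, path3):
        assert modularity(g, _whole(g)) == pytest.approx(0.0, abs=1e-12)


def test_single_edge_singletons_is_minus_half(single_edge):
    part = Partition({"u": "1", "v": "2"}, ["1", "2"])
    assert modularity(single_edge, part) == pytest.approx(-0.5, abs=1e-12)


def test_two_triangles_planted_is_half(two_triangles):
    part = _partition_of([{"a", "b", "c"}, {"d", "e", "f"}])
    assert modularity(two_triangles, part) == pytest.approx(0.5, abs=1e-12)


def test_modularity_errors():
    with pytest.raises(EdgelessGraphError):
        modularity(nx.empty_graph(3), _partition_of([{0, 1, 2}]))
    g = nx.Graph([("a", "b")])
    with pytest.raises(ValueError):
        modularity(g, _partition_of([{"a"}]))  # does not cover the nodes


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_modularity_agrees_with_networkx(seed):
    """Independent cross-check of the quality function on random graphs."""
    g = nx.gnp_random_graph(12, 0.3, seed=seed)
    if g.number_of_edges() == 0:
        pytest.skip("degenerate draw")
    comms = [set(c) for c in nxc.louvain_communities(g, seed=seed)]
    part = _partition_of(comms)
    ours = modularity(g, part)
    theirs = nxc.modularity(g, comms)
    assert ours == pytest.approx(theirs, abs=1e-12)


@pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
def test_modularity_resolution_agrees_with_networkx(two_triangles, gamma):
    part = _partition_of([{"a", "b", "c"}, {"d", "e", "f"}])
    theirs = nxc.modularity(two_triangles, part.communities(), resolution=gamma)
    assert modularity(two_triangles, part, gamma) == pytest.approx(theirs, abs=1e-12)


# --- louvain ------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 7, 41])
def test_louvain_recovers_two_triangles(two_triangles, seed):
    part = louvain(two_triangles, LouvainConfig(seed=seed))
    assert part.communities() == [{"a", "b", "c"}, {"d", "e", "f"}]
    assert modularity(two_triangles, part) == pytest.approx(0.5, abs=1e-12)


def test_louvain_leaves_complete_graph_whole(k4):
    part = louvain(k4, LouvainConfig(seed=0))
    assert len(part.labels) == 1
    assert modularity(k4, part) == pytest.approx(0.0, abs=1e-12)


def test_louvain_is_deterministic_for_fixed_seed():
    g = nx.gnp_random_graph(40, 0.12, seed=5)
    a = louvain(g, LouvainConfig(seed=11))
    b = louvain(g, LouvainConfig(seed=11))
    assert a.assignment == b.assignment
    assert a.labels == b.labels


def test_louvain_q_trace_is_non_decreasing():
    g = nx.gnp_random_graph(60, 0.08, seed=2)
    part = louvain(g, LouvainConfig(seed=3))
    qs = part.q_history
    assert qs is not None and len(qs) >= 1
    assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))


def test_louvain_edgeless_graph_errors():
    with pytest.raises(EdgelessGraphError):
        louvain(nx.empty_graph(4), LouvainConfig())


def test_louvain_permutation_equivariance(two_triangles):
    """An order-preserving relabeling of node ids yields the correspondingly
    relabeled partition (the seeded visit protocol sees the same order)."""
    g = nx.gnp_random_graph(25, 0.15, seed=9)
    relabel = {n: f"node{n:04d}" for n in g.nodes}  # monotone in sorted order
    h = nx.relabel_nodes(g, relabel)
    pg = louvain(g, LouvainConfig(seed=4))
    ph = louvain(h, LouvainConfig(seed=4))
    assert {relabel[n]: lab for n, lab in pg.assignment.items()} == ph.assignment


def test_louvain_handles_isolated_nodes():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    g.add_node("z")
    part = louvain(g, LouvainConfig(seed=0))
    assert part.members(part.assignment["z"]) == {"z"}
    assert set(part.assignment) == {"a", "b", "c", "z"}


def test_louvain_matches_networkx_quality():
    """Our heuristic should find partitions as good as the library's."""
    g = nx.planted_partition_graph(4, 20, 0.4, 0.02, seed=8)
    ours = modularity(g, louvain(g, LouvainConfig(seed=1)))
    theirs = nxc.modularity(g, nxc.louvain_communities(g, seed=1))
    assert ours >= theirs - 0.02


# --- exhaustive oracle --------------------------------------------------------


def test_oracle_two_triangles(two_triangles):
    part, q = exhaustive_best_partition(two_triangles)
    assert q == pytest.approx(0.5, abs=1e-12)
    assert part.communities() == [{"a", "b", "c"}, {"d", "e", "f"}]


def test_oracle_single_edge(single_edge):
    part, q = exhaustive_best_partition(single_edge)
    assert q == pytest.approx(0.0, abs=1e-12)
    assert len(part.labels) == 1  # both endpoints together


def test_oracle_path3_and_louvain_bound(path3):
    part, q = exhaustive_best_partition(path3)
    assert q == pytest.approx(0.0, abs=1e-12)  # P3's best is one community
    lq = modularity(path3, louvain(path3, LouvainConfig(seed=0)))
    assert lq <= q + 1e-12


def test_oracle_size_cap():
    with pytest.raises(ValueError):
        exhaustive_best_partition(nx.path_graph(13))


@pytest.mark.parametrize("seed", range(8))
def test_louvain_never_beats_oracle_on_random_graphs(seed):
    g = nx.gnp_random_graph(8, 0.35, seed=seed)
    if g.number_of_edges() == 0:
        pytest.skip("degenerate draw")
    _, q_star = exhaustive_best_partition(g)
    q = modularity(g, louvain(g, LouvainConfig(seed=seed)))
    assert q <= q_star + 1e-12


@pytest.mark.parametrize("k", [3, 4, 5])
def test_merging_disjoint_cliques_never_increases_q(k):
    """Resolution-limit sanity at gamma=1 for small separable cliques."""
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    planted = Partition.from_communities([set(range(k)), set(range(k, 2 * k))])
    merged = Partition.from_communities([set(range(2 * k))])
    assert modularity(g, merged) <= modularity(g, planted)


# --- sub-clustering and ranking ----------------------------------------------


def test_subcluster_labels_children_by_rank(two_triangles):
    parent = Partition({n: "1" for n in two_triangles.nodes}, ["1"])
    refined = subcluster(two_triangles, parent, "1", LouvainConfig(seed=0))
    assert set(refined.labels) == {"1-1", "1-2"}
    # rank 1 child contains the smallest id on the size tie
    assert refined.members("1-1") == {"a", "b", "c"}
    assert refined.members("1-2") == {"d", "e", "f"}


def test_subcluster_whole_parent_single_child(k4):
    parent = Partition({n: "1" for n in k4.nodes}, ["1"])
    refined = subcluster(k4, parent, "1", LouvainConfig(seed=0))
    assert refined.labels == ["1-1"]
    assert refined.members("1-1") == set(k4.nodes)


def test_subcluster_errors(two_triangles):
    parent = Partition({n: "1" for n in two_triangles.nodes}, ["1"])
    with pytest.raises(KeyError):
        subcluster(two_triangles, parent, "9", LouvainConfig())
    g = nx.Graph([("a", "b")])
    g.add_nodes_from(["c", "d"])
    part = Partition({"a": "1", "b": "1", "c": "2", "d": "2"}, ["1", "2"])
    with pytest.raises(EdgelessGraphError):
        subcluster(g, part, "2", LouvainConfig())  # edgeless induced subgraph


def test_subcluster_preserves_other_clusters(two_triangles):
    part = Partition.from_communities([{"a", "b", "c"}, {"d", "e", "f"}])
    refined = subcluster(two_triangles, part, "1", LouvainConfig(seed=0))
    assert refined.assignment["d"] == part.assignment["d"]
    assert all(refined.assignment[n].startswith("1-") for n in ("a", "b", "c"))


def test_rank_clusters_tie_breaks_by_smallest_member():
    part = Partition(
        {f"x{i}": "x" for i in range(5)}
        | {f"y{i}": "y" for i in range(7)}
        | {f"w{i}": "z" for i in range(5)},
        ["y", "x", "z"],
    )
    ranked = rank_clusters(part)
    assert ranked == [("y", 7), ("z", 5), ("x", 5)]  # min id w0 < x0


def test_partition_from_communities_rank_order():
    part = Partition.from_communities([{"m"}, {"a", "b"}, {"c", "d"}])
    assert part.labels == ["1", "2", "3"]
    assert part.members("1") == {"a", "b"}  # ties to smallest member id
    assert part.members("2") == {"c", "d"}
    assert part.members("3") == {"m"}
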