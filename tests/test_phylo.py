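"""Neighbor joining, midpoint rooting, Newick round trips."""

import numpy as np
import pytest

from mitoscan.phylo import (
    DistanceMatrix,
    from_newick,
    leaf_distances,
    midpoint_root,
    neighbor_joining,
    protein_p_distance,
    to_newick,
)


def _dm(ids, values):
    return DistanceMatrix(ids=tuple(ids), values=np.array(values, dtype=float))


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("MWWK", "MWWK", 0.0),
        ("MWW", "MWV", 1 / 3),
        ("MW", "MAW", 0.0),  # M-W / MAW: gap column excluded
    ],
)
def test_protein_p_distance(a, b, expected):
    assert protein_p_distance(a, b) == pytest.approx(expected)


def test_p_distance_rejects_empty():
    with pytest.raises(ValueError):
        protein_p_distance("", "MW")


def test_nj_two_taxa_symmetric_split():
    t = neighbor_joining(_dm("AB", [[0, 0.4], [0.4, 0]]))
    lengths = {n.name: n.length for n in t.tips()}
    assert lengths == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}


def test_nj_three_point_formula():
    t = neighbor_joining(
        _dm("ABC", [[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
    )
    lengths = {n.name: n.length for n in t.tips()}
    assert lengths["A"] == pytest.approx(0.1)
    assert lengths["B"] == pytest.approx(0.1)
    assert lengths["C"] == pytest.approx(0.3)


def test_nj_additive_four_taxa_exact():
    vals = [
        [0, 0.3, 0.45, 0.55],
        [0.3, 0, 0.55, 0.65],
        [0.45, 0.55, 0, 0.7],
        [0.55, 0.65, 0.7, 0],
    ]
    t = neighbor_joining(_dm("ABCD", vals))
    ld = leaf_distances(t)
    assert ld.ids == ("A", "B", "C", "D")
    assert np.allclose(ld.values, vals)
    # AB|CD split: A and B are siblings
    parents = {tip.name: id(tip.parent) for tip in t.tips()}
    assert parents["A"] == parents["B"]


def _random_tree_distances(rng, n):
    """Build a random unrooted binary tree edge list and return exact
    pairwise leaf path lengths (BFS over the edge graph)."""
    # start from a 3-leaf star and repeatedly attach a new leaf to a
    # random existing edge
    edges = {}  # (u, v) -> length

    def add_edge(u, v, w):
        edges[(u, v)] = w

    add_edge("L0", "X0", rng.uniform(0.05, 1.0))
    add_edge("L1", "X0", rng.uniform(0.05, 1.0))
    add_edge("L2", "X0", rng.uniform(0.05, 1.0))
    xi = 1
    for leaf in range(3, n):
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop((u, v))
        split = rng.uniform(0.2, 0.8) * w
        mid = f"X{xi}"; xi += 1
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(f"L{leaf}", mid, rng.uniform(0.05, 1.0))
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    ids = [f"L{i}" for i in range(n)]
    dist = np.zeros((n, n))
    for i, src in enumerate(ids):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        for j, dst in enumerate(ids):
            dist[i, j] = seen[dst]
    np.fill_diagonal(dist, 0.0)
    return ids, (dist + dist.T) / 2


@pytest.mark.parametrize("seed", range(12))
def test_nj_recovers_random_additive_trees(seed):
    """On additive matrices NJ reproduces every leaf-to-leaf path length
    exactly (hence the generating topology)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    ids, dist = _random_tree_distances(rng, n)
    t = neighbor_joining(DistanceMatrix(ids=tuple(ids), values=dist))
    ld = leaf_distances(t)
    order = [ld.ids.index(i) for i in ids]
    assert np.allclose(ld.values[np.ix_(order, order)], dist, atol=1e-9)


def test_nj_topology_agrees_with_skbio():
    """Independent oracle: scikit-bio's NJ yields the same leaf distances
    on an additive matrix."""
    import skbio

    rng = np.random.default_rng(99)
    ids, dist = _random_tree_distances(rng, 6)
    mine = leaf_distances(
        neighbor_joining(DistanceMatrix(ids=tuple(ids), values=dist))
    )
    ref_tree = skbio.tree.nj(skbio.DistanceMatrix(dist, ids))
    ref = {
        frozenset((a, b)): ref_tree.find(a).distance(ref_tree.find(b))
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    }
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = mine.values[mine.ids.index(a), mine.ids.index(b)]
            assert d == pytest.approx(ref[frozenset((a, b))], abs=1e-9)


def test_nj_clamps_negative_lengths():
    vals = [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.05, 0.6], [0.6, 0.05, 0, 0.1],
            [0.6, 0.6, 0.1, 0]]
    t = neighbor_joining(_dm("ABCD", vals))
    for node in t.traverse(include_self=False):
        assert node.length >= 0


def test_midpoint_two_leaves():
    t = neighbor_joining(_dm("AB", [[0, 0.4], [0.4, 0]]))
    r = midpoint_root(t)
    lengths = {n.name: n.length for n in r.tips()}
    assert lengths["A"] == pytest.approx(0.2)


def test_midpoint_roots_on_longest_path():
    t = neighbor_joining(
        _dm("ABC", [[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
    )
    r = midpoint_root(t)
    # root splits C's 0.3 branch at 0.2 from C
    sides = {}
    for child in r.children:
        tips = {tip.name for tip in child.tips()} or {child.name}
        sides[frozenset(tips)] = child.length
    assert sides[frozenset({"C"})] == pytest.approx(0.2)
    assert sides[frozenset({"A", "B"})] == pytest.approx(0.1)


def test_midpoint_of_equal_star_is_center():
    t = neighbor_joining(
        _dm("ABC", [[0, 0.4, 0.4], [0.4, 0, 0.4], [0.4, 0.4, 0]])
    )
    r = midpoint_root(t)
    assert len(r.children) == 3
    assert all(c.length == pytest.approx(0.2) for c in r.children)


def test_newick_round_trip_random_trees():
    rng = np.random.default_rng(4)
    ids, dist = _random_tree_distances(rng, 7)
    t = midpoint_root(neighbor_joining(DistanceMatrix(ids=tuple(ids), values=dist)))
    back = from_newick(to_newick(t))
    a, b = leaf_distances(t), leaf_distances(back)
    assert a.ids == b.ids
    assert np.allclose(a.values, b.values, atol=1e-6)


def test_newick_quotes_labels_with_spaces():
    t = neighbor_joining(
        DistanceMatrix(ids=("tax a", "B"), values=np.array([[0, 0.2], [0.2, 0]]))
    )
    nwk = to_newick(t)
    assert nwk.endswith(";")
    back = from_newick(nwk)
    assert {tip.name for tip in back.tips()} == {"tax a", "B"}
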