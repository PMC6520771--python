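"""Distance-based phylogeny: protein p-distances, neighbor joining,
midpoint rooting, Newick serialization.

A desk-scale alternative to maximum-likelihood inference for showing the
clade-per-species structure of a strain collection: pairwise p-distances
between deduced RdRp proteins feed classical neighbor joining
(Saitou-Nei Q criterion), and the resulting unrooted tree is displayed
midpoint-rooted.  Trees are :class:`skbio.TreeNode` objects, so Newick
round-trips through scikit-bio's parser.
"""

from __future__ import annotations

import dataclasses
import io
import itertools
import logging
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .align import AlignmentParams, global_align

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)


def protein_p_distance(
    a: str, b: str, params: AlignmentParams | None = None
) -> float:
    """Proportion of mismatched columns after global protein alignment.

    Gap columns are excluded from both numerator and denominator.  End
    gaps are penalized here (unlike the identity computation): since gap
    columns do not count, free terminal gaps would silently drop terminal
    residues from the comparison instead of pairing them.
    """
    if not a or not b:
        raise ValueError("cannot compute p-distance of an empty sequence")
    if params is None:
        params = AlignmentParams()
    params = dataclasses.replace(params, end_gaps_penalized=True)
    aln = global_align(a, b, params, kind="protein")
    mismatch = total = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        total += 1
        if x != y:
            mismatch += 1
    if total == 0:
        return 1.0
    return mismatch / total


def p_distance_matrix(
    proteins: dict[str, str], params: AlignmentParams | None = None
) -> DistanceMatrix:
    ids = tuple(proteins)
    n = len(ids)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = protein_p_distance(proteins[ids[i]], proteins[ids[j]], params)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamping negative branch length %.6g to 0 (%s)", length, context)
        return 0.0
    return length


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining (Saitou-Nei).

    Returns the unrooted tree as a TreeNode whose root is the final
    trifurcation (bifurcation for n = 2).  Negative branch-length
    estimates are clamped to 0 and the deficit logged.  Exact on additive
    matrices.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in d.ids]
    D = d.values.copy()

    if n == 2:
        half = D[0, 1] / 2.0
        for node in nodes:
            node.length = half
        return TreeNode(children=nodes)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        nodes[i].length = _clamp(li, f"join of {nodes[i].name}")
        nodes[j].length = _clamp(lj, f"join of {nodes[j].name}")
        new = TreeNode(children=[nodes[i], nodes[j]])
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # final trifurcation: three-point formulas
    (x, y, z) = nodes
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    x.length = _clamp((dxy + dxz - dyz) / 2.0, f"terminal {x.name}")
    y.length = _clamp((dxy + dyz - dxz) / 2.0, f"terminal {y.name}")
    z.length = _clamp((dxz + dyz - dxy) / 2.0, f"terminal {z.name}")
    return TreeNode(children=[x, y, z])


# -- midpoint rooting ---------------------------------------------------------


def _adjacency(tree: TreeNode):
    """Undirected edge map of a TreeNode; nodes keyed by object id."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}
    index: dict[int, TreeNode] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(id(node), [])
        names[id(node)] = node.name
        index[id(node)] = node
        if node.parent is not None:
            length = node.length or 0.0
            adj.setdefault(id(node.parent), []).append((id(node), length))
            adj[id(node)].append((id(node.parent), length))
    return adj, names, index


def _distances_from(adj, start):
    dist = {start: 0.0}
    prev = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                prev[v] = u
                stack.append(v)
    return dist, prev


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root an unrooted tree at the midpoint of its longest leaf-to-leaf
    path; ties break toward the lexicographically smallest leaf pair."""
    adj, names, index = _adjacency(tree)
    leaves = [nid for nid, nbrs in adj.items()
              if index[nid].is_tip()]
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")

    best = None  # (distance, (nameA, nameB), start_id, end_id)
    for u in leaves:
        dist, _ = _distances_from(adj, u)
        for v in leaves:
            if v == u:
                continue
            pair = tuple(sorted([names[u], names[v]]))
            cand = (dist[v], pair)
            if best is None or cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and pair < best[1]
            ):
                start = u if names[u] == pair[0] else v
                end = v if start == u else u
                best = (dist[v], pair, start, end)

    total, _, start, end = best
    dist, prev = _distances_from(adj, start)
    # walk the path from `end` back to `start`
    path = [end]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    half = total / 2.0

    # locate the midpoint along the path
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = next(w for v, w in adj[a] if v == b)
        if acc + w >= half - 1e-12:
            offset = half - acc  # distance from node a into edge (a, b)
            if abs(offset) <= 1e-12:
                return _build_rooted(adj, names, a, exclude=None)
            if abs(offset - w) <= 1e-12:
                return _build_rooted(adj, names, b, exclude=None)
            return _build_rooted_on_edge(adj, names, a, b, offset, w)
        acc += w
    raise AssertionError("midpoint not found on path")  # pragma: no cover


def _subtree(adj, names, node, parent, length):
    children = [
        _subtree(adj, names, v, node, w) for v, w in adj[node] if v != parent
    ]
    return TreeNode(name=names[node], length=length,
                    children=children or None)


def _build_rooted(adj, names, root_id, exclude):
    children = [_subtree(adj, names, v, root_id, w) for v, w in adj[root_id]]
    return TreeNode(name=names[root_id], children=children)


def _build_rooted_on_edge(adj, names, a, b, offset, w):
    left = _subtree(adj, names, a, b, offset)
    right = _subtree(adj, names, b, a, w - offset)
    return TreeNode(children=[left, right])


# -- Newick -------------------------------------------------------------------


def to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths; reserved characters are quoted."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


def leaf_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length distances between all leaf pairs of a tree."""
    adj, names, index = _adjacency(tree)
    leaves = sorted(
        (nid for nid in adj if index[nid].is_tip()),
        key=lambda nid: names[nid],
    )
    ids = tuple(names[nid] for nid in leaves)
    n = len(ids)
    values = np.zeros((n, n))
    for i, u in enumerate(leaves):
        dist, _ = _distances_from(adj, u)
        for j, v in enumerate(leaves):
            if i != j:
                values[i, j] = dist[v]
    values = (values + values.T) / 2.0
    return DistanceMatrix(ids=ids, values=values)


def is_monophyletic(tree: TreeNode, group: Sequence[str]) -> bool:
    """True iff `group` is exactly the leaf set of some clade of a rooted
    tree (or the complement of one, at the root)."""
    want = frozenset(group)
    for node in tree.traverse(include_self=True):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        if tips == want:
            return True
    all_tips = frozenset(t.name for t in tree.tips())
    # at an unrooted trifurcation the complement of a clade is also a clade
    for child in tree.children:
        tips = frozenset(t.name for t in child.tips()) or frozenset([child.name])
        if all_tips - tips == want:
            return True
    return False
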