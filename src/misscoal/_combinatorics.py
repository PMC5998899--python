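"""Low-level tree combinatorics shared by the public modules.

Everything here works on one of two representations:

* a :class:`dendropy.Tree` (the public container used throughout the
  package), from which we extract an *unrooted adjacency* with all
  degree-2 vertices suppressed — so topological path lengths are taken
  on the homeomorphically reduced, unrooted shape; or
* a "nested" tuple structure for enumeration and scoring: a rooted
  binary tree is a leaf label (``str``) or a pair ``(left, right)``.
  An unrooted binary tree on taxa ``X`` is stored as a nested structure
  on ``X - {x0}`` with the anchor taxon ``x0`` (the lexicographically
  smallest) implicitly attached to its root.

Bipartitions are encoded as bit masks over a sorted taxon order, always
normalized to the side *not* containing bit 0, so that set membership is
exact integer equality.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "tree_adjacency",
    "leaf_labels",
    "edge_count_distances",
    "nested_from_tree",
    "tree_from_nested",
    "unrooted_distance_matrix",
    "nested_clade_masks",
    "rooted_nested_from_tree",
    "rooted_tree_from_nested",
    "lca_depth_matrix",
    "nested_lca_depths",
    "enumerate_rooted_nested",
    "enumerate_unrooted",
    "constrained_unrooted",
    "count_constrained",
    "subset_index",
    "quartet_options",
    "triplet_options",
    "popcount",
    "mask_of",
    "labels_of_mask",
]


def popcount(x: int) -> int:
    return int(x).bit_count()


def mask_of(labels: Iterable[str], index: dict[str, int]) -> int:
    m = 0
    for lab in labels:
        m |= 1 << index[lab]
    return m


def labels_of_mask(mask: int, taxa: Sequence[str]) -> frozenset[str]:
    return frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)


# ---------------------------------------------------------------------------
# dendropy adjacency / distances
# ---------------------------------------------------------------------------

def tree_adjacency(tree: dendropy.Tree):
    """Unrooted adjacency of ``tree`` with degree-2 vertices suppressed.

    Returns ``(adj, leaves)`` where ``adj`` maps an integer node id to the
    list of adjacent ids and ``leaves`` maps taxon label -> node id.
    A rooted tree's degree-2 root disappears, so path edge counts refer to
    the unrooted homeomorphically reduced shape.
    """
    adj: dict[int, list[int]] = {}
    leaves: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        nid = id(node)
        adj.setdefault(nid, [])
        if node.parent_node is not None:
            pid = id(node.parent_node)
            adj[nid].append(pid)
            adj.setdefault(pid, []).append(nid)
        if node.is_leaf():
            if node.taxon is None or node.taxon.label is None:
                raise ValueError("leaf without a taxon label")
            leaves[node.taxon.label] = nid
    # suppress degree-2 vertices (root of a rooted tree, pruning artefacts)
    changed = True
    while changed:
        changed = False
        for nid, nbrs in list(adj.items()):
            if len(nbrs) == 2 and nid in adj:
                a, b = nbrs
                adj[a] = [x if x != nid else b for x in adj[a]]
                adj[b] = [x if x != nid else a for x in adj[b]]
                del adj[nid]
                changed = True
    return adj, leaves


def leaf_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))


def edge_count_distances(tree: dendropy.Tree):
    """Pairwise path edge counts on the reduced unrooted shape.

    Returns ``(labels, D)`` with labels sorted and ``D`` an ``(n, n)``
    integer matrix; ``D[i, j]`` is the number of edges on the i-j path.
    """
    adj, leaves = tree_adjacency(tree)
    labels = tuple(sorted(leaves))
    n = len(labels)
    D = np.zeros((n, n), dtype=np.int64)
    if n < 2:
        return labels, D
    if n == 2:
        D[0, 1] = D[1, 0] = 1
        return labels, D
    leaf_of = {nid: i for i, nid in enumerate(leaves[l] for l in labels)}
    for i, lab in enumerate(labels):
        # BFS from each leaf; trees are tiny so this is fine
        start = leaves[lab]
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for nid, j in leaf_of.items():
            D[i, j] = dist[nid]
    return labels, D


# ---------------------------------------------------------------------------
# nested (tuple) representation
# ---------------------------------------------------------------------------

def nested_from_tree(tree: dendropy.Tree):
    """Unrooted nested form: ``(x0, nested)`` with x0 the smallest taxon."""
    adj, leaves = tree_adjacency(tree)
    labels = tuple(sorted(leaves))
    if len(labels) < 3:
        raise ValueError("unrooted nested form requires >= 3 leaves")
    label_of = {nid: lab for lab, nid in leaves.items()}
    x0 = labels[0]
    anchor = leaves[x0]
    (root,) = adj[anchor]

    def build(nid, parent):
        if nid in label_of and len(adj[nid]) == 1:
            return label_of[nid]
        kids = [v for v in adj[nid] if v != parent]
        if len(kids) != 2:
            raise ValueError("tree is not binary")
        return (build(kids[0], nid), build(kids[1], nid))

    return x0, build(root, anchor)


def tree_from_nested(x0: str, nested, lengths: float | None = None) -> dendropy.Tree:
    """Build an unrooted dendropy tree from ``(x0, nested)``."""
    labels = sorted([x0, *nested_leafset(nested)])
    ns = dendropy.TaxonNamespace(labels)

    def build(node):
        nd = dendropy.Node()
        if isinstance(node, str):
            nd.taxon = ns.get_taxon(node)
        else:
            for child in node:
                c = build(child)
                nd.add_child(c)
                if lengths is not None:
                    c.edge.length = lengths
        return nd

    root = dendropy.Node()
    leaf0 = dendropy.Node()
    leaf0.taxon = ns.get_taxon(x0)
    root.add_child(leaf0)
    if isinstance(nested, str):
        other = dendropy.Node()
        other.taxon = ns.get_taxon(nested)
        root.add_child(other)
    else:
        for child in nested:
            root.add_child(build(child))
    if lengths is not None:
        for ch in root.child_nodes():
            ch.edge.length = lengths
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def nested_leafset(nested) -> frozenset[str]:
    if isinstance(nested, str):
        return frozenset((nested,))
    return nested_leafset(nested[0]) | nested_leafset(nested[1])


def unrooted_distance_matrix(x0: str, nested, index: dict[str, int], n: int):
    """Path edge counts of the unrooted tree ``(x0, nested)``."""
    D = np.zeros((n, n), dtype=np.int64)

    def rec(node):
        if isinstance(node, str):
            return {index[node]: 0}
        dl = rec(node[0])
        dr = rec(node[1])
        for i, di in dl.items():
            for j, dj in dr.items():
                D[i, j] = D[j, i] = di + dj + 2
        out = {i: d + 1 for i, d in dl.items()}
        out.update({j: d + 1 for j, d in dr.items()})
        return out

    top = rec(nested)
    i0 = index[x0]
    for i, d in top.items():
        D[i0, i] = D[i, i0] = d + 1
    return D


def nested_clade_masks(nested, index: dict[str, int]) -> list[int]:
    """Masks of all internal-node leaf sets of ``nested`` (root included)."""
    masks: list[int] = []

    def rec(node):
        if isinstance(node, str):
            return 1 << index[node]
        m = rec(node[0]) | rec(node[1])
        masks.append(m)
        return m

    rec(nested)
    return masks


# ---------------------------------------------------------------------------
# rooted trees (for triplet statistics)
# ---------------------------------------------------------------------------

def rooted_nested_from_tree(tree: dendropy.Tree):
    """Nested form of a rooted binary dendropy tree."""

    def build(node):
        if node.is_leaf():
            return node.taxon.label
        kids = node.child_nodes()
        while len(kids) == 1:  # suppress degree-2 chains
            node = kids[0]
            if node.is_leaf():
                return node.taxon.label
            kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("rooted tree is not binary")
        return (build(kids[0]), build(kids[1]))

    return build(tree.seed_node)


def rooted_tree_from_nested(nested, lengths: float | None = None) -> dendropy.Tree:
    labels = sorted(nested_leafset(nested))
    ns = dendropy.TaxonNamespace(labels)

    def build(node):
        nd = dendropy.Node()
        if isinstance(node, str):
            nd.taxon = ns.get_taxon(node)
        else:
            for child in node:
                c = build(child)
                nd.add_child(c)
                if lengths is not None:
                    c.edge.length = lengths
        return nd

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=build(nested))
    tree.is_rooted = True
    return tree


def lca_depth_matrix(tree: dendropy.Tree, index: dict[str, int], n: int):
    """``L[i, j]`` = depth (edges from root) of the LCA of leaves i, j.

    Depth comparisons survive restriction to a leaf subset, so the matrix
    determines every induced rooted triplet topology.
    """
    return nested_lca_depths(rooted_nested_from_tree(tree), index, n)


def nested_lca_depths(nested, index: dict[str, int], n: int):
    L = np.full((n, n), -1, dtype=np.int64)

    def rec(node, depth):
        if isinstance(node, str):
            return [index[node]]
        left = rec(node[0], depth + 1)
        right = rec(node[1], depth + 1)
        for i in left:
            for j in right:
                L[i, j] = L[j, i] = depth
        return left + right

    rec(nested, 0)
    return L


# ---------------------------------------------------------------------------
# topology enumeration
# ---------------------------------------------------------------------------

def _insert_leaf(node, leaf):
    yield (node, leaf)
    if isinstance(node, tuple):
        left, right = node
        for nl in _insert_leaf(left, leaf):
            yield (nl, right)
        for nr in _insert_leaf(right, leaf):
            yield (left, nr)


def enumerate_rooted_nested(labels: Sequence[str]):
    """All rooted binary topologies on ``labels`` (nested form)."""
    labels = list(labels)
    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = [nt for t in trees for nt in _insert_leaf(t, leaf)]
    return trees


def enumerate_unrooted(labels: Sequence[str]):
    """All unrooted binary topologies: pairs ``(x0, nested)``."""
    labels = sorted(labels)
    x0 = labels[0]
    return [(x0, nested) for nested in enumerate_rooted_nested(labels[1:])]


def count_constrained(full_mask: int, allowed: frozenset[int]) -> int:
    """Number of unrooted trees whose nontrivial bipartitions lie in
    ``allowed`` (masks normalized away from bit 0); ``full_mask`` excludes
    bit 0 (the anchor taxon)."""
    memo: dict[int, int] = {}

    def rec(mask: int) -> int:
        if popcount(mask) == 1:
            return 1
        if mask in memo:
            return memo[mask]
        low = mask & -mask
        total = 0
        for c1 in _allowed_subclades(mask, allowed):
            if not c1 & low:
                continue
            c2 = mask ^ c1
            if _clade_ok(c2, mask, allowed):
                total += rec(c1) * rec(c2)
        memo[mask] = total
        return total

    return rec(full_mask)


def _clade_ok(c: int, parent_mask: int, allowed: frozenset[int]) -> bool:
    return popcount(c) == 1 or c in allowed


def _allowed_subclades(mask: int, allowed: frozenset[int]):
    for i in range(mask.bit_length()):
        b = 1 << i
        if mask & b:
            yield b
    for c in allowed:
        if c & mask == c and c != mask and popcount(c) > 1:
            yield c


def constrained_unrooted(taxa: Sequence[str], allowed: frozenset[int],
                         limit: int = 2_000_000):
    """All unrooted trees on ``taxa`` drawing nontrivial bipartitions from
    ``allowed`` (bit masks over sorted ``taxa``, side excluding bit 0).

    Raises ``RuntimeError`` if the space exceeds ``limit`` trees.
    """
    taxa = sorted(taxa)
    n = len(taxa)
    full_mask = (1 << n) - 2  # all taxa except bit 0
    total = count_constrained(full_mask, allowed)
    if total > limit:
        raise RuntimeError(
            f"constrained search space has {total} trees (> limit {limit})")
    memo: dict[int, list] = {}

    def rec(mask: int) -> list:
        if popcount(mask) == 1:
            return [taxa[mask.bit_length() - 1]]
        if mask in memo:
            return memo[mask]
        low = mask & -mask
        out = []
        for c1 in _allowed_subclades(mask, allowed):
            if not c1 & low:
                continue
            c2 = mask ^ c1
            if _clade_ok(c2, mask, allowed):
                for l in rec(c1):
                    for r in rec(c2):
                        out.append((l, r))
        memo[mask] = out
        return out

    return [(taxa[0], nested) for nested in rec(full_mask)]


# ---------------------------------------------------------------------------
# quartet / triplet index machinery
# ---------------------------------------------------------------------------

def subset_index(n: int, ell: int) -> np.ndarray:
    """Sorted ``ell``-subsets of ``range(n)`` as an ``(S, ell)`` array."""
    return np.array(list(itertools.combinations(range(n), ell)), dtype=np.int64)


def quartet_options(D: np.ndarray, subs: np.ndarray) -> np.ndarray:
    """Induced quartet topology per 4-subset from a tree's path metric.

    Option 0: smallest index pairs with the 2nd (ij|kl); 1: with the 3rd
    (ik|jl); 2: with the 4th (il|jk). On a binary tree metric the minimum
    pairwise sum is strict, so argmin identifies the induced split.
    """
    i, j, k, l = subs.T
    sums = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
    return np.argmin(sums, axis=0)


def triplet_options(L: np.ndarray, subs: np.ndarray) -> np.ndarray:
    """Induced rooted triplet per 3-subset from an LCA-depth matrix.

    Option 0: cherry (i,j); 1: cherry (i,k); 2: cherry (j,k). The cherry
    pair has the strictly deepest LCA.
    """
    i, j, k = subs.T
    depths = np.stack([L[i, j], L[i, k], L[j, k]])
    return np.argmax(depths, axis=0)
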