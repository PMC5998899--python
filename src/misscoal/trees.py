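"""Tree data model and basic operations.

Trees are :class:`dendropy.Tree` objects. A tree is treated as *rooted*
when ``is_rooted`` is true (its seed node then has exactly two children);
otherwise operations work on the unrooted, homeomorphically reduced shape.
Newick input follows the structural convention: a top-level bifurcation is
read as a rooted tree, a trifurcation (or higher) as unrooted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy

from ._combinatorics import (
    labels_of_mask,
    leaf_labels,
    nested_clade_masks,
    nested_from_tree,
    popcount,
)

__all__ = [
    "Bipartition",
    "parse_newick",
    "write_newick",
    "read_gene_trees",
    "write_gene_trees",
    "restrict",
    "bipartitions",
    "bipartition_masks",
    "root_tree",
    "rf_distance",
]


@dataclass(frozen=True)
class Bipartition:
    """A bipartition of a reference leafset, in canonical form.

    ``side1`` is the side containing the lexicographically smallest taxon.
    Equality and hashing are order-insensitive by construction.
    """

    side1: frozenset[str]
    side2: frozenset[str]

    @staticmethod
    def of(a: Iterable[str], b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise ValueError("bipartition sides must be nonempty")
        if a & b:
            raise ValueError("bipartition sides must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        return Bipartition(a, b)

    @property
    def leafset(self) -> frozenset[str]:
        return self.side1 | self.side2

    def __str__(self) -> str:  # canonical text form
        return ",".join(sorted(self.side1)) + " | " + ",".join(sorted(self.side2))


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick tree.

    Duplicate leaf labels and malformed strings raise ``ValueError`` naming
    the offending token. Rootedness is structural: a binary top-level split
    yields a rooted tree, a trifurcation an unrooted one.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError("malformed Newick: unlabeled leaf")
        lab = leaf.taxon.label
        if lab in seen:
            raise ValueError(f"duplicate leaf label: {lab!r}")
        seen.add(lab)
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    return s.strip()


def read_gene_trees(path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file, one tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_gene_trees(trees: Iterable[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


def restrict(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Homeomorphic subtree on ``taxa``; merged edge lengths are summed.

    A rooted input stays rooted (re-seeded at the MRCA of the kept taxa);
    an unrooted input stays unrooted.
    """
    taxa = frozenset(taxa)
    leafset = frozenset(leaf_labels(tree))
    if len(taxa) < 2:
        raise ValueError("restriction requires at least 2 taxa")
    if not taxa <= leafset:
        missing = sorted(taxa - leafset)
        raise ValueError(f"taxa not in tree: {missing}")
    sub = tree.clone(depth=1)
    if taxa == leafset:
        return sub
    sub.retain_taxa_with_labels(sorted(taxa))
    # drop any residual unifurcation chain at the seed (keep lengths summed
    # on internal merges, which retain_taxa already handles)
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        sub.seed_node = child
    sub.seed_node.edge.length = None
    if not tree.is_rooted:
        sub.is_rooted = False
    return sub


def bipartition_masks(tree: dendropy.Tree, taxa: tuple[str, ...] | None = None) -> set[int]:
    """Nontrivial bipartitions of the unrooted shape as canonical bit masks.

    Masks are over sorted ``taxa`` (default: the tree's leafset) and always
    encode the side not containing the smallest taxon of the *tree*.
    """
    labels = leaf_labels(tree)
    if taxa is None:
        taxa = labels
    index = {t: i for i, t in enumerate(sorted(taxa))}
    n = len(labels)
    if n < 4:
        return set()
    _, nested = nested_from_tree(tree)
    masks = nested_clade_masks(nested, index)
    return {m for m in masks if 2 <= popcount(m) <= n - 2}


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Nontrivial bipartitions of the (unrooted) tree; ``n - 3`` of them
    for a binary tree on ``n >= 4`` leaves, empty otherwise."""
    labels = tuple(sorted(leaf_labels(tree)))
    leafset = frozenset(labels)
    out = set()
    for m in bipartition_masks(tree):
        side = labels_of_mask(m, labels)
        out.add(Bipartition.of(side, leafset - side))
    return out


def root_tree(tree: dendropy.Tree, outgroup: str | None = None) -> dendropy.Tree:
    """Root a tree, on the outgroup's pendant edge or at the midpoint of the
    longest leaf-to-leaf path (unit edge lengths if none are present)."""
    rooted = tree.clone(depth=1)
    if outgroup is not None:
        node = None
        for leaf in rooted.leaf_node_iter():
            if leaf.taxon.label == outgroup:
                node = leaf
                break
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        rooted.reroot_at_edge(node.edge, update_bipartitions=False)
    else:
        if any(e.length is None for e in rooted.preorder_edge_iter()
               if e.tail_node is not None):
            for e in rooted.preorder_edge_iter():
                if e.tail_node is not None:
                    e.length = 1.0
        rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = False) -> float:
    """Robinson-Foulds distance between the unrooted shapes of two binary
    trees on the same leafset.

    The raw value is the symmetric-difference count of nontrivial
    bipartitions; the normalized form divides by ``2 (n - 3)`` so that
    maximally different trees score 1.0. Trees on fewer than 4 leaves have
    no nontrivial bipartitions and score 0.
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            "leafsets differ (restrict to a common taxon set first): "
            f"{sorted(set(l1) ^ set(l2))}")
    n = len(l1)
    if n < 4:
        return 0.0
    b1 = bipartition_masks(t1, l1)
    b2 = bipartition_masks(t2, l1)
    raw = len(b1 ^ b2)
    if not normalized:
        return float(raw)
    return raw / (2.0 * (n - 3))
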