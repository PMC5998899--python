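"""Species-tree generation and gene-tree simulation under the
multi-species coalescent (MSC).

Branch lengths are in coalescent units throughout: within a population
containing ``k`` uncoalesced lineages, the waiting time to the next
coalescence is exponential with rate ``k (k - 1) / 2 * lam``, and the
coalescing pair is chosen uniformly. With lengths already expressed in
coalescent units the rate constant ``lam`` defaults to 1.

Gene-tree estimation error is emulated topologically, by applying random
nearest-neighbor-interchange (NNI) moves, instead of simulating sequence
evolution and re-estimating trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from ._combinatorics import nested_from_tree, tree_from_nested
from .trees import leaf_labels

__all__ = [
    "CoalescentConfig",
    "yule_species_tree",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "perturb_gene_tree",
]


@dataclass
class CoalescentConfig:
    """MSC simulation settings: coalescence rate ``lam`` (> 0) and seed."""

    lam: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("coalescent rate lam must be > 0")


def yule_species_tree(n: int, total_height: float, seed: int) -> dendropy.Tree:
    """Random pure-birth (Yule) species tree on ``n`` taxa, rescaled so the
    root-to-leaf height equals ``total_height`` coalescent units.

    Taller trees mean longer internal branches, hence less incomplete
    lineage sorting. Taxa are labeled ``t01, t02, ...`` in birth order.
    """
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if total_height <= 0:
        raise ValueError("total_height must be > 0")
    rng = np.random.default_rng(seed)
    width = len(str(n))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]
    ns = dendropy.TaxonNamespace(labels)
    # forward pure-birth process: two lineages from the root at time 0,
    # each lineage splits at unit rate; after the n-th tip appears the
    # process is held one further exponential waiting time so every
    # pendant branch has positive length
    t = 0.0
    root = dendropy.Node()
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node, birth = active.pop(int(rng.integers(k)))
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / n)
    order = rng.permutation(n)
    for (node, birth), lab_i in zip(active, order):
        node.edge.length = t - birth
        node.taxon = ns.get_taxon(labels[lab_i])
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = True
    factor = total_height / t
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length *= factor
    return tree


def caterpillar_species_tree(n: int, internal: float = 1.0,
                             pendant: float = 1.0) -> dendropy.Tree:
    """Rooted caterpillar ((...((t1,t2),t3)...),tn) with fixed branch
    lengths in coalescent units."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    width = len(str(n))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]
    ns = dendropy.TaxonNamespace(labels)
    node = dendropy.Node()
    a = dendropy.Node()
    a.taxon = ns.get_taxon(labels[0])
    b = dendropy.Node()
    b.taxon = ns.get_taxon(labels[1])
    node.add_child(a)
    node.add_child(b)
    a.edge.length = b.edge.length = pendant
    for lab in labels[2:]:
        parent = dendropy.Node()
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(lab)
        parent.add_child(node)
        parent.add_child(leaf)
        node.edge.length = internal
        leaf.edge.length = pendant
        node = parent
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=node)
    tree.is_rooted = True
    return tree


def _node_ages(st: dendropy.Tree) -> dict[int, float]:
    depth: dict[int, float] = {id(st.seed_node): 0.0}
    maxd = 0.0
    for node in st.preorder_node_iter():
        if node.parent_node is not None:
            d = depth[id(node.parent_node)] + (node.edge.length or 0.0)
            depth[id(node)] = d
            maxd = max(maxd, d)
    return {nid: maxd - d for nid, d in depth.items()}


def simulate_gene_tree(st: dendropy.Tree,
                       cfg: CoalescentConfig | None = None,
                       rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Simulate one rooted gene tree within species tree ``st`` under the
    MSC; branch lengths of the result are in coalescent units."""
    if cfg is None:
        cfg = CoalescentConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam = cfg.lam
    ages = _node_ages(st)
    labels = sorted(leaf_labels(st))
    ns = dendropy.TaxonNamespace(labels)

    def coalesce(pool, t_start, t_end):
        t = t_start
        while len(pool) > 1:
            k = len(pool)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0 * lam))
            if t > t_end:
                break
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            (n1, a1), (n2, a2) = pool[i], pool[j]
            parent = dendropy.Node()
            parent.add_child(n1)
            parent.add_child(n2)
            n1.edge.length = t - a1
            n2.edge.length = t - a2
            pool[i] = (parent, t)
            pool.pop(j)
        return pool

    def process(node) -> list:
        if node.is_leaf():
            leaf = dendropy.Node()
            leaf.taxon = ns.get_taxon(node.taxon.label)
            pool = [(leaf, ages[id(node)])]
        else:
            pool = []
            for child in node.child_nodes():
                pool.extend(process(child))
        if node.parent_node is None:
            return coalesce(pool, ages[id(node)], np.inf)
        return coalesce(pool, ages[id(node)], ages[id(node.parent_node)])

    (root, _), = process(st.seed_node)
    gt = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    gt.is_rooted = True
    return gt


def simulate_gene_trees(st: dendropy.Tree, m: int, seed: int,
                        lam: float = 1.0) -> list[dendropy.Tree]:
    """Simulate ``m`` independent gene trees; gene ``i`` uses a deterministic
    substream of ``seed`` so prefixes are reproducible across runs."""
    streams = np.random.SeedSequence(seed).spawn(m)
    cfg = CoalescentConfig(lam=lam)
    return [simulate_gene_tree(st, cfg, np.random.default_rng(s))
            for s in streams]


def perturb_gene_tree(gt: dendropy.Tree, n_moves: int,
                      seed: int | np.random.Generator = 0) -> dendropy.Tree:
    """Apply ``n_moves`` random NNI moves (internal edges chosen uniformly)
    to the unrooted shape of ``gt``; the result is unrooted without branch
    lengths. ``n_moves=0`` reproduces the topology; trees with fewer than 4
    leaves have no internal edge and are returned unchanged in shape."""
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = leaf_labels(gt)
    if len(labels) < 4:
        return gt.clone(depth=1)
    x0, nested = nested_from_tree(gt)

    def to_lists(node):
        if isinstance(node, str):
            return node
        return [to_lists(node[0]), to_lists(node[1])]

    def to_tuples(node):
        if isinstance(node, str):
            return node
        return (to_tuples(node[0]), to_tuples(node[1]))

    root = to_lists(nested)
    for _ in range(n_moves):
        edges = []  # (parent_list, slot) with internal child

        def walk(node):
            for slot in (0, 1):
                if isinstance(node[slot], list):
                    edges.append((node, slot))
                    walk(node[slot])

        if isinstance(root, list):
            walk(root)
        if not edges:
            break
        u, slot = edges[rng.integers(len(edges))]
        v = u[slot]
        s = int(rng.integers(2))
        u[1 - slot], v[s] = v[s], u[1 - slot]
    return tree_from_nested(x0, to_tuples(root))
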