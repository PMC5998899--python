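"""Species-tree estimators operating on tuple summary statistics.

Three estimator families:

* neighbor joining on the average internode distance matrix (the 2-tuple
  route used by NJst/ASTRID);
* quartet-score maximization (the ASTRAL objective): exact enumeration on
  small taxon sets, or a search constrained to candidate trees drawing
  every nontrivial bipartition from an allowed set ``beta``. The allowed
  set can be built from complete gene trees only (the default heuristic),
  augmented with the complement-completion of every gene-tree clade
  ("mod1"), or augmented with the bipartitions of a tree computed by an
  auxiliary method ("+Phi");
* rooted triplet-score maximization (a 3-tuple analogue of MP-EST's
  summary statistics; scores topologies only, no branch lengths or
  pseudo-likelihood).

Constrained search is implemented by memoized enumeration of the allowed
tree space followed by exact scoring, so its output provably maximizes
the objective over that space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from ._combinatorics import (
    constrained_unrooted,
    enumerate_rooted_nested,
    enumerate_unrooted,
    labels_of_mask,
    nested_clade_masks,
    nested_from_tree,
    nested_lca_depths,
    popcount,
    quartet_options,
    rooted_tree_from_nested,
    tree_from_nested,
    triplet_options,
    unrooted_distance_matrix,
)
from .summaries import DistanceSummary, QuartetTable, TripletTable
from .trees import Bipartition, bipartition_masks, leaf_labels, write_newick

__all__ = [
    "BipartitionSet",
    "EstimatorResult",
    "SearchSpaceEmptyError",
    "UndefinedDistanceError",
    "nj_tree",
    "quartet_score",
    "triplet_score",
    "exact_quartet_search",
    "constrained_quartet_search",
    "triplet_search",
    "beta_default",
    "beta_mod1",
    "beta_plus_phi",
]

EXACT_GUARD = 9     # unrooted enumeration guard
ROOTED_GUARD = 7    # rooted enumeration guard


class SearchSpaceEmptyError(RuntimeError):
    """No binary tree on the full taxon set draws all its bipartitions
    from the allowed set."""


class UndefinedDistanceError(ValueError):
    """The average internode matrix has pairs with zero co-occurrence."""


@dataclass
class BipartitionSet:
    """An allowed-bipartition search space over a reference taxon set.

    Bipartitions are stored as canonical bit masks (side not containing
    the first taxon of the sorted reference set); trivial bipartitions are
    implicit members. ``provenance`` maps each mask to the labels of the
    sources that contributed it.
    """

    taxa: tuple[str, ...]
    masks: set[int] = field(default_factory=set)
    provenance: dict[int, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxa = tuple(sorted(self.taxa))

    @property
    def n(self) -> int:
        return len(self.taxa)

    def _normalize(self, mask: int) -> int:
        full = (1 << self.n) - 1
        return full ^ mask if mask & 1 else mask

    def add(self, mask: int, source: str) -> None:
        if not 0 < mask < (1 << self.n) - 1:
            raise ValueError("mask does not bipartition the taxon set")
        mask = self._normalize(mask)
        if not 2 <= popcount(mask) <= self.n - 2:
            return  # trivial; always implicitly present
        self.masks.add(mask)
        self.provenance.setdefault(mask, set()).add(source)

    def add_bipartition(self, bp: Bipartition, source: str) -> None:
        if bp.leafset != frozenset(self.taxa):
            raise ValueError("bipartition is not on the reference taxon set")
        index = {t: i for i, t in enumerate(self.taxa)}
        mask = 0
        for t in bp.side2:
            mask |= 1 << index[t]
        self.add(mask, source)

    def __contains__(self, bp: Bipartition) -> bool:
        index = {t: i for i, t in enumerate(self.taxa)}
        mask = 0
        for t in bp.side2:
            mask |= 1 << index[t]
        return self._normalize(mask) in self.masks

    def bipartitions(self) -> set[Bipartition]:
        leafset = frozenset(self.taxa)
        return {Bipartition.of(labels_of_mask(m, self.taxa),
                               leafset - labels_of_mask(m, self.taxa))
                for m in self.masks}

    def union(self, other: "BipartitionSet") -> "BipartitionSet":
        if self.taxa != other.taxa:
            raise ValueError("taxon sets differ")
        out = BipartitionSet(self.taxa, set(self.masks),
                             {m: set(s) for m, s in self.provenance.items()})
        for m in other.masks:
            out.masks.add(m)
            out.provenance.setdefault(m, set()).update(
                other.provenance.get(m, set()))
        return out

    def to_text(self, path) -> None:
        leafset = frozenset(self.taxa)
        with open(path, "w") as fh:
            for m in sorted(self.masks):
                side = labels_of_mask(m, self.taxa)
                bp = Bipartition.of(side, leafset - side)
                src = ";".join(sorted(self.provenance.get(m, set())))
                fh.write(f"{bp}\t{src}\n")


@dataclass
class EstimatorResult:
    """Outcome of a species-tree estimation run.

    ``objective`` is the quartet or triplet score (0.0 for distance-based
    estimation, which has no discrete objective).
    """

    tree: dendropy.Tree
    objective: float
    method: str
    search_space: str
    warnings: list[str] = field(default_factory=list)
    n_genes: int | None = None

    def summary(self) -> str:
        lines = [
            f"Species tree estimate ({self.method})",
            "=" * 46,
            f"taxa:          {len(leaf_labels(self.tree))}",
            f"genes:         {self.n_genes if self.n_genes is not None else 'n/a'}",
            f"objective:     {self.objective:g}",
            f"search space:  {self.search_space}",
            f"tree:          {write_newick(self.tree)}",
        ]
        for w in self.warnings:
            lines.append(f"warning:       {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(ds: DistanceSummary) -> EstimatorResult:
    """Classic neighbor joining on the average internode matrix.

    Ties in the Q-criterion break to the lowest index pair under the
    sorted taxon order (merged nodes rank after the originals), making
    the procedure fully deterministic. Any undefined pair is an error.
    """
    und = ds.undefined_pairs()
    if und:
        raise UndefinedDistanceError(
            f"undefined average distances for pairs {und}; "
            "add genes covering these taxa together")
    n = ds.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    taxa = list(ds.taxa)
    if n == 2:
        nested = taxa[1]
        tree = tree_from_nested(taxa[0], nested)
        return EstimatorResult(tree, 0.0, "nj", "distance-based",
                               n_genes=None)
    D = ds.average.astype(np.float64).copy()
    nodes: list = list(taxa)  # str leaf or tuple subtree
    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # row-major => lowest pair
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        d_ij = D[ai, aj]
        new = len(nodes)
        nodes.append((nodes[ai], nodes[aj]))
        D = np.pad(D, ((0, 1), (0, 1)))
        for a in active:
            if a in (ai, aj):
                continue
            D[new, a] = D[a, new] = 0.5 * (D[ai, a] + D[aj, a] - d_ij)
        active = [a for a in active if a not in (ai, aj)] + [new]
    a, b, c = active
    star = (nodes[a], nodes[b], nodes[c])
    tree = _tree_from_star(star)
    return EstimatorResult(tree, 0.0, "nj", "distance-based")


def _tree_from_star(star) -> dendropy.Tree:
    """Unrooted tree from three subtrees joined at one internal vertex."""
    from ._combinatorics import nested_leafset

    def leafset(node):
        return {node} if isinstance(node, str) else nested_leafset(node)

    labels = sorted(set().union(*(leafset(s) for s in star)))
    ns = dendropy.TaxonNamespace(labels)

    def build(node):
        nd = dendropy.Node()
        if isinstance(node, str):
            nd.taxon = ns.get_taxon(node)
        else:
            nd.add_child(build(node[0]))
            nd.add_child(build(node[1]))
        return nd

    root = dendropy.Node()
    for s in star:
        root.add_child(build(s))
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# quartet scoring and search
# ---------------------------------------------------------------------------

def quartet_score(candidate: dendropy.Tree, qt: QuartetTable) -> int:
    """Number of gene-quartet topologies the candidate agrees with, summed
    over all 4-subsets."""
    labels = leaf_labels(candidate)
    if tuple(sorted(labels)) != qt.taxa:
        raise ValueError("candidate leafset does not match the quartet table")
    x0, nested = nested_from_tree(candidate)
    return _score_nested(x0, nested, qt)


def _score_nested(x0, nested, qt: QuartetTable) -> int:
    index = {t: i for i, t in enumerate(qt.taxa)}
    D = unrooted_distance_matrix(x0, nested, index, len(qt.taxa))
    opts = quartet_options(D, qt.subsets)
    return int(qt.counts[np.arange(len(qt.subsets)), opts].sum())


def _canonical_newick(x0, nested) -> str:
    def canon(node):
        if isinstance(node, str):
            return node
        a, b = canon(node[0]), canon(node[1])
        if a > b:
            a, b = b, a
        return f"({a},{b})"

    return f"({x0},{canon(nested)});"


def _pick_maximizer(cands, scores):
    """Maximal score; ties broken by canonical Newick order."""
    best = max(scores)
    tied = [c for c, s in zip(cands, scores) if s == best]
    tied.sort(key=lambda c: _canonical_newick(*c))
    return tied[0], best, len(tied)


def exact_quartet_search(qt: QuartetTable,
                         taxa: Sequence[str] | None = None) -> EstimatorResult:
    """Maximize the quartet score over *all* unrooted binary topologies
    (enumeration; guarded to at most 9 taxa)."""
    taxa = tuple(sorted(taxa if taxa is not None else qt.taxa))
    if taxa != qt.taxa:
        raise ValueError("taxa do not match the quartet table")
    if len(taxa) > EXACT_GUARD:
        raise ValueError(
            f"exact search is limited to {EXACT_GUARD} taxa; use "
            "constrained_quartet_search")
    cands = enumerate_unrooted(taxa)
    scores = [_score_nested(x0, nested, qt) for x0, nested in cands]
    (x0, nested), best, n_tied = _pick_maximizer(cands, scores)
    warnings = []
    if n_tied > 1:
        warnings.append(f"{n_tied} topologies tie at the optimum; "
                        "returned the canonically smallest")
    return EstimatorResult(tree_from_nested(x0, nested), float(best),
                           "quartet-exact", f"all {len(cands)} topologies",
                           warnings)


def constrained_quartet_search(qt: QuartetTable,
                               beta: BipartitionSet) -> EstimatorResult:
    """Maximize the quartet score over trees drawing every nontrivial
    bipartition from ``beta``."""
    if beta.taxa != qt.taxa:
        raise ValueError("beta and quartet table taxon sets differ")
    cands = constrained_unrooted(beta.taxa, frozenset(beta.masks))
    if not cands:
        raise SearchSpaceEmptyError(
            "search space empty under beta: no binary tree on "
            f"{len(beta.taxa)} taxa draws all its bipartitions from the "
            f"{len(beta.masks)} allowed nontrivial bipartitions")
    scores = [_score_nested(x0, nested, qt) for x0, nested in cands]
    (x0, nested), best, n_tied = _pick_maximizer(cands, scores)
    warnings = []
    if n_tied > 1:
        warnings.append(f"{n_tied} topologies tie at the optimum; "
                        "returned the canonically smallest")
    return EstimatorResult(tree_from_nested(x0, nested), float(best),
                           "quartet-constrained",
                           f"{len(cands)} trees from {len(beta.masks)} "
                           "allowed bipartitions", warnings)


# ---------------------------------------------------------------------------
# allowed-bipartition sets
# ---------------------------------------------------------------------------

def beta_default(gene_trees: Sequence[dendropy.Tree],
                 full_taxa: Sequence[str]) -> BipartitionSet:
    """Bipartitions appearing in *complete* gene trees (a bipartition of an
    incomplete gene is not a bipartition of the full taxon set), plus the
    implicit trivial bipartitions."""
    beta = BipartitionSet(tuple(full_taxa))
    full = frozenset(beta.taxa)
    for gi, gt in enumerate(gene_trees):
        if frozenset(leaf_labels(gt)) != full:
            continue
        for m in bipartition_masks(gt, beta.taxa):
            beta.add(m, "gene-tree")
    return beta


def beta_mod1(gene_trees: Sequence[dendropy.Tree],
              full_taxa: Sequence[str]) -> BipartitionSet:
    """The default set plus, for every clade C of any gene tree (complete
    or not), the completed bipartition C | X \\ C."""
    beta = beta_default(gene_trees, full_taxa)
    index = {t: i for i, t in enumerate(beta.taxa)}
    n = beta.n
    full_mask = (1 << n) - 1
    for gt in gene_trees:
        labels = leaf_labels(gt)
        g_mask = sum(1 << index[l] for l in labels)
        if len(labels) < 3:
            clade_masks = []
        else:
            _, nested = nested_from_tree(gt)
            clade_masks = nested_clade_masks(nested, index)
        halves = set()
        for cm in clade_masks:
            halves.add(cm)
            halves.add(g_mask ^ cm)
        for l in labels:  # pendant-edge halves
            b = 1 << index[l]
            halves.add(b)
            halves.add(g_mask ^ b)
        for c in halves:
            if 2 <= popcount(c) <= n - 2:
                beta.add(c, "mod1-clade-complement")
    return beta


def beta_plus_phi(base: BipartitionSet,
                  phi_tree: dendropy.Tree) -> BipartitionSet:
    """Augment a bipartition set with those of a tree estimated by an
    auxiliary method Phi (idempotent if already covered)."""
    if tuple(sorted(leaf_labels(phi_tree))) != base.taxa:
        raise ValueError("phi tree leafset does not match the taxon set")
    out = base.union(BipartitionSet(base.taxa))
    for m in bipartition_masks(phi_tree, base.taxa):
        out.add(m, "phi-tree")
    return out


# ---------------------------------------------------------------------------
# triplet scoring and search
# ---------------------------------------------------------------------------

def triplet_score(candidate: dendropy.Tree, tt: TripletTable) -> int:
    """Number of gene rooted-triplet topologies the rooted candidate agrees
    with, summed over all 3-subsets."""
    from ._combinatorics import rooted_nested_from_tree

    labels = tuple(sorted(leaf_labels(candidate)))
    if labels != tt.taxa:
        raise ValueError("candidate leafset does not match the triplet table")
    if not candidate.is_rooted:
        raise ValueError("triplet scoring needs a rooted candidate")
    nested = rooted_nested_from_tree(candidate)
    return _score_rooted_nested(nested, tt)


def _score_rooted_nested(nested, tt: TripletTable) -> int:
    index = {t: i for i, t in enumerate(tt.taxa)}
    L = nested_lca_depths(nested, index, len(tt.taxa))
    opts = triplet_options(L, tt.subsets)
    return int(tt.counts[np.arange(len(tt.subsets)), opts].sum())


def triplet_search(tt: TripletTable,
                   taxa: Sequence[str] | None = None) -> EstimatorResult:
    """Maximize the rooted triplet score over all rooted binary topologies
    (enumeration; guarded to at most 7 taxa)."""
    taxa = tuple(sorted(taxa if taxa is not None else tt.taxa))
    if taxa != tt.taxa:
        raise ValueError("taxa do not match the triplet table")
    if len(taxa) > ROOTED_GUARD:
        raise ValueError(f"triplet search is limited to {ROOTED_GUARD} taxa")
    cands = enumerate_rooted_nested(list(taxa))
    scores = [_score_rooted_nested(c, tt) for c in cands]
    best = max(scores)
    tied = [c for c, s in zip(cands, scores) if s == best]

    def canon(node):
        if isinstance(node, str):
            return node
        a, b = canon(node[0]), canon(node[1])
        return f"({min(a, b)},{max(a, b)})"

    tied.sort(key=canon)
    warnings = []
    if len(tied) > 1:
        warnings.append(f"{len(tied)} rooted topologies tie at the optimum")
    return EstimatorResult(rooted_tree_from_nested(tied[0]), float(best),
                           "triplet", f"all {len(cands)} rooted topologies",
                           warnings)
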