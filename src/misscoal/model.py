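"""Model/Results front end for the estimators.

Each model class is constructed from a set of gene trees (the data) plus
estimator settings; ``fit()`` runs the summary-statistic computation and
the tree search and returns the :class:`~misscoal.estimators.EstimatorResult`
carrying the estimate, its objective value, a description of the search
space, and any warnings, with a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import dendropy

from .estimators import (
    BipartitionSet,
    EstimatorResult,
    beta_default,
    beta_mod1,
    beta_plus_phi,
    constrained_quartet_search,
    exact_quartet_search,
    nj_tree,
    triplet_search,
)
from .summaries import average_internode_matrix, quartet_table, triplet_table
from .trees import leaf_labels, root_tree

__all__ = [
    "DistanceSpeciesTree",
    "QuartetSpeciesTree",
    "TripletSpeciesTree",
]


def _union_taxa(gene_trees) -> tuple[str, ...]:
    taxa: set[str] = set()
    for gt in gene_trees:
        taxa.update(leaf_labels(gt))
    return tuple(sorted(taxa))


class DistanceSpeciesTree:
    """Distance-based species-tree estimation (NJst/ASTRID route): average
    internode distances, then neighbor joining."""

    def __init__(self, gene_trees: Sequence[dendropy.Tree],
                 taxa: Sequence[str] | None = None):
        self.gene_trees = list(gene_trees)
        self.taxa = tuple(sorted(taxa)) if taxa else _union_taxa(gene_trees)
        self.distance_summary = average_internode_matrix(
            self.gene_trees, self.taxa)

    def fit(self) -> EstimatorResult:
        res = nj_tree(self.distance_summary)
        res.n_genes = len(self.gene_trees)
        return res


class QuartetSpeciesTree:
    """Quartet-score maximization (the ASTRAL objective).

    ``beta`` selects the search space: ``"exact"`` enumerates everything,
    ``"default"`` allows bipartitions of complete gene trees only,
    ``"mod1"`` additionally completes every gene-tree clade against the
    full taxon set, or pass a prebuilt :class:`BipartitionSet`. With
    ``plus_phi=True`` the bipartitions of the distance-based (NJ) tree
    are added; pass ``phi_tree`` to use a different auxiliary estimate.
    """

    def __init__(self, gene_trees: Sequence[dendropy.Tree],
                 taxa: Sequence[str] | None = None,
                 beta: str | BipartitionSet = "mod1",
                 plus_phi: bool = False,
                 phi_tree: dendropy.Tree | None = None):
        self.gene_trees = list(gene_trees)
        self.taxa = tuple(sorted(taxa)) if taxa else _union_taxa(gene_trees)
        self.beta_mode = beta
        self.plus_phi = plus_phi or phi_tree is not None
        self.phi_tree = phi_tree
        self.quartet_table = quartet_table(self.gene_trees, self.taxa)

    def build_beta(self) -> BipartitionSet | None:
        if self.beta_mode == "exact":
            return None
        if isinstance(self.beta_mode, BipartitionSet):
            beta = self.beta_mode
        elif self.beta_mode == "default":
            beta = beta_default(self.gene_trees, self.taxa)
        elif self.beta_mode == "mod1":
            beta = beta_mod1(self.gene_trees, self.taxa)
        else:
            raise ValueError(f"unknown beta mode {self.beta_mode!r}")
        if self.plus_phi:
            phi = self.phi_tree
            if phi is None:
                phi = DistanceSpeciesTree(self.gene_trees, self.taxa).fit().tree
            beta = beta_plus_phi(beta, phi)
        return beta

    def fit(self) -> EstimatorResult:
        beta = self.build_beta()
        if beta is None:
            res = exact_quartet_search(self.quartet_table, self.taxa)
        else:
            res = constrained_quartet_search(self.quartet_table, beta)
        res.n_genes = len(self.gene_trees)
        return res


class TripletSpeciesTree:
    """Rooted-triplet-score maximization (3-tuple summary statistics).

    Unrooted gene trees are rooted at the outgroup when it is present in
    the gene, else at the midpoint of the longest leaf-to-leaf path.
    """

    def __init__(self, gene_trees: Sequence[dendropy.Tree],
                 taxa: Sequence[str] | None = None,
                 outgroup: str | None = None):
        self.taxa = tuple(sorted(taxa)) if taxa else _union_taxa(gene_trees)
        self.outgroup = outgroup
        rooted = []
        for gt in gene_trees:
            if gt.is_rooted and outgroup is None:
                rooted.append(gt)
            elif outgroup is not None and outgroup in leaf_labels(gt):
                rooted.append(root_tree(gt, outgroup))
            else:
                rooted.append(root_tree(gt))
        self.gene_trees = rooted
        self.triplet_table = triplet_table(self.gene_trees, self.taxa)

    def fit(self) -> EstimatorResult:
        res = triplet_search(self.triplet_table, self.taxa)
        res.n_genes = len(self.gene_trees)
        return res
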