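"""Evaluation statistics for simulation studies.

* normalized Robinson-Foulds species-tree error;
* AD, the mean normalized RF distance between the (restricted) true
  species tree and the true gene trees — a proxy for the level of
  incomplete lineage sorting;
* GTEE, the mean normalized RF distance between true and estimated gene
  trees;
* the Euclidean norm of the upper-triangle difference between the
  unit-branch-length species-tree internode matrix and an estimated
  average internode matrix;
* the four-point condition check on a distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from ._combinatorics import edge_count_distances
from .summaries import DistanceSummary
from .trees import leaf_labels, restrict, rf_distance

__all__ = [
    "MetricsRecord",
    "species_tree_error",
    "average_distance_AD",
    "gtee",
    "true_internode_matrix",
    "matrix_error_norm",
    "four_point_check",
]

RESULT_COLUMNS = [
    "replicate", "method", "model", "m", "rf_error", "ad", "gtee",
    "matrix_error", "warnings",
]


@dataclass
class MetricsRecord:
    """One evaluated (replicate, deletion model, gene count, method) cell."""

    replicate: int
    method: str
    model: str
    m: int
    rf_error: float | None = None
    ad: float | None = None
    gtee: float | None = None
    matrix_error: float | None = None
    warnings: str = ""

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in RESULT_COLUMNS}


def species_tree_error(estimated: dendropy.Tree,
                       true_tree: dendropy.Tree) -> float:
    """Normalized RF error rate between the unrooted shapes."""
    return rf_distance(estimated, true_tree, normalized=True)


def average_distance_AD(st: dendropy.Tree,
                        gene_trees: Sequence[dendropy.Tree]) -> float:
    """Mean normalized RF between the species tree (restricted to each
    gene's leafset) and the gene trees; genes with < 4 taxa are skipped."""
    vals = []
    st_leaves = frozenset(leaf_labels(st))
    for gt in gene_trees:
        leaves = frozenset(leaf_labels(gt))
        if len(leaves) < 4:
            continue
        if not leaves <= st_leaves:
            raise ValueError("gene tree has taxa outside the species tree")
        ref = st if leaves == st_leaves else restrict(st, leaves)
        vals.append(rf_distance(ref, gt, normalized=True))
    if not vals:
        raise ValueError("no gene tree with >= 4 taxa")
    return float(np.mean(vals))


def gtee(true_gts: Sequence[dendropy.Tree],
         est_gts: Sequence[dendropy.Tree]) -> float:
    """Mean normalized RF between paired true and estimated gene trees."""
    if len(true_gts) != len(est_gts):
        raise ValueError("gene tree lists have different lengths")
    vals = []
    for t, e in zip(true_gts, est_gts):
        if frozenset(leaf_labels(t)) != frozenset(leaf_labels(e)):
            raise ValueError("paired gene trees have different leafsets")
        if len(leaf_labels(t)) < 4:
            continue
        vals.append(rf_distance(t, e, normalized=True))
    if not vals:
        raise ValueError("no gene tree with >= 4 taxa")
    return float(np.mean(vals))


def true_internode_matrix(st: dendropy.Tree) -> DistanceSummary:
    """Path edge counts on the species tree's unrooted shape — the target
    additive matrix for unit branch lengths."""
    labels, D = edge_count_distances(st)
    counts = np.ones_like(D)
    np.fill_diagonal(counts, 0)
    return DistanceSummary(labels, D.astype(float), counts)


def matrix_error_norm(d_true: DistanceSummary | np.ndarray,
                      d_est: DistanceSummary) -> float:
    """Euclidean (Frobenius) norm of the strictly-upper-triangle entrywise
    difference between the true and estimated internode matrices."""
    if d_est.undefined_pairs():
        raise ValueError(
            f"estimated matrix has undefined pairs: {d_est.undefined_pairs()}")
    est = d_est.average
    if isinstance(d_true, DistanceSummary):
        if d_true.taxa != d_est.taxa:
            raise ValueError("taxon orders differ")
        tru = d_true.average
    else:
        tru = np.asarray(d_true, dtype=float)
        if tru.shape != est.shape:
            raise ValueError("matrix shapes differ")
    iu = np.triu_indices(len(est), k=1)
    return float(np.linalg.norm(tru[iu] - est[iu]))


def four_point_check(matrix: np.ndarray, quartet: Sequence[int],
                     tolerance: float = 1e-9):
    """Check the four-point condition for one index quartet.

    Returns ``(holds, split)`` where ``holds`` means |median - maximum| of
    the three pairwise sums is within ``tolerance`` and ``split`` is the
    pairing achieving the minimum sum — ``((i, j), (k, l))`` index pairs,
    or the string ``"tied"`` when all three sums are within tolerance of
    each other.
    """
    i, j, k, l = quartet
    D = np.asarray(matrix, dtype=float)
    sums = np.array([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
    order = np.argsort(sums)
    holds = bool(abs(sums[order[1]] - sums[order[2]]) <= tolerance)
    if sums.max() - sums.min() <= tolerance:
        return holds, "tied"
    pairings = [((i, j), (k, l)), ((i, k), (j, l)), ((i, l), (j, k))]
    return holds, pairings[int(order[0])]
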