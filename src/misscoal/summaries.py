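"""Tuple-based summary statistics under the natural extension.

Each statistic on an l-subset of taxa is computed from exactly the genes
that contain all l taxa of the subset:

* 2-tuple: average topological internode distances between pairs of taxa
  (the matrix neighbor joining is applied to);
* 3-tuple: per-3-subset frequencies of the three rooted triplet
  topologies (requires rooted gene trees);
* 4-tuple: per-4-subset frequencies of the three unrooted quartet
  topologies (the quartet-score objective's input).

The internode distance between two leaves is the number of edges on the
path joining them in the homeomorphically reduced *unrooted* tree (1 for a
two-leaf tree, 2 within a cherry of a quartet). The quartet and triplet
tables are invariant to deleting taxa outside the subset of interest
("Type 1" statistics); the average-distance matrix is not ("Type 2"),
because removing a taxon can shorten the reduced path between two others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from ._combinatorics import (
    edge_count_distances,
    lca_depth_matrix,
    quartet_options,
    subset_index,
    triplet_options,
)
from .trees import leaf_labels

__all__ = [
    "DistanceSummary",
    "QuartetTable",
    "TripletTable",
    "internode_distance",
    "average_internode_matrix",
    "quartet_table",
    "triplet_table",
    "statistic_count",
]


def internode_distance(tree: dendropy.Tree, i: str, j: str) -> int:
    """Edge count on the i-j path of the reduced unrooted tree."""
    if i == j:
        raise ValueError("taxa must be distinct")
    labels, D = edge_count_distances(tree)
    try:
        a, b = labels.index(i), labels.index(j)
    except ValueError as exc:
        raise ValueError(f"taxon not in tree: {exc}") from None
    return int(D[a, b])


@dataclass
class DistanceSummary:
    """Summed internode distances, co-occurrence counts and their ratio.

    ``average[i, j]`` is defined only where ``counts[i, j] > 0``; the
    boolean ``defined`` matrix flags usable entries (diagonal excluded).
    """

    taxa: tuple[str, ...]
    sums: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def average(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(self.counts > 0, self.sums / np.maximum(self.counts, 1),
                           np.nan)
        np.fill_diagonal(avg, 0.0)
        return avg

    @property
    def defined(self) -> np.ndarray:
        d = self.counts > 0
        np.fill_diagonal(d, True)
        return d

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        und = ~self.defined
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if und[i, j]:
                    out.append((self.taxa[i], self.taxa[j]))
        return out

    def to_phylip(self, path) -> None:
        """Square PHYLIP-style distance matrix plus a parallel counts file
        (``<path>.counts``)."""
        avg = self.average
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, t in enumerate(self.taxa):
                row = " ".join("NA" if np.isnan(v) else f"{v:.6f}"
                               for v in avg[i])
                fh.write(f"{t} {row}\n")
        with open(str(path) + ".counts", "w") as fh:
            fh.write(f"{self.n}\n")
            for i, t in enumerate(self.taxa):
                fh.write(f"{t} " + " ".join(str(int(c)) for c in
                                            self.counts[i]) + "\n")


def average_internode_matrix(gene_trees: Sequence[dendropy.Tree],
                             taxa: Sequence[str] | None = None) -> DistanceSummary:
    """Average internode distances, each pair averaged over exactly the
    genes containing both taxa (rooted inputs are unrooted first)."""
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    if taxa is None:
        all_taxa: set[str] = set()
        for gt in gene_trees:
            all_taxa.update(leaf_labels(gt))
        taxa = sorted(all_taxa)
    taxa = tuple(sorted(taxa))
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    sums = np.zeros((n, n), dtype=np.float64)
    counts = np.zeros((n, n), dtype=np.int64)
    for gt in gene_trees:
        labels, D = edge_count_distances(gt)
        keep = [k for k, l in enumerate(labels) if l in index]
        if len(keep) < 2:
            continue
        if len(keep) < len(labels):
            # distances stay measured on the whole gene tree: the 2-tuple
            # statistic is Type 2, sensitive to taxa outside the pair
            D = D[np.ix_(keep, keep)]
            labels = [labels[k] for k in keep]
        ids = np.array([index[l] for l in labels])
        sums[np.ix_(ids, ids)] += D
        ones = np.ones((len(ids), len(ids)), dtype=np.int64)
        np.fill_diagonal(ones, 0)
        counts[np.ix_(ids, ids)] += ones
    return DistanceSummary(taxa, sums, counts)


@dataclass
class QuartetTable:
    """Per-4-subset counts of the three unrooted quartet topologies.

    Subsets are sorted index quadruples over sorted ``taxa``; for subset
    (i, j, k, l) with i < j < k < l, column 0 counts ij|kl, column 1
    ik|jl, and column 2 il|jk.
    """

    taxa: tuple[str, ...]
    subsets: np.ndarray  # (S, 4) sorted index combos
    counts: np.ndarray   # (S, 3)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset_counts(self, quartet: Sequence[str]) -> np.ndarray:
        """Counts (3,) for one 4-subset given as taxon labels."""
        idx = tuple(sorted(self.taxa.index(t) for t in quartet))
        pos = np.flatnonzero((self.subsets == idx).all(axis=1))
        if len(pos) != 1:
            raise KeyError(f"quartet {quartet} not in table")
        return self.counts[pos[0]]

    def to_tsv(self, path) -> None:
        rows = []
        for (i, j, k, l), c in zip(self.subsets, self.counts):
            rows.append({
                "subset": ",".join(self.taxa[x] for x in (i, j, k, l)),
                "n_12_34": int(c[0]), "n_13_24": int(c[1]),
                "n_14_23": int(c[2]),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def quartet_table(gene_trees: Sequence[dendropy.Tree],
                  taxa: Sequence[str]) -> QuartetTable:
    """Quartet topology frequencies; a gene contributes to a 4-subset only
    when it contains all four taxa (the natural extension)."""
    taxa = tuple(sorted(taxa))
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    subs = subset_index(n, 4)
    counts = np.zeros((len(subs), 3), dtype=np.int64)
    if len(subs) == 0:
        return QuartetTable(taxa, subs, counts)
    for gt in gene_trees:
        labels, Dg = edge_count_distances(gt)
        ids = [index[l] for l in labels if l in index]
        if len(ids) < 4 or len(ids) < len(labels):
            keep = [x for x, l in enumerate(labels) if l in index]
            if len(keep) < 4:
                continue
            Dg = Dg[np.ix_(keep, keep)]
            ids = [index[labels[x]] for x in keep]
        D = np.zeros((n, n), dtype=np.int64)
        ids = np.array(ids)
        D[np.ix_(ids, ids)] = Dg
        present = np.zeros(n, dtype=bool)
        present[ids] = True
        valid = present[subs].all(axis=1)
        if not valid.any():
            continue
        opts = quartet_options(D, subs[valid])
        np.add.at(counts, (np.flatnonzero(valid), opts), 1)
    return QuartetTable(taxa, subs, counts)


@dataclass
class TripletTable:
    """Per-3-subset counts of the three rooted triplet topologies.

    For subset (i, j, k) with i < j < k, column 0 counts ((i,j),k),
    column 1 ((i,k),j), and column 2 ((j,k),i).
    """

    taxa: tuple[str, ...]
    subsets: np.ndarray  # (S, 3)
    counts: np.ndarray   # (S, 3)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        rows = []
        for (i, j, k), c in zip(self.subsets, self.counts):
            rows.append({
                "subset": ",".join(self.taxa[x] for x in (i, j, k)),
                "n_12_3": int(c[0]), "n_13_2": int(c[1]), "n_23_1": int(c[2]),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def triplet_table(rooted_gene_trees: Sequence[dendropy.Tree],
                  taxa: Sequence[str]) -> TripletTable:
    """Rooted triplet frequencies under the natural extension; unrooted
    input is rejected (root the gene trees first)."""
    taxa = tuple(sorted(taxa))
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    subs = subset_index(n, 3)
    counts = np.zeros((len(subs), 3), dtype=np.int64)
    for gt in rooted_gene_trees:
        if not gt.is_rooted:
            raise ValueError(
                "triplet statistics need rooted gene trees; root them first "
                "(e.g. with trees.root_tree)")
        labels = leaf_labels(gt)
        ids = np.array([index[l] for l in labels if l in index])
        if len(ids) < 3:
            continue
        # leaves outside the reference set get scratch indices past n; the
        # top-left n-by-n block is all the subset machinery reads
        ext_index = dict(index)
        extra = n
        for l in labels:
            if l not in ext_index:
                ext_index[l] = extra
                extra += 1
        Lg = lca_depth_matrix(gt, ext_index, extra)[:n, :n]
        present = np.zeros(n, dtype=bool)
        present[ids] = True
        valid = present[subs].all(axis=1)
        if not valid.any():
            continue
        opts = triplet_options(Lg, subs[valid])
        np.add.at(counts, (np.flatnonzero(valid), opts), 1)
    return TripletTable(taxa, subs, counts)


def statistic_count(ell: int, n: int) -> int:
    """Number of summary statistics an l-tuple method computes on n taxa:
    C(n,2) pairwise distances, 3*C(n,3) rooted triplets, or 3*C(n,4)
    unrooted quartets."""
    if n < ell:
        raise ValueError("n must be at least ell")
    if ell == 2:
        return math.comb(n, 2)
    if ell == 3:
        return 3 * math.comb(n, 3)
    if ell == 4:
        return 3 * math.comb(n, 4)
    raise ValueError("ell must be 2, 3, or 4")
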