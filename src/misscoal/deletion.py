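"""Taxon-deletion models for gene trees.

Masks are m-by-n 0/1 presence matrices (genes by taxa), generated
independently of the gene trees themselves. Models:

* i.i.d. deletion: each taxon is missing from each gene independently
  with probability ``p_miss``;
* clade-based deletion: for each gene one rooted clade of the species
  tree is drawn uniformly from the eligible sizes, and all taxa outside
  it are deleted (a pure gene-birth pattern);
* mixtures of complete and clade-deleted genes;
* exactly-k random subsets: each gene keeps a uniformly random k-subset
  of taxa (a full-subset-coverage model used in non-identifiability
  demonstrations);
* an adversary filter that retains a gene if and only if its topology
  equals a target tree — deletion then *depends* on the gene tree, which
  destroys identifiability of the species tree.

``p_miss`` is always the probability that a taxon is *missing*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import dendropy
import numpy as np
import pandas as pd

from .trees import leaf_labels, restrict, rf_distance

__all__ = [
    "DeletionMask",
    "ModelSpec",
    "miid_mask",
    "clade_mask",
    "mixture_mask",
    "ksubset_mask",
    "adversary_filter",
    "apply_mask",
    "MaskedGenes",
    "species_tree_clades",
]


@dataclass
class DeletionMask:
    """Per-gene, per-taxon presence indicators (1 = present)."""

    taxa: tuple[str, ...]
    matrix: np.ndarray  # (m, n) of 0/1
    model: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.taxa):
            raise ValueError("mask matrix shape does not match taxa")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def missing_fraction(self) -> float:
        return float(1.0 - self.matrix.mean())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=list(self.taxa)).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, model: str = "file") -> "DeletionMask":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df.columns), df.to_numpy(), model)


@dataclass
class ModelSpec:
    """Declarative description of a deletion model for experiment configs."""

    name: str  # miid | clade | ksubset | mixture | adversary | none
    p_miss: float = 0.0
    size_min: int = 2
    size_max: int | None = None
    k: int | None = None
    fraction_incomplete: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.name not in {"miid", "clade", "ksubset", "mixture",
                             "adversary", "none"}:
            raise ValueError(f"unknown deletion model {self.name!r}")
        if not 0.0 <= self.p_miss < 1.0:
            raise ValueError("p_miss must be in [0, 1)")
        if not 0.0 <= self.fraction_incomplete <= 1.0:
            raise ValueError("fraction_incomplete must be in [0, 1]")
        if self.label is None:
            self.label = self._default_label()

    def _default_label(self) -> str:
        if self.name == "miid":
            return f"miid(p={self.p_miss:g})"
        if self.name == "clade":
            return f"clade({self.size_min}-{self.size_max})"
        if self.name == "mixture":
            return (f"mixture(f={self.fraction_incomplete:g},"
                    f"{self.size_min}-{self.size_max})")
        if self.name == "ksubset":
            return f"ksubset(k={self.k})"
        return self.name


def miid_mask(m: int, n: int, p_miss: float, seed: int,
              taxa: Iterable[str] | None = None) -> DeletionMask:
    """Independent Bernoulli deletion: each entry missing w.p. ``p_miss``."""
    if not 0.0 <= p_miss < 1.0:
        raise ValueError("p_miss must be in [0, 1) (1 would leave no data)")
    rng = np.random.default_rng(seed)
    mat = (rng.random((m, n)) >= p_miss).astype(np.int8)
    taxa = tuple(taxa) if taxa is not None else tuple(
        f"x{i}" for i in range(n))
    if len(taxa) != n:
        raise ValueError("taxa must have length n")
    return DeletionMask(taxa, mat, f"miid(p={p_miss:g})", seed)


def species_tree_clades(st: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets of all internal nodes of a rooted species tree (the rooted
    clades of size >= 2, full set included last)."""
    clades = []
    for node in st.postorder_node_iter():
        if not node.is_leaf():
            clades.append(frozenset(
                lf.taxon.label for lf in node.leaf_iter()))
    return clades


def _eligible_clades(st, size_min, size_max):
    n = len(leaf_labels(st))
    if size_max is None:
        size_max = n - 1
    clades = [c for c in species_tree_clades(st)
              if size_min <= len(c) <= size_max]
    if size_max < n:
        clades = [c for c in clades if len(c) < n]
    if not clades:
        sizes = sorted({len(c) for c in species_tree_clades(st)})
        raise ValueError(
            f"no clade of size in [{size_min}, {size_max}]; "
            f"available clade sizes: {sizes}")
    return sorted(clades, key=lambda c: (len(c), sorted(c)))


def clade_mask(st: dendropy.Tree, m: int, size_min: int, size_max: int,
               seed: int) -> DeletionMask:
    """Per gene, keep one uniformly chosen eligible species-tree clade and
    delete everything outside it."""
    taxa = tuple(sorted(leaf_labels(st)))
    clades = _eligible_clades(st, size_min, size_max)
    rng = np.random.default_rng(seed)
    mat = np.zeros((m, len(taxa)), dtype=np.int8)
    idx = {t: i for i, t in enumerate(taxa)}
    choices = rng.integers(len(clades), size=m)
    for g, c in enumerate(choices):
        for t in clades[c]:
            mat[g, idx[t]] = 1
    return DeletionMask(taxa, mat, f"clade({size_min}-{size_max})", seed)


def mixture_mask(st: dendropy.Tree, m: int, fraction_incomplete: float,
                 size_min: int, size_max: int, seed: int) -> DeletionMask:
    """A uniformly chosen ``floor(fraction_incomplete * m)``-subset of genes
    gets clade-based deletion; the rest stay complete."""
    if not 0.0 <= fraction_incomplete <= 1.0:
        raise ValueError("fraction_incomplete must be in [0, 1]")
    taxa = tuple(sorted(leaf_labels(st)))
    rng = np.random.default_rng(seed)
    n_inc = int(np.floor(fraction_incomplete * m))
    incomplete = rng.choice(m, size=n_inc, replace=False)
    mat = np.ones((m, len(taxa)), dtype=np.int8)
    if n_inc:
        sub = clade_mask(st, n_inc, size_min, size_max,
                         int(rng.integers(2 ** 31)))
        mat[np.sort(incomplete)] = sub.matrix
    return DeletionMask(
        taxa, mat,
        f"mixture(f={fraction_incomplete:g},{size_min}-{size_max})", seed)


def ksubset_mask(m: int, n: int, k: int, seed: int,
                 taxa: Iterable[str] | None = None) -> DeletionMask:
    """Each gene keeps an independent uniformly random k-subset of taxa."""
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    mat = np.zeros((m, n), dtype=np.int8)
    for g in range(m):
        mat[g, rng.choice(n, size=k, replace=False)] = 1
    taxa = tuple(taxa) if taxa is not None else tuple(
        f"x{i}" for i in range(n))
    if len(taxa) != n:
        raise ValueError("taxa must have length n")
    return DeletionMask(taxa, mat, f"ksubset(k={k})", seed)


def adversary_filter(gene_trees: list[dendropy.Tree],
                     target: dendropy.Tree) -> list[dendropy.Tree]:
    """Retain exactly the genes whose unrooted topology equals ``target``
    (all taxa present); all other genes are removed entirely."""
    full = frozenset(leaf_labels(target))
    kept = []
    for gt in gene_trees:
        if frozenset(leaf_labels(gt)) != full:
            continue
        if rf_distance(gt, target) == 0:
            kept.append(gt)
    if not kept:
        warnings.warn("adversary filter removed every gene", stacklevel=2)
    return kept


class MaskedGenes(NamedTuple):
    trees: list[dendropy.Tree]
    n_dropped: int


def apply_mask(gene_trees: list[dendropy.Tree],
               mask: DeletionMask) -> MaskedGenes:
    """Restrict gene ``i`` to the taxa its mask row retains; genes left with
    fewer than 2 taxa are dropped and counted."""
    if len(gene_trees) != mask.n_genes:
        raise ValueError(
            f"mask has {mask.n_genes} rows but {len(gene_trees)} gene trees")
    out: list[dendropy.Tree] = []
    dropped = 0
    for gt, row in zip(gene_trees, mask.matrix):
        present = {t for t, y in zip(mask.taxa, row) if y}
        keep = present & frozenset(leaf_labels(gt))
        if len(keep) < 2:
            dropped += 1
            continue
        if keep == frozenset(leaf_labels(gt)):
            out.append(gt)
        else:
            out.append(restrict(gt, keep))
    return MaskedGenes(out, dropped)
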