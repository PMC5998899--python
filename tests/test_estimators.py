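"""Estimators: NJ, quartet-score search spaces, triplet search.

The brute-force quartet oracle used here determines induced quartet
topologies through bipartition separation (frozenset logic), a different
route from the path-distance argmin the implementation uses.
"""

import itertools
import math

import dendropy
import numpy as np
import pytest

import misscoal as mc
from misscoal._combinatorics import enumerate_rooted_nested, enumerate_unrooted
from misscoal.estimators import (
    SearchSpaceEmptyError,
    UndefinedDistanceError,
    _score_rooted_nested,
    tree_from_nested,
)
from misscoal.summaries import DistanceSummary
from misscoal.trees import Bipartition, bipartitions, leaf_labels

from conftest import random_unrooted_tree


def brute_quartet_topology(bips, quartet):
    """Oracle: the pairing some bipartition separates 2|2 (in a binary
    tree the resolving internal edge always exists)."""
    for side1, _ in bips:
        a = quartet & side1
        if len(a) == 2:
            return frozenset((a, quartet - a))
    raise AssertionError("binary tree must induce a resolved quartet")


def brute_quartet_score(candidate, gene_trees):
    """Oracle: direct double loop over genes and 4-subsets, topologies by
    bipartition separation."""
    taxa = sorted(leaf_labels(candidate))
    cand_b = [(bp.side1, bp.side2) for bp in bipartitions(candidate)]
    gene_b = [([(bp.side1, bp.side2) for bp in bipartitions(gt)],
               frozenset(leaf_labels(gt))) for gt in gene_trees]
    score = 0
    for q in itertools.combinations(taxa, 4):
        qs = frozenset(q)
        cand_top = brute_quartet_topology(cand_b, qs)
        for gb, gleaves in gene_b:
            if qs <= gleaves and brute_quartet_topology(gb, qs) == cand_top:
                score += 1
    return score


def brute_best_quartet_score(taxa, gene_trees):
    """Oracle: maximum brute-force score over every unrooted topology."""
    taxa = sorted(taxa)
    subsets = [frozenset(q) for q in itertools.combinations(taxa, 4)]
    gene_b = [([(bp.side1, bp.side2) for bp in bipartitions(gt)],
               frozenset(leaf_labels(gt))) for gt in gene_trees]
    gene_tops = []
    for gb, gleaves in gene_b:
        tops = {}
        for qs in subsets:
            if qs <= gleaves:
                tops[qs] = brute_quartet_topology(gb, qs)
        gene_tops.append(tops)
    best = -1
    for x0, nested in enumerate_unrooted(taxa):
        cand = tree_from_nested(x0, nested)
        cand_b = [(bp.side1, bp.side2) for bp in bipartitions(cand)]
        score = 0
        for qs in subsets:
            top = brute_quartet_topology(cand_b, qs)
            score += sum(1 for tops in gene_tops if tops.get(qs) == top)
        best = max(best, score)
    return best


def _weighted_additive_summary(tree):
    """DistanceSummary holding exact weighted path lengths of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = tuple(sorted(leaf_labels(tree)))
    tax_of = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(
                    tax_of[a], tax_of[b])
    counts = np.ones((n, n), dtype=np.int64)
    np.fill_diagonal(counts, 0)
    return DistanceSummary(taxa, D, counts)


class TestNJ:
    def test_unit_quartet_matrix(self):
        D = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                      [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float)
        counts = np.ones((4, 4), dtype=np.int64)
        np.fill_diagonal(counts, 0)
        ds = DistanceSummary(("a", "b", "c", "d"), D, counts)
        res = mc.nj_tree(ds)
        assert bipartitions(res.tree) == {
            Bipartition.of({"a", "b"}, {"c", "d"})}

    def test_atteson_robustness(self):
        """Perturbations below half the minimum edge weight do not change
        the recovered topology."""
        rng = np.random.default_rng(0)
        base = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                         [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float)
        counts = np.ones((4, 4), dtype=np.int64)
        np.fill_diagonal(counts, 0)
        for _ in range(20):
            eps = rng.uniform(-0.49, 0.49, size=(4, 4))
            eps = (eps + eps.T) / 2
            np.fill_diagonal(eps, 0)
            ds = DistanceSummary(("a", "b", "c", "d"), base + eps, counts)
            res = mc.nj_tree(ds)
            assert bipartitions(res.tree) == {
                Bipartition.of({"a", "b"}, {"c", "d"})}

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovery(self, seed):
        """NJ on exact weighted path lengths of random 8-leaf trees with
        edge weights in [0.5, 2] recovers the topology."""
        rng = np.random.default_rng(seed)
        tree = random_unrooted_tree(8, seed)
        for e in tree.preorder_edge_iter():
            if e.tail_node is not None:
                e.length = rng.uniform(0.5, 2.0)
        ds = _weighted_additive_summary(tree)
        res = mc.nj_tree(ds)
        assert mc.rf_distance(res.tree, tree) == 0

    def test_undefined_pair_error(self):
        g1 = mc.parse_newick("(a,b,(c,d));")
        g2 = mc.parse_newick("(a,b,(c,e));")
        ds = mc.average_internode_matrix([g1, g2])
        with pytest.raises(UndefinedDistanceError, match="more genes|add genes"):
            mc.nj_tree(ds)


class TestQuartetScore:
    def test_single_identical_gene(self):
        t = random_unrooted_tree(5, 1)
        qt = mc.quartet_table([t], sorted(leaf_labels(t)))
        assert mc.quartet_score(t, qt) == math.comb(5, 4)

    def test_rival_topology_scores_zero(self):
        gene = mc.parse_newick("(a,c,(b,d));")
        cand = mc.parse_newick("(a,b,(c,d));")
        qt = mc.quartet_table([gene] * 4, "abcd")
        assert mc.quartet_score(cand, qt) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        st = mc.yule_species_tree(6, 1.0, seed)
        genes = mc.simulate_gene_trees(st, 10, seed + 50)
        taxa = sorted(leaf_labels(st))
        cand = random_unrooted_tree(6, seed + 99)
        cand = _relabel(cand, taxa)
        qt = mc.quartet_table(genes, taxa)
        assert mc.quartet_score(cand, qt) == brute_quartet_score(cand, genes)

    def test_conservation(self):
        t = random_unrooted_tree(6, 3)
        m = 7
        qt = mc.quartet_table([t] * m, sorted(leaf_labels(t)))
        assert mc.quartet_score(t, qt) == m * math.comb(6, 4)

    def test_leafset_mismatch(self):
        qt = mc.quartet_table([mc.parse_newick("(a,b,(c,d));")], "abcd")
        with pytest.raises(ValueError):
            mc.quartet_score(mc.parse_newick("(a,b,(c,e));"), qt)


def _relabel(tree, labels):
    old = sorted(leaf_labels(tree))
    mapping = dict(zip(old, labels))
    ns = dendropy.TaxonNamespace(sorted(labels))
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.get_taxon(mapping[leaf.taxon.label])
    tree.taxon_namespace = ns
    return tree


class TestExactSearch:
    def test_majority_quartet(self):
        genes = [mc.parse_newick("(a,b,(c,d));")] * 3 + \
                [mc.parse_newick("(a,c,(b,d));")]
        qt = mc.quartet_table(genes, "abcd")
        res = mc.exact_quartet_search(qt)
        assert res.objective == 3
        assert bipartitions(res.tree) == {
            Bipartition.of({"a", "b"}, {"c", "d"})}

    def test_recovers_generating_tree(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 50, 5)
        taxa = sorted(leaf_labels(six_taxon_tall))
        res = mc.exact_quartet_search(mc.quartet_table(genes, taxa))
        assert mc.rf_distance(res.tree, six_taxon_tall) == 0

    def test_objective_is_global_max(self):
        st = mc.yule_species_tree(6, 0.8, 7)
        genes = mc.simulate_gene_trees(st, 8, 8)
        taxa = sorted(leaf_labels(st))
        qt = mc.quartet_table(genes, taxa)
        res = mc.exact_quartet_search(qt)
        assert res.objective == brute_best_quartet_score(taxa, genes)

    def test_guard(self):
        taxa = [f"x{i}" for i in range(10)]
        qt = mc.quartet_table([], taxa)
        with pytest.raises(ValueError, match="constrained"):
            mc.exact_quartet_search(qt)


class TestBetaSets:
    def test_default_complete_genes(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 5, 9)
        taxa = sorted(leaf_labels(six_taxon_tall))
        beta = mc.beta_default(genes, taxa)
        expect = set()
        for g in genes:
            expect |= bipartitions(g)
        assert beta.bipartitions() == expect

    def test_default_ignores_incomplete(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 5, 10)
        taxa = sorted(leaf_labels(six_taxon_tall))
        incomplete = [mc.restrict(g, taxa[:5]) for g in genes]
        beta = mc.beta_default(incomplete, taxa)
        assert beta.masks == set()

    def test_mod1_completes_clades(self):
        gene = mc.parse_newick("(a,b,(c,d));")
        taxa = list("abcdef")
        beta = mc.beta_mod1([gene], taxa)
        full = frozenset(taxa)
        assert Bipartition.of({"a", "b"}, full - {"a", "b"}) in beta
        assert Bipartition.of({"c", "d"}, full - {"c", "d"}) in beta
        # pendant-complement halves of the gene are clades too
        assert Bipartition.of({"b", "c", "d"}, full - {"b", "c", "d"}) in beta

    def test_mod1_superset_of_default(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 10, 11)
        taxa = sorted(leaf_labels(six_taxon_tall))
        d = mc.beta_default(genes, taxa)
        m1 = mc.beta_mod1(genes, taxa)
        assert d.masks <= m1.masks

    def test_plus_phi_contains_and_idempotent(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 10, 12)
        taxa = sorted(leaf_labels(six_taxon_tall))
        base = mc.beta_default(genes, taxa)
        phi = random_unrooted_tree(6, 5)
        phi = _relabel(phi, taxa)
        aug = mc.beta_plus_phi(base, phi)
        for bp in bipartitions(phi):
            assert bp in aug
        again = mc.beta_plus_phi(aug, phi)
        assert again.masks == aug.masks

    def test_plus_phi_leafset_mismatch(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 3, 13)
        taxa = sorted(leaf_labels(six_taxon_tall))
        base = mc.beta_default(genes, taxa)
        with pytest.raises(ValueError):
            mc.beta_plus_phi(base, mc.parse_newick("(a,b,(c,d));"))


class TestConstrainedSearch:
    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2)])
    def test_full_beta_equals_exact(self, n, seed):
        st = mc.yule_species_tree(n, 1.0, seed)
        genes = mc.simulate_gene_trees(st, 12, seed + 20)
        taxa = tuple(sorted(leaf_labels(st)))
        qt = mc.quartet_table(genes, taxa)
        beta = mc.BipartitionSet(taxa)
        for mask in range(1, 2 ** n - 1):
            if 2 <= bin(mask).count("1") <= n - 2:
                beta.add(mask, "all")
        res_c = mc.constrained_quartet_search(qt, beta)
        res_e = mc.exact_quartet_search(qt)
        assert res_c.objective == res_e.objective

    def test_singleton_space_returns_that_tree(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 20, 21)
        taxa = tuple(sorted(leaf_labels(six_taxon_tall)))
        target = _relabel(random_unrooted_tree(6, 77), taxa)
        beta = mc.BipartitionSet(taxa)
        for bp in bipartitions(target):
            beta.add_bipartition(bp, "target")
        res = mc.constrained_quartet_search(mc.quartet_table(genes, taxa),
                                            beta)
        assert mc.rf_distance(res.tree, target) == 0

    def test_trivial_only_is_empty(self):
        taxa = ("a", "b", "c", "d", "e")
        qt = mc.quartet_table([], taxa)
        with pytest.raises(SearchSpaceEmptyError):
            mc.constrained_quartet_search(qt, mc.BipartitionSet(taxa))

    def test_monotone_in_beta(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 30, 22)
        incomplete_taxa = sorted(leaf_labels(six_taxon_tall))
        taxa = tuple(incomplete_taxa)
        qt = mc.quartet_table(genes, taxa)
        base = mc.beta_mod1(genes[:5], taxa)
        bigger = mc.beta_plus_phi(
            base, mc.DistanceSpeciesTree(genes, taxa).fit().tree)
        try:
            obj_base = mc.constrained_quartet_search(qt, base).objective
        except SearchSpaceEmptyError:
            obj_base = -1
        obj_big = mc.constrained_quartet_search(qt, bigger).objective
        assert obj_big >= obj_base


class TestTripletSearch:
    def test_all_genes_identical(self):
        t = mc.parse_newick("(((a,b),c),(d,e));")
        t.is_rooted = True
        tt = mc.triplet_table([t] * 10, "abcde")
        res = mc.triplet_search(tt)
        assert res.tree.is_rooted
        assert mc.rf_distance(res.tree, t) == 0
        assert res.objective == 10 * math.comb(5, 3)

    def test_majority_triplet(self):
        g1 = mc.parse_newick("((a,b),c);")
        g2 = mc.parse_newick("((a,c),b);")
        g3 = mc.parse_newick("((b,c),a);")
        for g in (g1, g2, g3):
            g.is_rooted = True
        tt = mc.triplet_table([g1] * 5 + [g2] * 2 + [g3], "abc")
        res = mc.triplet_search(tt)
        assert res.objective == 5

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive(self, seed):
        st = mc.yule_species_tree(5, 0.8, seed + 30)
        genes = mc.simulate_gene_trees(st, 15, seed + 40)
        taxa = tuple(sorted(leaf_labels(st)))
        tt = mc.triplet_table(genes, taxa)
        res = mc.triplet_search(tt)
        best = max(_score_rooted_nested(c, tt)
                   for c in enumerate_rooted_nested(list(taxa)))
        assert res.objective == best

    def test_guard(self):
        taxa = [f"x{i}" for i in range(8)]
        tt = mc.triplet_table([], taxa)
        with pytest.raises(ValueError, match="limited"):
            mc.triplet_search(tt)


def test_result_summary(six_taxon_tall):
    genes = mc.simulate_gene_trees(six_taxon_tall, 10, 1)
    res = mc.DistanceSpeciesTree(genes).fit()
    text = res.summary()
    assert "nj" in text and "genes:" in text and "tree:" in text


def test_beta_text_output(tmp_path, six_taxon_tall):
    genes = mc.simulate_gene_trees(six_taxon_tall, 5, 2)
    taxa = sorted(leaf_labels(six_taxon_tall))
    beta = mc.beta_mod1(genes, taxa)
    beta.to_text(tmp_path / "beta.txt")
    text = (tmp_path / "beta.txt").read_text()
    assert len(text.splitlines()) == len(beta.masks)
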