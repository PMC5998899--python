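"""Taxon-deletion models and mask application."""

import numpy as np
import pytest
from scipy import stats

import misscoal as mc
from misscoal.deletion import ModelSpec, species_tree_clades
from misscoal.trees import leaf_labels


class TestMiid:
    def test_p_zero_all_ones(self):
        mask = mc.miid_mask(50, 6, 0.0, 1)
        assert mask.matrix.all()

    def test_p_one_rejected(self):
        with pytest.raises(ValueError):
            mc.miid_mask(10, 4, 1.0, 0)

    def test_law_of_large_numbers(self):
        mask = mc.miid_mask(10_000, 10, 0.3, 2)
        assert abs(mask.missing_fraction() - 0.3) < 0.01
        col_means = 1 - mask.matrix.mean(axis=0)
        assert np.all(np.abs(col_means - 0.3) < 0.02)

    def test_determinism(self):
        a = mc.miid_mask(100, 5, 0.4, 7)
        b = mc.miid_mask(100, 5, 0.4, 7)
        assert (a.matrix == b.matrix).all()


class TestClade:
    def test_caterpillar_deleted_range(self):
        st = mc.caterpillar_species_tree(26)
        mask = mc.clade_mask(st, 2000, 5, 24, 3)
        deleted = 1 - mask.matrix.mean(axis=1)
        assert deleted.min() == pytest.approx(2 / 26)
        assert deleted.max() == pytest.approx(21 / 26)

    def test_rows_are_eligible_clades(self):
        st = mc.yule_species_tree(12, 2.0, 4)
        clades = {frozenset(c) for c in species_tree_clades(st)
                  if 3 <= len(c) <= 11}
        mask = mc.clade_mask(st, 200, 3, 11, 5)
        for row in mask.matrix:
            kept = frozenset(t for t, y in zip(mask.taxa, row) if y)
            assert kept in clades

    def test_outgroup_always_deleted(self):
        # on a caterpillar with size_max < n the deepest leaf is outside
        # every eligible clade
        st = mc.caterpillar_species_tree(10)
        mask = mc.clade_mask(st, 300, 3, 8, 6)
        out_col = list(mask.taxa).index("t10")
        assert mask.matrix[:, out_col].sum() == 0

    def test_single_eligible_clade(self):
        st = mc.caterpillar_species_tree(8)
        mask = mc.clade_mask(st, 50, 7, 7, 7)
        assert (mask.matrix.sum(axis=1) == 7).all()
        assert len({tuple(r) for r in mask.matrix}) == 1

    def test_no_eligible_clade_error(self):
        st = mc.parse_newick("((a,b),(c,d));")
        st.is_rooted = True
        with pytest.raises(ValueError, match="available clade sizes"):
            mc.clade_mask(st, 10, 3, 3, 0)


class TestMixture:
    def test_zero_fraction(self):
        st = mc.caterpillar_species_tree(8)
        mask = mc.mixture_mask(st, 100, 0.0, 3, 7, 1)
        assert mask.matrix.all()

    def test_exact_incomplete_count(self):
        st = mc.caterpillar_species_tree(26)
        mask = mc.mixture_mask(st, 1000, 0.55, 5, 24, 2)
        incomplete = (mask.matrix.min(axis=1) == 0).sum()
        assert incomplete == 550

    def test_degenerate_is_clade_like(self):
        st = mc.caterpillar_species_tree(8)
        mask = mc.mixture_mask(st, 200, 1.0, 3, 7, 3)
        clades = {frozenset(c) for c in species_tree_clades(st)
                  if 3 <= len(c) <= 7}
        for row in mask.matrix:
            kept = frozenset(t for t, y in zip(mask.taxa, row) if y)
            assert kept in clades


class TestKSubset:
    def test_k_equals_n(self):
        mask = mc.ksubset_mask(50, 6, 6, 1)
        assert mask.matrix.all()

    def test_row_sums(self):
        mask = mc.ksubset_mask(500, 9, 4, 2)
        assert (mask.matrix.sum(axis=1) == 4).all()

    def test_uniform_over_subsets(self):
        n, k, m = 5, 2, 20_000
        mask = mc.ksubset_mask(m, n, k, 3)
        keys = [tuple(r) for r in mask.matrix]
        counts = np.array(list(
            {key: keys.count(key) for key in set(keys)}.values()))
        assert len(counts) == 10
        assert stats.chisquare(counts).pvalue > 0.01

    def test_central_bipartition_never_covered(self):
        # n > 2k on a caterpillar: no gene contains either half of the
        # central split
        st = mc.caterpillar_species_tree(10)
        central_half = frozenset(sorted(leaf_labels(st))[:5])
        mask = mc.ksubset_mask(2000, 10, 4, 4, taxa=sorted(leaf_labels(st)))
        for row in mask.matrix:
            kept = frozenset(t for t, y in zip(mask.taxa, row) if y)
            assert not central_half <= kept
            assert not (frozenset(mask.taxa) - central_half) <= kept

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            mc.ksubset_mask(10, 5, 1, 0)
        with pytest.raises(ValueError):
            mc.ksubset_mask(10, 5, 6, 0)


class TestAdversaryFilter:
    def test_all_match(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 20, 1)
        matching = [g for g in genes
                    if mc.rf_distance(g, six_taxon_tall) == 0]
        kept = mc.adversary_filter(matching, six_taxon_tall)
        assert len(kept) == len(matching) > 0

    def test_none_match_warns(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 10, 2)
        wrong = mc.perturb_gene_tree(genes[0], 2, 3)
        if mc.rf_distance(wrong, six_taxon_tall) == 0:
            wrong = mc.perturb_gene_tree(genes[0], 3, 4)
        matching = [g for g in genes if mc.rf_distance(g, wrong) == 0]
        if matching:  # pragma: no cover - tall tree makes this unlikely
            pytest.skip("perturbed target occurred naturally")
        with pytest.warns(UserWarning, match="removed every gene"):
            assert mc.adversary_filter(genes, wrong) == []


class TestApplyMask:
    def test_identity(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 10, 1)
        taxa = sorted(leaf_labels(six_taxon_tall))
        mask = mc.miid_mask(10, 6, 0.0, 0, taxa=taxa)
        out = mc.apply_mask(genes, mask)
        assert out.n_dropped == 0
        assert all(mc.rf_distance(a, b) == 0
                   for a, b in zip(out.trees, genes))

    def test_single_taxon_row_dropped(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 3, 2)
        taxa = tuple(sorted(leaf_labels(six_taxon_tall)))
        mat = np.ones((3, 6), dtype=np.int8)
        mat[1] = 0
        mat[1, 0] = 1
        mask = mc.DeletionMask(taxa, mat, "custom")
        out = mc.apply_mask(genes, mask)
        assert out.n_dropped == 1
        assert len(out.trees) == 2

    def test_leafset_equals_row_support(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 30, 3)
        taxa = sorted(leaf_labels(six_taxon_tall))
        mask = mc.miid_mask(30, 6, 0.4, 4, taxa=taxa)
        out = mc.apply_mask(genes, mask)
        kept_rows = [frozenset(t for t, y in zip(mask.taxa, row) if y)
                     for row in mask.matrix if row.sum() >= 2]
        assert [frozenset(leaf_labels(t)) for t in out.trees] == kept_rows

    def test_dimension_mismatch(self, six_taxon_tall):
        genes = mc.simulate_gene_trees(six_taxon_tall, 5, 4)
        mask = mc.miid_mask(4, 6, 0.3, 5)
        with pytest.raises(ValueError, match="rows"):
            mc.apply_mask(genes, mask)


class TestIndependence:
    def test_topology_independent_of_mask(self):
        """Deletion is independent of gene-tree topology for i.i.d. masks:
        the topology distribution conditional on a fixed mask row matches
        the unconditional one."""
        st = mc.parse_newick("((a:1,b:1):0.2,(c:1,d:1):0.2);")
        st.is_rooted = True
        m = 12_000
        genes = mc.simulate_gene_trees(st, m, 11)
        taxa = ("a", "b", "c", "d")
        qt_all = mc.quartet_table(genes, taxa)
        mask = mc.miid_mask(m, 4, 0.3, 12, taxa=taxa)
        sel = [g for g, row in zip(genes, mask.matrix) if row.all()]
        qt_sel = mc.quartet_table(sel, taxa)
        p = stats.chi2_contingency(
            np.array([qt_all.counts[0], qt_sel.counts[0]])).pvalue
        assert p > 0.01


class TestModelSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("bogus")
        with pytest.raises(ValueError):
            ModelSpec("miid", p_miss=1.0)

    def test_labels(self):
        assert ModelSpec("miid", p_miss=0.3).label == "miid(p=0.3)"
        assert ModelSpec("none").label == "none"


def test_mask_tsv_roundtrip(tmp_path):
    mask = mc.miid_mask(20, 5, 0.3, 1, taxa=list("abcde"))
    path = tmp_path / "mask.tsv"
    mask.to_tsv(path)
    back = mc.DeletionMask.from_tsv(path)
    assert back.taxa == mask.taxa
    assert (back.matrix == mask.matrix).all()
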