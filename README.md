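# misscoal

Coalescent-based species tree estimation under models of missing data.

Phylogenomic datasets routinely have *incomplete genes*: many loci are
sequenced or assembled for only a subset of the species under study.
Standard "summary" species-tree methods — which combine per-locus gene
trees into a species tree — are proven statistically consistent under the
multi-species coalescent (MSC) only when every gene tree contains every
species. `misscoal` is a simulation and estimation toolkit for studying
what happens when they do not. It is aimed at researchers in
phylogenomics and molecular evolution who want executable, reproducible
versions of the theory: simulators, deletion models, estimators and
metrics that can be composed into full experiments from Python or the
command line.

## What it implements

**Simulation.** Rooted gene trees evolve within a species tree
`(T, Θ)` (branch lengths in coalescent units) under the MSC: in a
population with *k* uncoalesced lineages the waiting time to the next
coalescence is `Exp(k(k-1)/2 · λ)` and the coalescing pair is uniform.
Species trees come from a pure-birth (Yule) process rescaled to a chosen
root height (the height controls the level of incomplete lineage
sorting), or from fixed shapes (caterpillars, Newick input). Gene-tree
estimation error is emulated topologically by random NNI moves.

**Taxon-deletion models.** Presence indicators `Y_ij ∈ {0,1}` per gene
*i* and taxon *j*, drawn independently of the gene trees:

* `M_iid` — each taxon missing from each gene independently with
  probability *p*;
* `M_clade` — per gene one rooted species-tree clade (within a size
  range) is kept, everything outside is deleted; mixtures of complete
  and clade-deleted genes;
* exactly-*k* random subsets — each gene keeps a uniform *k*-subset
  (a "full subset coverage" model);
* an *adversary* filter that keeps a gene iff its topology equals a
  chosen target tree — deletion then depends on the gene tree, and the
  species tree is no longer identifiable.

**Summary statistics (the natural extension).** Each statistic for an
ℓ-subset of taxa is computed from exactly the genes containing the whole
subset: average topological internode distances (2-tuple), rooted
triplet frequencies (3-tuple), unrooted quartet frequencies (4-tuple).

**Estimators.**

* `DistanceSpeciesTree` — neighbor joining on the average internode
  distance matrix (the NJst/ASTRID route);
* `QuartetSpeciesTree` — maximize the quartet score
  `Σ_q Σ_i 1{Top(q, t) = Top(q, t_i)}` over all topologies (exact mode)
  or over trees drawing bipartitions from an allowed set β: bipartitions
  of complete gene trees (default), plus every gene-tree clade completed
  against the full taxon set (mod1), plus optionally the bipartitions of
  an auxiliary tree such as the NJ estimate (+Φ);
* `TripletSpeciesTree` — maximize the rooted-triplet score.

**Metrics.** Normalized Robinson–Foulds error; AD (mean normalized RF
between true species tree and true gene trees — an ILS proxy); GTEE
(mean normalized RF between true and estimated gene trees); `‖E‖₂`, the
upper-triangle Euclidean distance between the estimated average
internode matrix and the unit-branch-length species-tree matrix; the
four-point condition check.

**Experiments.** Config-driven pipelines (`run_experiment`,
`run_experiment1`, `run_demonstrations`) that reproduce, at desk scale,
the qualitative behavior of summary methods under missing data,
including executable demonstrations of the non-identifiability results.

## Worked example

```python
import misscoal as mc

st = mc.yule_species_tree(8, total_height=5.0, seed=1)   # species tree
genes = mc.simulate_gene_trees(st, m=500, seed=2)        # MSC gene trees
taxa = sorted(mc.trees.leaf_labels(st))

mask = mc.miid_mask(500, 8, p_miss=0.30, seed=3, taxa=taxa)
masked = mc.apply_mask(genes, mask).trees                # incomplete genes

res = mc.QuartetSpeciesTree(masked, taxa, beta="mod1").fit()
print(res.summary())
print("RF error:", mc.species_tree_error(res.tree, st))
```

Output:

```
Species tree estimate (quartet-constrained)
==============================================
taxa:          8
genes:         497
objective:     6769
search space:  10395 trees from 119 allowed bipartitions
tree:          (t1,((t2,(t4,(t6,t7))),(t3,t5)),t8);
RF error: 0.0
```

497 of the 500 genes survive masking (three were left with fewer than
two taxa). The objective is the number of gene-quartet topologies the
estimate agrees with; the search space line reports how many candidate
trees the allowed-bipartition set admits; an RF error of 0 means the
unrooted species-tree topology was recovered exactly. The same pipeline is available from the shell:

```bash
misscoal simulate --n-taxa 8 --height 5 --genes 500 --seed 1 --out sim/
misscoal delete --genes sim/genes.nwk --model miid --p-miss 0.3 --out del/
misscoal estimate quartet --genes del/genes_masked.nwk --beta-mode mod1
misscoal demos --seed 1
```

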