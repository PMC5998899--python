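# Methods

## Model

Gene trees are generated by the multi-species coalescent (MSC) within a
rooted binary species tree whose branch lengths are in coalescent units
(time divided by population size). One lineage enters at each leaf;
within a species-tree branch containing *k* uncoalesced lineages the
waiting time to the next coalescence is exponential with rate
`k(k-1)/2 · λ`, the coalescing pair is chosen uniformly, surviving
lineages pass to the parent branch, and above the root the process runs
until a single lineage remains. `λ = 1` by default: with lengths already
in coalescent units any other value would just rescale time. The
simulator was validated against the closed-form probability that a
rooted triplet matches the species tree, `1 − (2/3) e^{−t}` for an
internal branch of *t* coalescent units, and against the exchangeability
property that restricting simulated gene trees to a taxon subset is
distributionally identical to simulating within the restricted species
tree.

Species trees come from a forward pure-birth (Yule) process: two
lineages from the root, each splitting at unit rate; after the *n*-th
tip appears the process is held one further exponential waiting time so
every pendant branch is positive, and the tree is rescaled so the
root-to-leaf height equals a chosen value. The height is the ILS dial:
at height 8–12 (26 taxa) the mean gene-tree/species-tree normalized RF
distance (AD) is roughly 0.2–0.4, at height 5 roughly 0.5, and at
height 0.75 roughly 0.85. Fixed caterpillar trees with unit or
2-coalescent-unit internal branches are used where a deterministic shape
is needed.

## Missing data

Deletion masks are m×n presence matrices generated independently of the
gene trees. `p_miss` is always the probability a taxon is *missing* (the
operational definition used when thresholding uniform draws at 0.30 or
0.60). The clade model draws, per gene, one rooted species-tree clade
uniformly from those within a size range and deletes everything outside
it; eligibility excludes the root clade unless the maximum size is set
to *n*. Mixtures make an exact `⌊f·m⌋`-subset of genes clade-deleted and
leave the rest complete. The exactly-k model keeps an independent
uniform k-subset per gene. Genes reduced to fewer than two taxa are
dropped (no summary statistic can use them) and counted.

Masked genes are produced by homeomorphic restriction of the gene tree
to the retained taxa, with merged edge lengths summed.

## Summary statistics and the natural extension

Every ℓ-subset statistic is computed from exactly the genes containing
all ℓ taxa. The internode distance between two leaves is implemented as
the number of **edges** on their path in the homeomorphically reduced
unrooted tree (1 for a two-leaf tree, 2 within a quartet cherry, 3
across a quartet). The field sometimes words this as a node count; the
edge count is the convention under which the 4-taxon conditional
expectation of the sibling pair under i.i.d. deletion is exactly
`2 − p²`, which we treat as the operational ground truth. For the cross
pair, explicit enumeration of the deletion cases — both other taxa
present `(1−p)²` (distance 3), exactly one deleted `2p(1−p)` (distance
2), both deleted `p²` (distance 1) — gives `3 − 2p`. An alternative
case weighting `((1−p)², 2p−p², p²)`, whose weights sum to `1+p−p²`,
yields `3 − 2p + 2p²` instead; the demonstration code reports both, and
Monte-Carlo at 50,000 genes sides with the enumeration (for example at
p = 0.3: measured 2.405 ± 0.007 versus 2.40 enumerated, 2.58
alternative). The four-point condition on the conditional expectations
holds under either value, with the minimum pairwise sum identifying the
species-tree split.

Quartet topologies are induced via path-distance comparison (the
minimum of the three pairwise sums is strict on a binary tree metric);
rooted triplets via LCA depths (the cherry pair has the strictly
deepest LCA). Both are Type-1 statistics (invariant to deleting taxa
outside the subset); the average internode distance is Type 2 — a
5-leaf witness where removing a taxon shortens another pair's reduced
path is kept as a regression test.

## Estimators

* **Distance route**: classic neighbor joining on the average internode
  matrix. Ties in the Q-criterion break to the lowest index pair under
  the sorted taxon order (merged nodes rank last), so runs are fully
  deterministic. Undefined pairs (zero co-occurrence) are an error that
  names the pairs and suggests adding genes; no imputation is attempted.
* **Quartet route**: maximize the quartet score. Exact mode enumerates
  all unrooted topologies (guarded at 9 taxa). Constrained mode
  enumerates, by memoized clade decomposition, every tree whose
  nontrivial bipartitions lie in the allowed set β, then scores each
  candidate; a counting pre-pass aborts above 2·10⁶ trees. This is a
  specification-by-contract implementation: its output provably attains
  the maximum over the constrained space, which the test suite pins to
  exact enumeration and to an independent bipartition-logic scorer.
  β variants: bipartitions of complete genes (default); plus every
  gene-tree clade C completed to `C | X∖C` (mod1; pendant-edge halves
  included, since every bipartition half of a gene tree counts as a
  clade); plus the bipartitions of an auxiliary tree (+Φ, by default
  the NJ estimate).
* **Triplet route**: maximize the rooted-triplet score over all rooted
  topologies (guarded at 7 taxa). This scores topologies only — it
  stands in for pseudo-likelihood methods whose statistics are the same
  rooted-triplet frequencies but whose likelihood machinery (and
  branch-length estimation) is out of scope. Gene trees are rooted at
  the outgroup when present, else at the midpoint of the longest
  leaf-to-leaf path.

Optimum ties are broken by canonical Newick order and reported in the
result's warnings. Estimator failures inside experiment pipelines
(undefined distances, empty search spaces, enumeration guards) become
row-level warnings, not crashes.

## Metrics

Species-tree error is the normalized RF distance, `|Bip(t₁) Δ Bip(t₂)| /
(2(n−3))`, on unrooted shapes. AD and GTEE restrict the reference tree
to each gene's leafset and skip genes with fewer than four taxa. `‖E‖₂`
is the Euclidean norm over the strict upper triangle of the difference
between the estimated average internode matrix and the species tree's
unit-branch-length path-edge-count matrix. The four-point check uses
tolerance 1e-9 for exact matrices and three Monte-Carlo standard errors
for estimated expectations.

## Study conditions and problem sizes

The simulation study runs at desk scale, chosen so the qualitative
questions — consistency trends, search-space coverage, deviation
directions — are answerable in minutes on one CPU:

* **Mask realism**: 26 taxa × 1000 genes × 20 replicates; i.i.d.
  deletion at p ∈ {0.30, 0.60}; clade deletion with sizes 5–24 on a
  26-taxon caterpillar (per-gene deleted fraction spans 2/26 to 21/26).
  On Yule-shaped 26-taxon trees the clade model deletes 62% of taxa per
  incomplete gene on average, and the 55%/95% mixtures carry ≈34%/≈59%
  total missing data.
* **Consistency trend**: fixed 8-taxon caterpillar with 1-coalescent-
  unit internal branches, true gene trees, i.i.d. deletion at p = 0.3,
  20 replicates, gene counts 50/200/1000 taken as prefixes of one
  sample. Both the NJ and the mod1-constrained quartet estimators reach
  zero RF error in ≥ 18/20 replicates at 1000 genes.
* **4-taxon additivity**: 50,000 genes per deletion level, conditional
  on the gene quartet matching the species topology.
* **Identifiability demos**: adversary filtering on a 6-taxon tree at
  height 1 (high ILS, so the wrong target topology is observed);
  exactly-k deletion with k = 4 on a 10-taxon caterpillar at 10,000
  genes, where neither gene-tree-derived search space can cover the
  central 5|5 bipartition but adding the NJ tree's bipartitions does.
* **Input-deviation experiment**: 26 taxa, 1000 genes, the very-high-ILS
  regime (height 0.75, AD ≈ 0.85). There, i.i.d. deletion increases
  `‖E‖₂` monotonically in p on every replicate, while clade-based
  deletion does not increase it and lowers AD. At moderate ILS the
  95%-incomplete mixture can reverse: only the ~5% complete genes inform
  cross-clade pairs, and their sampling noise can exceed the (small)
  within-clade bias reduction. The implementation reports both regimes
  honestly; the demonstration condition is the high-ILS one because that
  is where the clade model's information-quality effect is the
  phenomenon of interest.

## What the generator does and does not emulate

The synthetic data cover topology-level behavior: ILS via the MSC,
missing data via mask models, and gene-tree estimation error via random
NNI moves whose count is Poisson per gene. They do not include sequence
evolution, alignment error, model misspecification in gene-tree
inference, or gene birth/death processes; GTEE emulated by NNI moves is
uniform over the tree, whereas likelihood-based gene-tree error
concentrates on short branches. Passing tests therefore support claims
about the estimators' behavior under the stated stochastic models, not
about any particular empirical pipeline.

## Known limitations

* Constrained search enumerates the allowed space; it is exact but not
  scalable beyond desk size (the guard errors out rather than
  approximating).
* The triplet estimator is a score maximizer, not a pseudo-likelihood
  optimizer, and estimates no branch lengths.
* Undefined distance pairs are an error by design; downstream users who
  need imputation must supply their own matrix.
* The Yule generator's clade-size distribution (many small, few large
  clades) matches the 62% mean deleted fraction of clade-based deletion
  but has a larger per-gene spread than birth-death trees simulated
  with explicit population parameters.
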