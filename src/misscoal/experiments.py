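"""Desk-scale simulation experiments and executable demonstrations.

The pipelines mirror a standard missing-data simulation design: simulate a
species tree, simulate gene trees under the multi-species coalescent,
optionally emulate gene-tree estimation error by random NNI moves, delete
taxa under a deletion model, then estimate species trees from prefixes of
the gene set and score them. Everything is deterministic given the master
seed, with per-replicate and per-gene substreams, and results at a smaller
gene count always use a prefix of the larger sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import metrics as _metrics
from .deletion import (
    DeletionMask,
    ModelSpec,
    adversary_filter,
    apply_mask,
    clade_mask,
    ksubset_mask,
    miid_mask,
    mixture_mask,
)
from .estimators import (
    SearchSpaceEmptyError,
    UndefinedDistanceError,
    beta_default,
    beta_mod1,
    beta_plus_phi,
)
from .model import DistanceSpeciesTree, QuartetSpeciesTree, TripletSpeciesTree
from .msc import (
    caterpillar_species_tree,
    perturb_gene_tree,
    simulate_gene_trees,
    yule_species_tree,
)
from .summaries import average_internode_matrix
from .trees import (
    Bipartition,
    bipartitions,
    leaf_labels,
    parse_newick,
    restrict,
    rf_distance,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "run_experiment1",
    "run_demonstrations",
    "expected_internode_by_enumeration",
]


@dataclass
class ExperimentConfig:
    """Settings for one simulation experiment.

    ``gene_counts`` must be ascending; smaller counts reuse the prefix of
    the largest sample. ``gtee_moves`` is the mean of the per-gene Poisson
    number of NNI moves used to emulate gene-tree estimation error
    (0 = true gene trees).
    """

    n_taxa: int = 8
    tree_height: float = 5.0
    species_tree_newick: str | None = None
    gene_counts: tuple[int, ...] = (50, 200, 1000)
    replicates: int = 10
    models: tuple[ModelSpec, ...] = (
        ModelSpec("none"),
        ModelSpec("miid", p_miss=0.30),
        ModelSpec("miid", p_miss=0.60),
    )
    estimators: tuple[str, ...] = ("nj", "quartet-mod1")
    gtee_moves: float = 0.0
    seed: int = 0
    clade_size_min: int = 3
    clade_size_max: int | None = None

    def __post_init__(self) -> None:
        if list(self.gene_counts) != sorted(self.gene_counts) or \
                min(self.gene_counts) <= 0:
            raise ValueError("gene_counts must be positive and ascending")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        models = raw.pop("models", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if models is not None:
            cfg.models = tuple(ModelSpec(**m) for m in models)
        return cfg


def _species_tree(cfg: ExperimentConfig, seed: int) -> dendropy.Tree:
    if cfg.species_tree_newick:
        tree = parse_newick(cfg.species_tree_newick)
        tree.is_rooted = True
        return tree
    return yule_species_tree(cfg.n_taxa, cfg.tree_height, seed)


def _make_mask(spec: ModelSpec, st, m, n, taxa, seed) -> DeletionMask:
    if spec.name == "none":
        return DeletionMask(taxa, np.ones((m, n), dtype=np.int8), "none", seed)
    if spec.name == "miid":
        return miid_mask(m, n, spec.p_miss, seed, taxa=taxa)
    if spec.name == "clade":
        return clade_mask(st, m, spec.size_min, spec.size_max or n - 1, seed)
    if spec.name == "mixture":
        return mixture_mask(st, m, spec.fraction_incomplete,
                            spec.size_min, spec.size_max or n - 1, seed)
    if spec.name == "ksubset":
        return ksubset_mask(m, n, spec.k, seed, taxa=taxa)
    raise ValueError(f"model {spec.name!r} has no mask form")


def _estimate(name: str, genes, taxa, outgroup=None):
    if name == "nj":
        return DistanceSpeciesTree(genes, taxa).fit()
    if name == "quartet-default":
        return QuartetSpeciesTree(genes, taxa, beta="default").fit()
    if name == "quartet-mod1":
        return QuartetSpeciesTree(genes, taxa, beta="mod1").fit()
    if name == "quartet-plus-phi":
        return QuartetSpeciesTree(genes, taxa, beta="mod1",
                                  plus_phi=True).fit()
    if name == "quartet-exact":
        return QuartetSpeciesTree(genes, taxa, beta="exact").fit()
    if name == "triplet":
        return TripletSpeciesTree(genes, taxa, outgroup=outgroup).fit()
    raise ValueError(f"unknown estimator {name!r}")


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Species-tree error versus gene count under each deletion model.

    Returns a long-format table with one row per (replicate, model, gene
    count, estimator); estimator failures (undefined distances, empty
    search spaces, enumeration guards) become row warnings, not crashes.
    """
    rows = []
    rep_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    m_max = max(cfg.gene_counts)
    for rep, ss in enumerate(rep_seeds):
        s_tree, s_genes, s_gtee, *s_models = [
            int(x.generate_state(1)[0] % (2 ** 31))
            for x in ss.spawn(3 + len(cfg.models))]
        st = _species_tree(cfg, s_tree)
        taxa = tuple(sorted(leaf_labels(st)))
        true_genes = simulate_gene_trees(st, m_max, s_genes)
        if cfg.gtee_moves > 0:
            rng = np.random.default_rng(s_gtee)
            input_genes = [
                perturb_gene_tree(gt, int(rng.poisson(cfg.gtee_moves)), rng)
                for gt in true_genes]
            gtee_all = _metrics.gtee(true_genes, input_genes)
        else:
            input_genes = true_genes
            gtee_all = 0.0
        for spec, s_model in zip(cfg.models, s_models):
            mask = _make_mask(spec, st, m_max, len(taxa), taxa, s_model)
            for m in cfg.gene_counts:
                genes_m = _prefix(input_genes, mask, m)
                true_m = _prefix(true_genes, mask, m)
                try:
                    ad = _metrics.average_distance_AD(st, true_m)
                except ValueError:
                    ad = None
                for est in cfg.estimators:
                    rec = _metrics.MetricsRecord(
                        replicate=rep, method=est, model=spec.label, m=m,
                        ad=ad, gtee=gtee_all)
                    try:
                        res = _estimate(est, genes_m, taxa)
                        rec.rf_error = _metrics.species_tree_error(
                            res.tree, st)
                        rec.warnings = "; ".join(res.warnings)
                        if est == "nj":
                            ds = average_internode_matrix(genes_m, taxa)
                            dt = _metrics.true_internode_matrix(st)
                            if not ds.undefined_pairs():
                                rec.matrix_error = _metrics.matrix_error_norm(
                                    dt, ds)
                    except (UndefinedDistanceError, SearchSpaceEmptyError,
                            ValueError) as exc:
                        rec.warnings = f"{type(exc).__name__}: {exc}"
                    rows.append(rec.as_row())
    return pd.DataFrame(rows, columns=_metrics.RESULT_COLUMNS)


def _prefix(genes, mask: DeletionMask, m: int):
    """Masked restriction of the first ``m`` genes (prefix property)."""
    sub = DeletionMask(mask.taxa, mask.matrix[:m], mask.model, mask.seed)
    return apply_mask(genes[:m], sub).trees


def run_experiment1(cfg: ExperimentConfig) -> pd.DataFrame:
    """Impact of taxon deletion on the *inputs* to estimation: AD, GTEE and
    the deviation of the average internode matrix from the unit-branch
    species-tree matrix, per deletion model and gene count."""
    rows = []
    rep_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    m_max = max(cfg.gene_counts)
    for rep, ss in enumerate(rep_seeds):
        s_tree, s_genes, s_gtee, *s_models = [
            int(x.generate_state(1)[0] % (2 ** 31))
            for x in ss.spawn(3 + len(cfg.models))]
        st = _species_tree(cfg, s_tree)
        taxa = tuple(sorted(leaf_labels(st)))
        true_genes = simulate_gene_trees(st, m_max, s_genes)
        if cfg.gtee_moves > 0:
            rng = np.random.default_rng(s_gtee)
            input_genes = [
                perturb_gene_tree(gt, int(rng.poisson(cfg.gtee_moves)), rng)
                for gt in true_genes]
        else:
            input_genes = true_genes
        dt = _metrics.true_internode_matrix(st)
        for spec, s_model in zip(cfg.models, s_models):
            mask = _make_mask(spec, st, m_max, len(taxa), taxa, s_model)
            for m in cfg.gene_counts:
                true_m = _prefix(true_genes, mask, m)
                input_m = _prefix(input_genes, mask, m)
                rec = _metrics.MetricsRecord(
                    replicate=rep, method="inputs", model=spec.label, m=m)
                try:
                    rec.ad = _metrics.average_distance_AD(st, true_m)
                except ValueError:
                    pass
                if cfg.gtee_moves > 0:
                    vals = [rf_distance(t, e, normalized=True)
                            for t, e in zip(true_m, input_m)
                            if leaf_labels(t) == leaf_labels(e)
                            and len(leaf_labels(t)) >= 4]
                    rec.gtee = float(np.mean(vals)) if vals else None
                ds = average_internode_matrix(input_m, taxa)
                if not ds.undefined_pairs():
                    rec.matrix_error = _metrics.matrix_error_norm(dt, ds)
                else:
                    rec.warnings = "undefined pairs in distance matrix"
                rows.append(rec.as_row())
    return pd.DataFrame(rows, columns=_metrics.RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# executable demonstrations of the identifiability results
# ---------------------------------------------------------------------------

def expected_internode_by_enumeration(p: float) -> dict[str, float]:
    """Exact conditional expectations of internode distances on a 4-taxon
    tree, by explicit enumeration of deletion patterns.

    Conditions on the gene quartet matching the species topology 12|ab and
    on both focal taxa being present; the other two taxa are deleted
    independently with probability ``p`` and the path is re-measured on
    the reduced tree. Also returns the alternative cross-pair polynomial
    ``3 - 2p + 2p^2`` obtained when the three deletion cases are weighted
    as (1-p)^2, 2p - p^2 and p^2; the enumeration weights (which sum to
    one) are (1-p)^2, 2p(1-p) and p^2.
    """
    from .summaries import internode_distance

    quartet = parse_newick("((x1,x2),(xa,xb));")
    quartet.is_rooted = False

    def cond_mean(pair, others):
        total = 0.0
        for da in (0, 1):
            for db in (0, 1):
                keep = set(pair) | {o for o, d in zip(others, (da, db))
                                    if not d}
                w = (p if da else 1 - p) * (p if db else 1 - p)
                if len(keep) >= 2:
                    sub = restrict(quartet, keep)
                    total += w * internode_distance(sub, *pair)
        return total

    return {
        "sibling": cond_mean(("x1", "x2"), ("xa", "xb")),
        "cross": cond_mean(("x1", "xa"), ("x2", "xb")),
        "cross_alternative_weighting": 3 * (1 - p) ** 2
        + 2 * (2 * p - p ** 2) + 1 * p ** 2,
    }


def _fourpoint_demo(seed: int, m: int = 50_000,
                    p_values=(0.0, 0.3, 0.6)) -> dict:
    """Monte-Carlo check of additivity of conditional expected internode
    distances on a 4-taxon tree under i.i.d. deletion."""
    st = parse_newick("((x1:1,x2:1):1,(xa:1,xb:1):1);")
    st.is_rooted = True
    taxa = ("x1", "x2", "xa", "xb")
    genes = simulate_gene_trees(st, m, seed)
    match = np.array([rf_distance(g, st) == 0 for g in genes])
    from ._combinatorics import edge_count_distances

    out = {}
    for pi, p in enumerate(p_values):
        mask = miid_mask(m, 4, p, seed + 1000 + pi, taxa=taxa)
        sums = np.zeros((4, 4))
        sq = np.zeros((4, 4))
        cnt = np.zeros((4, 4))
        for g in range(m):
            if not match[g]:
                continue
            keep = [t for t, y in zip(taxa, mask.matrix[g]) if y]
            if len(keep) < 2:
                continue
            sub = restrict(genes[g], keep) if len(keep) < 4 else genes[g]
            labels, D = edge_count_distances(sub)
            ids = [taxa.index(l) for l in labels]
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    i, j = ids[a], ids[b]
                    d = D[a, b]
                    sums[i, j] += d
                    sq[i, j] += d * d
                    cnt[i, j] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sums / cnt
            se = np.sqrt((sq / cnt - mean ** 2) / cnt)
        pair_sums = {
            "S_sib": mean[0, 1] + mean[2, 3],
            "S_cross1": mean[0, 2] + mean[1, 3],
            "S_cross2": mean[0, 3] + mean[1, 2],
        }
        se_sums = {
            "S_sib": math.hypot(se[0, 1], se[2, 3]),
            "S_cross1": math.hypot(se[0, 2], se[1, 3]),
            "S_cross2": math.hypot(se[0, 3], se[1, 2]),
        }
        ordered = sorted(pair_sums, key=pair_sums.get)
        med, mx = ordered[1], ordered[2]
        gap = abs(pair_sums[mx] - pair_sums[med])
        gap_se = math.hypot(se_sums[med], se_sums[mx])
        oracle = expected_internode_by_enumeration(p)
        out[p] = {
            "mean_sibling": float(mean[0, 1]),
            "se_sibling": float(se[0, 1]),
            "mean_cross": float(mean[0, 2]),
            "se_cross": float(se[0, 2]),
            "closed_form_sibling": 2 - p ** 2,
            "enumeration_cross": oracle["cross"],
            "alternative_cross": oracle["cross_alternative_weighting"],
            "sibling_ok": bool(abs(mean[0, 1] - (2 - p ** 2))
                               <= 3 * se[0, 1] + 1e-12),
            "cross_ok": bool(abs(mean[0, 2] - oracle["cross"])
                             <= 3 * se[0, 2] + 1e-12),
            "fourpoint_gap": float(gap),
            "fourpoint_ok": bool(gap <= 3 * gap_se + 1e-12),
            "min_sum_is_species_split": ordered[0] == "S_sib",
        }
    return out


def _adversary_demo(seed: int, m: int = 1000) -> dict:
    st = yule_species_tree(6, 1.0, seed)
    taxa = tuple(sorted(leaf_labels(st)))
    genes = simulate_gene_trees(st, m, seed + 1)
    # target: a wrong topology that actually occurs among the gene trees
    # (any topology has positive probability under the MSC; picking an
    # observed one keeps the filtered set nonempty)
    target = None
    for gt in genes:
        if rf_distance(gt, st) > 0:
            target = gt
            break
    if target is None:  # pragma: no cover - needs pathologically low ILS
        raise RuntimeError("no discordant gene tree to use as target")
    kept = adversary_filter(genes, target)
    out = {"n_kept": len(kept), "target_rf_to_true":
           rf_distance(target, st, normalized=True)}
    if kept:
        nj = DistanceSpeciesTree(kept, taxa).fit().tree
        qt = QuartetSpeciesTree(kept, taxa, beta="mod1").fit().tree
        out["nj_rf_to_target"] = rf_distance(nj, target, normalized=True)
        out["quartet_rf_to_target"] = rf_distance(qt, target, normalized=True)
        out["nj_rf_to_true"] = rf_distance(nj, st, normalized=True)
        out["quartet_rf_to_true"] = rf_distance(qt, st, normalized=True)
    return out


def _ksubset_demo(seed: int, n: int = 10, k: int = 4,
                  m: int = 10_000) -> dict:
    """Central-bipartition coverage under exactly-k random subsets on a
    caterpillar: no gene can contain either half of the central split when
    n > 2k, so neither the default nor the clade-completed search space
    covers it; adding the bipartitions of the distance-based tree does."""
    st = caterpillar_species_tree(n, internal=2.0)
    taxa = tuple(sorted(leaf_labels(st)))
    genes = simulate_gene_trees(st, m, seed)
    mask = ksubset_mask(m, n, k, seed + 1, taxa=taxa)
    masked = apply_mask(genes, mask)
    central = _central_bipartition(st)
    b_def = beta_default(masked.trees, taxa)
    b_mod1 = beta_mod1(masked.trees, taxa)
    ds = average_internode_matrix(masked.trees, taxa)
    result = {
        "n_genes": m,
        "central_in_default": central in b_def,
        "central_in_mod1": central in b_mod1,
        "coverage_count": sum(
            1 for gt in masked.trees
            if central.side1 <= frozenset(leaf_labels(gt))
            or central.side2 <= frozenset(leaf_labels(gt))),
    }
    if not ds.undefined_pairs():
        nj = DistanceSpeciesTree(masked.trees, taxa).fit().tree
        b_phi = beta_plus_phi(b_mod1, nj)
        result["nj_defined"] = True
        result["central_in_plus_phi"] = central in b_phi
        result["nj_rf_to_true"] = rf_distance(nj, st, normalized=True)
    else:
        result["nj_defined"] = False
    return result


def _central_bipartition(st) -> Bipartition:
    """The most balanced nontrivial bipartition of a tree."""
    n = len(leaf_labels(st))
    best = min(bipartitions(st),
               key=lambda bp: abs(len(bp.side1) - n / 2))
    return best


def run_demonstrations(seed: int, fourpoint_genes: int = 50_000,
                      ksubset_genes: int = 10_000) -> dict:
    """Run the adversary, exactly-k-subset and 4-taxon additivity
    demonstrations; returns a nested dict of measured quantities with
    pass/fail flags."""
    return {
        "adversary": _adversary_demo(seed),
        "ksubset": _ksubset_demo(seed + 1, m=ksubset_genes),
        "fourpoint": _fourpoint_demo(seed + 2, m=fourpoint_genes),
    }


def format_demo_report(report: dict) -> str:
    lines = ["Identifiability and additivity demonstrations",
             "=" * 46]
    adv = report["adversary"]
    lines.append("\n[adversary filter] retain a gene iff it matches a wrong "
                 "target topology")
    for k, v in adv.items():
        lines.append(f"  {k}: {v}")
    ks = report["ksubset"]
    lines.append("\n[exactly-k subsets] central bipartition coverage on a "
                 "caterpillar (n > 2k)")
    for k, v in ks.items():
        lines.append(f"  {k}: {v}")
    lines.append("\n[4-taxon additivity] conditional expected internode "
                 "distances under i.i.d. deletion")
    for p, vals in report["fourpoint"].items():
        lines.append(f"  p_miss = {p}:")
        for k, v in vals.items():
            lines.append(f"    {k}: {v}")
    return "\n".join(lines)
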