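"""Self-contained validation experiments on synthetic data.

Genome-scale claims about a motif-cluster predictor cannot be checked on a
laptop, but the machinery can: these protocols plant clusters with known
feature laws, run the full train/decode/evaluate pipeline, and measure how
well parameters and clusters are recovered.  Each function takes a seed and
returns plain numbers; the problem sizes are chosen so a full run finishes
in minutes on one core while leaving comfortable statistical margin.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binomtest, spearmanr

from .evaluation import (
    crossval_two_fold,
    make_footprints,
    roc_from_overlap,
    sample_negative_windows,
    score_bin_overlap,
)
from .hmm_core import HmmState
from .io_formats import GenomicInterval, RegionType, exon_ext_mask, merge_intervals
from .pipeline import Dataset, featurize_dataset, predict, scan_dataset, train_model
from .simulate import (
    SimSpec,
    accessibility_pmf,
    conservation_pmf,
    recovery_report,
    simulate_dataset,
    simulate_label_paths,
    simulate_labeled_corpus,
)
from .training import (
    TrainingConfig,
    estimate_transitions,
    train,
)

__all__ = [
    "emission_recovery",
    "transition_recovery",
    "planted_cluster_recovery",
    "feature_ablation",
    "score_bin_monotonicity",
    "crossval_consistency",
]


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


# ---------------------------------------------------------------------------
# emission & transition parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class EmissionRecoveryResult:
    tv_by_component: dict[str, float]
    max_tv: float
    max_transition_error: float


def emission_recovery(
    seed: int, n_sites_per_side: int = 50_000
) -> EmissionRecoveryResult:
    """Train on a feature-level corpus and compare every estimated emission
    distribution with its exact generating law (total variation), plus
    transition MLEs against known generating rates."""
    spec = SimSpec(seed=_derive_seed(seed, 1))
    rng = np.random.default_rng(spec.seed)
    corpus = simulate_labeled_corpus(
        spec, n_pos_sites=n_sites_per_side, n_neg_sites=n_sites_per_side, rng=rng
    )
    config = TrainingConfig()
    model = train(corpus, feature_set=("d", "c", "a"), config=config)

    import io as _io

    from Bio import Phylo as _Phylo

    from .io_formats import PhyloTree

    tree = PhyloTree.from_biopython(_Phylo.read(_io.StringIO(spec.tree_newick), "newick"))
    truths = {
        "d+": spec.cluster_spacing.censored_masses(config.d_cens),
        "d-": spec.background_spacing.censored_masses(config.d_cens),
        "c+": conservation_pmf(tree, spec.ref_species, spec.p_keep_pos, config.bins_c),
        "c-": conservation_pmf(tree, spec.ref_species, spec.p_keep_neg, config.bins_c),
        "a+": accessibility_pmf(*spec.acc_pos, config.bins_a),
        "a-": accessibility_pmf(*spec.acc_neg, config.bins_a),
    }
    estimates = {
        "d+": model.dists[("d", "+")].masses,
        "d-": model.dists[("d", "-")].masses,
        # the corpus places every site in the intron stratum
        "c+": model.dists[("c", "+", RegionType.INTRON)].masses,
        "c-": model.dists[("c", "-", RegionType.INTRON)].masses,
        "a+": model.dists[("a", "+")].masses,
        "a-": model.dists[("a", "-")].masses,
    }
    tv = {
        k: 0.5 * float(np.abs(estimates[k] - truths[k]).sum()) for k in truths
    }
    max_trans_err = transition_recovery(seed)
    return EmissionRecoveryResult(
        tv_by_component=tv,
        max_tv=max(tv.values()),
        max_transition_error=max_trans_err,
    )


def transition_recovery(seed: int, n_sequences: int = 4000, mean_length: float = 15.0) -> float:
    """Max absolute error of transition MLEs against generating rates."""
    rng = np.random.default_rng(_derive_seed(seed, 2))
    gen = {"+": 0.90, "-": 0.97}
    init_plus = 0.2
    labels = simulate_label_paths(gen, init_plus, n_sequences, mean_length, rng)
    trans, initial = estimate_transitions(labels, pseudocount=1.0)
    errors = [
        abs(trans[(HmmState.PLUS, HmmState.PLUS)] - gen["+"]),
        abs(trans[(HmmState.PLUS, HmmState.I_MINUS)] - (1 - gen["+"])),
        abs(trans[(HmmState.MINUS, HmmState.MINUS)] - gen["-"]),
        abs(trans[(HmmState.MINUS, HmmState.I_PLUS)] - (1 - gen["-"])),
        # internal-initiation states inherit their side's continuation rate
        abs(trans[(HmmState.I_PLUS, HmmState.PLUS)] - gen["+"]),
        abs(trans[(HmmState.I_MINUS, HmmState.MINUS)] - gen["-"]),
        abs(initial[HmmState.S_PLUS] - init_plus),
    ]
    return max(errors)


# ---------------------------------------------------------------------------
# planted-cluster recovery (train / tune / test)
# ---------------------------------------------------------------------------

@dataclass
class PlantedRecoveryResult:
    precision: float
    recall: float
    f1: float
    threshold: float
    n_small_candidates_with_filter: int


def _run_replicate(spec: SimSpec, min_sites: int = 3, min_score=None):
    data = simulate_dataset(spec)
    ds = Dataset.from_sim(data)
    sites = scan_dataset(ds)
    feats = featurize_dataset(ds, sites)
    return data, ds, sites, feats


def planted_cluster_recovery(seed: int, n_genes: int = 60) -> PlantedRecoveryResult:
    """Three-replicate protocol: train on one simulated transcriptome, pick
    the F1-maximizing score threshold on a second, report precision/recall
    on a third.  Also verifies the >= 3-site filter leaves no 1-2-site calls."""
    base = SimSpec(seed=0, n_genes=n_genes, cluster_rate=2.0)
    specs = [replace(base, seed=_derive_seed(seed, 10 + i)) for i in range(3)]
    train_data, train_ds, train_sites, train_feats = _run_replicate(specs[0])
    model = train_model(train_ds, train_sites, train_feats)

    def calls_for(spec_idx: int):
        data, ds, sites, feats = _run_replicate(specs[spec_idx])
        return data, predict(model, sites, feats, min_sites=3)

    tune_data, tune_calls = calls_for(1)
    thresholds = sorted({c.score for c in tune_calls})
    best_thr, best_f1 = 0.0, -1.0
    for thr in thresholds:
        rep = recovery_report(
            tune_data.truth.clusters, [c for c in tune_calls if c.score >= thr]
        )
        if rep.f1 is not None and rep.f1 > best_f1:
            best_f1, best_thr = rep.f1, thr

    test_data, test_calls = calls_for(2)
    kept = [c for c in test_calls if c.score >= best_thr]
    rep = recovery_report(test_data.truth.clusters, kept)
    n_small = sum(1 for c in kept if c.n_sites < 3)
    return PlantedRecoveryResult(
        precision=rep.precision if rep.precision is not None else 0.0,
        recall=rep.recall,
        f1=rep.f1 if rep.f1 is not None else 0.0,
        threshold=best_thr,
        n_small_candidates_with_filter=n_small,
    )


# ---------------------------------------------------------------------------
# feature ablation (full vs spacing-only)
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    auc_full: list[float]
    auc_d_only: list[float]
    n_full_wins_or_ties: int
    sign_test_p: float


def _footprint_eval(ds: Dataset, data, calls, seed: int):
    footprints = make_footprints(
        ds.clip, ph_min=1, seq_lengths={k: len(v) for k, v in ds.sequences.items()}
    )
    tag_free = _tag_free_regions(ds)
    negatives = sample_negative_windows(
        tag_free, length=100, n=max(30, len(footprints)), seed=seed
    )
    return roc_from_overlap(calls, footprints, negatives)


def _tag_free_regions(ds: Dataset) -> list[GenomicInterval]:
    out = []
    for t in ds.transcripts:
        mask = exon_ext_mask(t, 1000)
        if any(
            any(m.overlaps(c.interval) for m in mask) for c in ds.clip
        ):
            continue
        out.extend(mask)
    if not out:  # no fully tag-free gene: use the mask pieces without tags
        for t in ds.transcripts:
            for m in exon_ext_mask(t, 1000):
                if not any(m.overlaps(c.interval) for c in ds.clip):
                    out.append(m)
    return merge_intervals(out)


def feature_ablation(seed: int, n_seeds: int = 10, n_genes: int = 25) -> AblationResult:
    """AUC of the full model vs the spacing-only model on paired replicates.

    For each of ``n_seeds`` paired simulations, trains both models on one
    replicate and evaluates footprint/background discrimination on a second;
    the sign test asks whether the full model wins (ties count for neither
    side and degrade the test, not the tally of non-losses)."""
    auc_full, auc_d = [], []
    base = SimSpec(seed=0, n_genes=n_genes, cluster_rate=1.5,
                   sites_per_cluster_extra_mean=4.0)
    for i in range(n_seeds):
        train_spec = replace(base, seed=_derive_seed(seed, 100 + 2 * i))
        test_spec = replace(base, seed=_derive_seed(seed, 101 + 2 * i))
        _, train_ds, train_sites, train_feats = _run_replicate(train_spec)
        test_data, test_ds, test_sites, test_feats = _run_replicate(test_spec)
        for feature_set, bucket in ((("d", "c", "a"), auc_full), (("d",), auc_d)):
            model = train_model(train_ds, train_sites, train_feats, feature_set=feature_set)
            calls = predict(model, test_sites, test_feats, min_sites=3)
            roc = _footprint_eval(test_ds, test_data, calls, seed=_derive_seed(seed, 999 + i))
            bucket.append(roc.auc)
    wins = sum(1 for f, d in zip(auc_full, auc_d) if f > d)
    losses = sum(1 for f, d in zip(auc_full, auc_d) if f < d)
    non_losses = n_seeds - losses
    if wins + losses:
        p = binomtest(wins, wins + losses, 0.5, alternative="greater").pvalue
    else:
        p = 1.0
    return AblationResult(
        auc_full=auc_full,
        auc_d_only=auc_d,
        n_full_wins_or_ties=non_losses,
        sign_test_p=float(p),
    )


# ---------------------------------------------------------------------------
# score-bin overlap monotonicity
# ---------------------------------------------------------------------------

@dataclass
class ScoreBinResult:
    fractions: list[float]
    spearman_rho: float
    spearman_p: float


def score_bin_monotonicity(seed: int, n_genes: int = 400, n_bins: int = 9) -> ScoreBinResult:
    """Footprint-overlap fraction per score bin; Spearman rank trend.

    Planted clusters carry heterogeneous strength (affinity), which couples
    cluster confidence to CLIP peak height: weak clusters rarely reach the
    footprint peak-height cutoff, so overlap should rise with score."""
    spec = SimSpec(
        seed=_derive_seed(seed, 3),
        n_genes=n_genes,
        cluster_rate=2.5,
        cluster_strength_range=(0.1, 1.0),
    )
    data, ds, sites, feats = _run_replicate(spec)
    model = train_model(ds, sites, feats)
    calls = predict(model, sites, feats, min_sites=3)
    footprints = make_footprints(
        ds.clip, ph_min=15, seq_lengths={k: len(v) for k, v in ds.sequences.items()}
    )
    scores = np.array([c.score for c in calls])
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(scores, qs))
    edges[-1] += 1e-9
    table = score_bin_overlap(calls, footprints, edges)
    defined = table.dropna(subset=["fraction_overlap"])
    rho, p = spearmanr(defined.index.values, defined["fraction_overlap"].values)
    return ScoreBinResult(
        fractions=list(table["fraction_overlap"].values),
        spearman_rho=float(rho),
        spearman_p=float(p),
    )


# ---------------------------------------------------------------------------
# two-fold cross-validation consistency
# ---------------------------------------------------------------------------

@dataclass
class CrossvalResult:
    r_squared: float
    n_shared: int


def crossval_consistency(seed: int, n_genes: int = 250) -> CrossvalResult:
    """Out-of-fold vs full-model cluster score agreement (squared Pearson)."""
    spec = SimSpec(seed=_derive_seed(seed, 4), n_genes=n_genes, cluster_rate=2.0)
    data, ds, sites, feats = _run_replicate(spec)
    gene_ids = [t.id for t in ds.transcripts]

    def train_on(genes):
        sub = ds.subset(genes)
        sub_sites = {k: v for k, v in sites.items() if k in sub.sequences}
        sub_feats = {k: v for k, v in feats.items() if k in sub.sequences}
        return train_model(sub, sub_sites, sub_feats)

    def predict_on(model, genes):
        seqs = {
            t.interval.seq_id for t in ds.transcripts if t.id in set(genes)
        }
        sub_sites = {k: v for k, v in sites.items() if k in seqs}
        sub_feats = {k: v for k, v in feats.items() if k in seqs}
        return predict(model, sub_sites, sub_feats, min_sites=3)

    report = crossval_two_fold(
        gene_ids, seed=_derive_seed(seed, 5), train_on=train_on, predict_on=predict_on
    )
    return CrossvalResult(r_squared=report.r_squared, n_shared=report.n_shared)
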