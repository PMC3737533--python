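"""Evaluation of predicted clusters against CLIP data.

The protocol mirrors how such predictions are benchmarked in vivo: the
+-50 nt "footprint" around each robust CLIP cluster peak is the positive
example set; length-matched windows sampled uniformly from tag-free exon+ext
sequence are the negatives.  An example counts as predicted positive when a
cluster above the score threshold overlaps it by at least 1 nt; sweeping the
threshold yields the ROC.  Gene-level two-fold cross-validation checks that
out-of-fold cluster scores agree with full-model scores.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score, roc_curve

from .hmm_core import ClusterCall
from .io_formats import ClipCluster, GenomicInterval

__all__ = [
    "RocCurve",
    "make_footprints",
    "sample_negative_windows",
    "roc_from_overlap",
    "split_genes_two_fold",
    "crossval_two_fold",
    "CrossValReport",
    "score_bin_overlap",
    "max_overlap_scores",
]

FOOTPRINT_HALF_WIDTH = 50


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered by descending threshold, with AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def sensitivity_at_specificity(self, target: float) -> float:
        """Highest sensitivity among points with specificity >= target."""
        ok = self.specificity >= target
        if not ok.any():
            return 0.0
        return float(self.sensitivity[ok].max())


def make_footprints(
    clip_clusters: Sequence[ClipCluster],
    ph_min: int,
    half_width: int = FOOTPRINT_HALF_WIDTH,
    seq_lengths: Mapping[str, int] | None = None,
    location_filter: Callable[[ClipCluster], bool] | None = None,
) -> list[GenomicInterval]:
    """Footprint intervals around qualifying CLIP peaks.

    +-``half_width`` nt around the peak, inclusive on both sides, i.e. the
    half-open interval [peak - hw, peak + hw + 1) of width 2*hw + 1;
    truncated (with a warning) at sequence bounds when ``seq_lengths`` is
    given.
    """
    import logging

    logger = logging.getLogger(__name__)
    out = []
    for cl in clip_clusters:
        if cl.peak_height < ph_min:
            continue
        if location_filter is not None and not location_filter(cl):
            continue
        seq_id = cl.interval.seq_id
        start = cl.peak_position - half_width
        end = cl.peak_position + half_width + 1
        limit = None if seq_lengths is None else seq_lengths.get(seq_id)
        t_start = max(0, start)
        t_end = min(end, limit) if limit is not None else end
        if (t_start, t_end) != (start, end):
            logger.warning(
                "footprint at %s:%d truncated to sequence bounds", seq_id, cl.peak_position
            )
        out.append(GenomicInterval(seq_id, t_start, t_end, cl.interval.strand))
    return out


def sample_negative_windows(
    tag_free_regions: Sequence[GenomicInterval],
    length: int = 100,
    n: int = 1000,
    seed: int = 0,
) -> list[GenomicInterval]:
    """``n`` windows of ``length`` nt, uniform over all eligible placements.

    Placements are the start offsets at which a window fits inside a region;
    they are sampled without replacement, so the same seed always yields the
    same (sorted) sample and an infeasible request fails with the achievable
    count.
    """
    eligible = [r for r in tag_free_regions if r.length >= length]
    counts = np.array([r.length - length + 1 for r in eligible], dtype=np.int64)
    total = int(counts.sum())
    if total < n:
        raise ValueError(
            f"cannot sample {n} windows of {length} nt: only {total} placements available"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(total, size=n, replace=False)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    region_idx = np.searchsorted(np.cumsum(counts), picks, side="right")
    out = []
    for p, ri in zip(picks, region_idx):
        r = eligible[ri]
        start = r.start + int(p - offsets[ri])
        out.append(GenomicInterval(r.seq_id, start, start + length, r.strand))
    out.sort(key=lambda iv: (iv.seq_id, iv.start))
    return out


def max_overlap_scores(
    examples: Sequence[GenomicInterval],
    clusters: Sequence[ClusterCall],
) -> np.ndarray:
    """Per-example score: max over clusters overlapping by >= 1 nt, else -inf."""
    by_seq: dict[str, list[ClusterCall]] = {}
    for c in clusters:
        by_seq.setdefault(c.interval.seq_id, []).append(c)
    for cs in by_seq.values():
        cs.sort(key=lambda c: c.interval.start)
    scores = np.full(len(examples), -np.inf)
    for i, ex in enumerate(examples):
        best = -np.inf
        for c in by_seq.get(ex.seq_id, []):
            if c.interval.start >= ex.end:
                break
            if c.interval.end > ex.start:
                best = max(best, c.score)
        scores[i] = best
    return scores


def roc_from_overlap(
    clusters: Sequence[ClusterCall],
    positives: Sequence[GenomicInterval],
    negatives: Sequence[GenomicInterval],
) -> RocCurve:
    """ROC over footprint/background examples scored by overlapping clusters."""
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative example")
    pos_scores = max_overlap_scores(positives, clusters)
    neg_scores = max_overlap_scores(negatives, clusters)
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    finite = scores[np.isfinite(scores)]
    floor = (finite.min() - 1.0) if finite.size else -1.0
    scores = np.where(np.isfinite(scores), scores, floor)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
    )


def split_genes_two_fold(gene_ids: Sequence[str], seed: int) -> tuple[list[str], list[str]]:
    """Random gene-level halves: union = input, intersection empty."""
    genes = list(gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cross-validate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    half = len(genes) // 2
    a = sorted(genes[i] for i in order[:half])
    b = sorted(genes[i] for i in order[half:])
    return a, b


@dataclass
class CrossValReport:
    """Agreement between out-of-fold and full-model cluster scores."""

    fold_a: list[str]
    fold_b: list[str]
    r_squared: float
    n_shared: int


def crossval_two_fold(
    gene_ids: Sequence[str],
    seed: int,
    train_on: Callable[[Sequence[str]], object],
    predict_on: Callable[[object, Sequence[str]], Sequence[ClusterCall]],
    full_model: object | None = None,
) -> CrossValReport:
    """Gene-level 2-fold cross-validation of cluster scores.

    Trains on each half (via ``train_on``) and predicts on the other half;
    the pooled out-of-fold scores are compared with full-model scores on
    clusters matched by coordinate identity, via squared Pearson
    correlation.  A gene never appears in its own training fold.
    """
    fold_a, fold_b = split_genes_two_fold(gene_ids, seed)
    model_a = train_on(fold_a)
    model_b = train_on(fold_b)
    oof: dict[tuple[str, int, int], float] = {}
    for model, test_genes in ((model_a, fold_b), (model_b, fold_a)):
        for call in predict_on(model, test_genes):
            iv = call.interval
            oof[(iv.seq_id, iv.start, iv.end)] = call.score
    if full_model is None:
        full_model = train_on(list(gene_ids))
    full: dict[tuple[str, int, int], float] = {}
    for call in predict_on(full_model, list(gene_ids)):
        iv = call.interval
        full[(iv.seq_id, iv.start, iv.end)] = call.score
    shared = sorted(set(oof) & set(full))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared clusters; cannot correlate")
    x = np.array([oof[k] for k in shared])
    y = np.array([full[k] for k in shared])
    r, _ = pearsonr(x, y)
    return CrossValReport(
        fold_a=fold_a, fold_b=fold_b, r_squared=float(r**2), n_shared=len(shared)
    )


def score_bin_overlap(
    clusters: Sequence[ClusterCall],
    footprints: Sequence[GenomicInterval],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-score-bin footprint overlap fractions and cumulative counts.

    Clusters are binned by score into ``[e_i, e_{i+1})`` (last bin closed on
    the right); per bin the fraction overlapping any footprint by >= 1 nt is
    reported (NaN for empty bins), plus the cumulative number of clusters
    with score >= the bin's lower edge.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    scores = np.array([c.score for c in clusters])
    overlap_flags = np.zeros(len(clusters), dtype=bool)
    by_seq: dict[str, list[GenomicInterval]] = {}
    for fp in footprints:
        by_seq.setdefault(fp.seq_id, []).append(fp)
    for i, c in enumerate(clusters):
        overlap_flags[i] = any(
            fp.start < c.interval.end and c.interval.start < fp.end
            for fp in by_seq.get(c.interval.seq_id, [])
        )
    idx = np.digitize(scores, edges) - 1
    idx = np.clip(idx, -1, len(edges) - 2)
    idx[scores == edges[-1]] = len(edges) - 2  # close last bin on the right
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        n_overlap = int(overlap_flags[mask].sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": n,
                "n_overlap": n_overlap,
                "fraction_overlap": (n_overlap / n) if n else np.nan,
                "cumulative_n": int((scores >= edges[b]).sum()),
            }
        )
    return pd.DataFrame(rows)
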