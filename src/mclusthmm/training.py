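"""Supervised model estimation from CLIP-labeled site sets.

Training is fully supervised: positive regions are robust, nonrepetitive
CLIP tag clusters (peak height >= ``ph_min``) inside the exon+ext mask,
negative regions are the exon+ext sequences of genes carrying *no* CLIP tags
anywhere in their mask.  Each training region contributes one ordered site
sequence with a constant label; every motif site inside a positive cluster
interval is labeled '+', sites in tagged genes but outside clusters are
excluded from training altogether (neither '+' nor '-').

Emission distributions are nonparametric: smoothed histograms on fixed bins
(spacing: unit bins up to the censoring point, whose last bin absorbs all
censored distances; conservation and accessibility: equal-width bins on
[0, 1]).  Conservation is stratified by region on both sides; spacing and
accessibility are region-pooled.  Transition and initial probabilities are
smoothed maximum-likelihood counts over the state paths induced by the
labels.  There is no Baum-Welch step: all parameters come from labeled
counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import SiteFeatures, compute_spacing
from .hmm_core import (
    ALLOWED_EDGES,
    INITIAL_STATES,
    HmmModel,
    HmmState,
)
from .io_formats import (
    ClipCluster,
    GenomicInterval,
    RegionType,
    TranscriptModel,
    exon_ext_mask,
    intervals_cover,
    merge_intervals,
)
from .motif_scan import MotifSite

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "FeatureDistribution",
    "LabeledSiteSequence",
    "build_training_sets",
    "build_labeled_sequences",
    "estimate_distribution",
    "labels_to_states",
    "estimate_transitions",
    "train",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of training-set construction and emission estimation.

    ``ph_min`` is the CLIP peak-height cutoff for positive clusters (15 was
    used for Nova, 7 for Mbnl -- roughly the median peak height near
    validated target exons); ``ext`` the intronic extension of the exon mask
    in nt; ``d_cens`` the spacing censoring point; ``bins_c``/``bins_a`` the
    histogram resolution of the conservation/accessibility emissions; and
    ``pseudocount`` the additive smoothing constant keeping every bin
    strictly positive.
    """

    ph_min: int = 15
    ext: int = 1000
    exclude_repetitive_positives: bool = True
    d_cens: int = 30
    bins_c: int = 20
    bins_a: int = 20
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.ph_min < 1:
            raise ValueError("ph_min must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.d_cens < 2 or self.bins_c < 2 or self.bins_a < 2:
            raise ValueError("binning too coarse")


@dataclass
class FeatureDistribution:
    """Smoothed binned probability mass over one feature's value range.

    For spacing, ``bin_edges`` are the integers 1..d_cens+1 (unit bins, the
    last absorbing every censored distance); for conservation and
    accessibility, equal-width edges on [0, 1].  Masses are strictly
    positive and sum to 1.
    """

    feature: str
    bin_edges: np.ndarray
    masses: np.ndarray
    stratum: RegionType | None = None

    def __post_init__(self) -> None:
        if self.feature not in ("d", "c", "a"):
            raise ValueError(f"unknown feature {self.feature!r}")
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.masses) != len(self.bin_edges) - 1:
            raise ValueError("need exactly one mass per bin")
        if not np.all(self.masses > 0):
            raise ValueError("every bin mass must be > 0 (smoothing)")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.masses)

    def bin_index(self, value: float) -> int:
        if self.feature == "d":
            d = int(value)
            lo = int(self.bin_edges[0])
            hi = int(self.bin_edges[-1]) - 1  # censoring point
            if d < lo:
                raise ValueError(f"spacing {d} below bin range")
            return min(d, hi) - lo
        if not (self.bin_edges[0] <= value <= self.bin_edges[-1]):
            raise ValueError(f"value {value} outside [{self.bin_edges[0]}, {self.bin_edges[-1]}]")
        idx = int(np.searchsorted(self.bin_edges, value, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)

    def pmf(self, value: float) -> float:
        return float(self.masses[self.bin_index(value)])

    def logpmf(self, value: float) -> float:
        """Base-2 log probability mass of the bin containing ``value``."""
        return float(np.log2(self.masses[self.bin_index(value)]))

    def total_variation(self, other: "FeatureDistribution") -> float:
        if self.n_bins != other.n_bins:
            raise ValueError("bin structures differ")
        return 0.5 * float(np.abs(self.masses - other.masses).sum())


@dataclass
class LabeledSiteSequence:
    """One training region's ordered site features with per-site labels.

    Labels are '+' or '-'; by construction of the training sets they are
    constant within one region, but mixed sequences are accepted (the
    label-to-state mapping is defined for them).
    """

    features: list[SiteFeatures]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("one label per site required")
        if any(l not in ("+", "-") for l in self.labels):
            raise ValueError("labels must be '+' or '-'")


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

def build_training_sets(
    clip_clusters: Sequence[ClipCluster],
    transcripts: Sequence[TranscriptModel],
    repeats: Sequence[GenomicInterval] = (),
    config: TrainingConfig = TrainingConfig(),
) -> tuple[list[GenomicInterval], dict[str, list[GenomicInterval]]]:
    """Positive cluster intervals and negative gene masks.

    Positives: CLIP clusters with PH >= ``ph_min``, fully inside some gene's
    exon+ext mask and (by default) not overlapping any repeat interval by
    even 1 nt.  Negatives: the exon+ext masks of genes that are wholly
    tag-free -- no CLIP cluster anywhere in the gene body or its ``ext``
    flanks, regardless of peak height.  A gene with a tag outside the mask
    (e.g. deep in an intron) is still not tag-free and is excluded.

    Returns ``(positive_intervals, {gene_id: mask_intervals})``.
    """
    masks = {t.id: exon_ext_mask(t, config.ext) for t in transcripts}
    all_mask = merge_intervals(iv for m in masks.values() for iv in m)
    merged_repeats = merge_intervals(repeats) if repeats else []

    positives = []
    for cl in clip_clusters:
        if cl.peak_height < config.ph_min:
            continue
        if not intervals_cover(all_mask, cl.interval):
            continue
        if config.exclude_repetitive_positives and any(
            r.overlaps(cl.interval) for r in merged_repeats
        ):
            continue
        positives.append(cl.interval)

    negatives = {}
    for t in transcripts:
        iv = t.interval
        span = GenomicInterval(
            iv.seq_id, max(0, iv.start - config.ext), iv.end + config.ext, iv.strand
        )
        tagged = any(span.overlaps(cl.interval) for cl in clip_clusters)
        if not tagged:
            negatives[t.id] = masks[t.id]

    if not positives:
        raise ValueError("no positive training regions; model untrainable")
    if not negatives:
        raise ValueError("no negative training regions; model untrainable")
    return positives, negatives


def build_labeled_sequences(
    positive_regions: Sequence[GenomicInterval],
    negative_regions: Mapping[str, Sequence[GenomicInterval]] | Sequence[Sequence[GenomicInterval]],
    sites_by_seq: Mapping[str, Sequence[MotifSite]],
    feats_by_seq: Mapping[str, Sequence[SiteFeatures]],
    config: TrainingConfig = TrainingConfig(),
) -> list[LabeledSiteSequence]:
    """Turn training regions into labeled site sequences.

    Spacing is recomputed *within* each training region (the first site of a
    region carries the sentinel d = 0; later sites measure to their
    predecessor inside the region); conservation, accessibility and region
    stratum carry over from the global featurization.  Regions without sites
    contribute nothing.  Positive clusters that would be repetitive are
    expected to have been filtered upstream.
    """
    out = []

    def region_sequence(seq_id: str, intervals: Sequence[GenomicInterval], label: str):
        sites = sites_by_seq.get(seq_id, [])
        feats = feats_by_seq.get(seq_id, [])
        merged = merge_intervals(intervals)
        picked = [
            (s, f)
            for s, f in zip(sites, feats)
            if intervals_cover(merged, s.interval)
        ]
        if not picked:
            return
        if config.exclude_repetitive_positives and label == "+":
            picked = [(s, f) for s, f in picked if not s.is_repetitive]
            if not picked:
                return
        ds = compute_spacing([s for s, _ in picked], d_cens=config.d_cens)
        out.append(
            LabeledSiteSequence(
                features=[replace(f, d=d) for (_, f), d in zip(picked, ds)],
                labels=[label] * len(picked),
            )
        )

    for iv in positive_regions:
        region_sequence(iv.seq_id, [iv], "+")
    neg_iter = (
        negative_regions.values()
        if isinstance(negative_regions, Mapping)
        else negative_regions
    )
    for mask in neg_iter:
        if mask:
            region_sequence(mask[0].seq_id, mask, "-")
    return out


# ---------------------------------------------------------------------------
# emission estimation
# ---------------------------------------------------------------------------

def estimate_distribution(
    values: Sequence[float],
    feature: str,
    bins: int = 20,
    pseudocount: float = 1.0,
    d_cens: int = 30,
    stratum: RegionType | None = None,
) -> FeatureDistribution:
    """Smoothed histogram estimate of one feature's distribution.

    mass_i = (count_i + pseudocount) / (N + B * pseudocount), so every bin
    stays strictly positive.  Spacing values must lie in [1, d_cens]
    (censoring happens upstream); conservation/accessibility in [0, 1].
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate a distribution from zero values")
    if feature == "d":
        if np.any((values < 1) | (values > d_cens)):
            raise ValueError(f"spacing values outside [1, {d_cens}]")
        edges = np.arange(1, d_cens + 2, dtype=float)
        counts, _ = np.histogram(values, bins=edges)
    elif feature in ("c", "a"):
        if np.any((values < 0) | (values > 1)):
            raise ValueError("values outside [0, 1]")
        edges = np.linspace(0.0, 1.0, bins + 1)
        counts, _ = np.histogram(values, bins=edges)
    else:
        raise ValueError(f"unknown feature {feature!r}")
    masses = (counts + pseudocount) / (values.size + len(counts) * pseudocount)
    return FeatureDistribution(
        feature=feature, bin_edges=edges, masses=masses, stratum=stratum
    )


# ---------------------------------------------------------------------------
# transition estimation
# ---------------------------------------------------------------------------

def labels_to_states(labels: Sequence[str]) -> list[HmmState]:
    """The unique state path induced by a label sequence.

    First site: S+ or S-.  Later sites: a label change '-'->'+' enters I+,
    '+'->'-' enters I-; no change stays in '+'/'-'.
    """
    if not labels:
        return []
    states = [HmmState.S_PLUS if labels[0] == "+" else HmmState.S_MINUS]
    for prev, cur in zip(labels, labels[1:]):
        if cur == "+":
            states.append(HmmState.PLUS if prev == "+" else HmmState.I_PLUS)
        else:
            states.append(HmmState.MINUS if prev == "-" else HmmState.I_MINUS)
    return states


def estimate_transitions(
    labeled_sequences: Iterable[LabeledSiteSequence | Sequence[str]],
    pseudocount: float = 1.0,
) -> tuple[dict[tuple[HmmState, HmmState], float], dict[HmmState, float]]:
    """Smoothed MLE of transition and initial probabilities.

    Counts come from the state paths induced by the labels; each allowed
    edge receives ``pseudocount`` additional mass and rows are normalized
    per source state.  Disallowed edges have probability exactly 0 (they are
    simply absent from the returned mapping).
    """
    edge_counts: dict[tuple[HmmState, HmmState], float] = {
        (src, dst): 0.0 for src, dsts in ALLOWED_EDGES.items() for dst in dsts
    }
    init_counts: dict[HmmState, float] = {s: 0.0 for s in INITIAL_STATES}
    for seq in labeled_sequences:
        labels = seq.labels if isinstance(seq, LabeledSiteSequence) else list(seq)
        states = labels_to_states(labels)
        if not states:
            continue
        init_counts[states[0]] += 1.0
        for a, b in zip(states, states[1:]):
            assert b in ALLOWED_EDGES[a], "label-induced edge outside allowed set"
            edge_counts[(a, b)] += 1.0
    trans = {}
    for src, dsts in ALLOWED_EDGES.items():
        total = sum(edge_counts[(src, d)] for d in dsts) + pseudocount * len(dsts)
        for d in dsts:
            trans[(src, d)] = (edge_counts[(src, d)] + pseudocount) / total
    total0 = sum(init_counts.values()) + pseudocount * len(init_counts)
    initial = {s: (c + pseudocount) / total0 for s, c in init_counts.items()}
    return trans, initial


# ---------------------------------------------------------------------------
# full training
# ---------------------------------------------------------------------------

def train(
    labeled_sequences: Sequence[LabeledSiteSequence],
    feature_set: Sequence[str] = ("d", "c", "a"),
    config: TrainingConfig = TrainingConfig(),
) -> HmmModel:
    """Assemble a six-state model from labeled site sequences.

    Emissions: '+'/'-' spacing distributions from the non-initial sites of
    each side (initial sites carry the sentinel d = 0 and belong to the
    degenerate components), conservation stratified by region on both sides
    (a stratum with zero sites on one side falls back to that side's pooled
    distribution with a logged warning), accessibility pooled over sites
    where it is present.  Transitions and initial probabilities from the
    label-induced state paths.
    """
    feature_set = tuple(feature_set)
    if not feature_set or not set(feature_set) <= {"d", "c", "a"}:
        raise ValueError(f"invalid feature set {feature_set}")

    d_vals: dict[str, list[int]] = {"+": [], "-": []}
    c_vals: dict[tuple[str, RegionType], list[float]] = {}
    c_pool: dict[str, list[float]] = {"+": [], "-": []}
    a_vals: dict[str, list[float]] = {"+": [], "-": []}
    for seq in labeled_sequences:
        for i, (f, label) in enumerate(zip(seq.features, seq.labels)):
            if i > 0:
                d_vals[label].append(f.d)
            c_vals.setdefault((label, f.region), []).append(f.c)
            c_pool[label].append(f.c)
            if f.a is not None:
                a_vals[label].append(f.a)

    dists: dict[tuple, FeatureDistribution] = {}
    pc = config.pseudocount
    if "d" in feature_set:
        for sign in "+-":
            if not d_vals[sign]:
                raise ValueError(f"no non-initial '{sign}' sites to estimate spacing from")
            dists[("d", sign)] = estimate_distribution(
                d_vals[sign], "d", pseudocount=pc, d_cens=config.d_cens
            )
    if "c" in feature_set:
        pooled = {}
        for sign in "+-":
            if not c_pool[sign]:
                raise ValueError(f"no '{sign}' sites to estimate conservation from")
            pooled[sign] = estimate_distribution(
                c_pool[sign], "c", bins=config.bins_c, pseudocount=pc
            )
        for sign in "+-":
            for region in RegionType:
                vals = c_vals.get((sign, region), [])
                if vals:
                    dists[("c", sign, region)] = estimate_distribution(
                        vals, "c", bins=config.bins_c, pseudocount=pc, stratum=region
                    )
                else:
                    logger.warning(
                        "no '%s' sites in stratum %s; falling back to pooled distribution",
                        sign,
                        region.value,
                    )
                    dists[("c", sign, region)] = replace(pooled[sign], stratum=region)
    if "a" in feature_set:
        for sign in "+-":
            if not a_vals[sign]:
                raise ValueError(f"no '{sign}' sites with accessibility values")
            dists[("a", sign)] = estimate_distribution(
                a_vals[sign], "a", bins=config.bins_a, pseudocount=pc
            )

    trans, initial = estimate_transitions(labeled_sequences, pseudocount=pc)
    return HmmModel(
        feature_set=feature_set,
        dists=dists,
        log_trans={k: float(np.log2(v)) for k, v in trans.items()},
        log_initial={k: float(np.log2(v)) for k, v in initial.items()},
        log_base=2.0,
        config={
            "ph_min": config.ph_min,
            "ext": config.ext,
            "d_cens": config.d_cens,
            "bins_c": config.bins_c,
            "bins_a": config.bins_a,
            "pseudocount": config.pseudocount,
        },
    )
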