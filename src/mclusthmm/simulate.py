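"""Synthetic toy transcriptomes with planted motif clusters.

The generator emulates the statistical structure the predictor exploits:
bound clusters are runs of >= 3 consensus matches with tight spacing, high
per-species motif retention (hence high branch length score) and high
accessibility, while background sites are sparse, poorly retained and less
accessible.  CLIP-like peaks are placed over the planted clusters.  Every
draw flows from one seeded generator, so a given seed reproduces the
dataset byte-for-byte.

What it does *not* emulate: phylogenetically correlated motif loss (species
retain or lose motifs i.i.d. given the label), alignment indels (rows are
substitution-only), read-level CLIP noise, and overlapping genes.  Passing
recovery tests on this generator therefore demonstrates correctness of
estimation and decoding under the model's assumptions, not robustness to
every property of real genomes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .features import SiteFeatures
from .hmm_core import ClusterCall
from .io_formats import (
    AccessibilityTrack,
    AlignmentBlock,
    ClipCluster,
    GenomicInterval,
    PhyloTree,
    TranscriptModel,
    build_region_segments,
    write_bed,
    write_bed12,
    write_bedgraph,
    write_fasta,
    write_maf,
)
from .motif_scan import IupacConsensus

__all__ = [
    "ShiftedGeometric",
    "SimSpec",
    "TruthCluster",
    "TruthSet",
    "SimData",
    "simulate_dataset",
    "simulate_labeled_corpus",
    "simulate_label_paths",
    "recovery_report",
    "RecoveryReport",
    "default_tree_newick",
    "conservation_pmf",
    "accessibility_pmf",
]

# a small mammal-like tree: 7 species, ~2 substitutions/site total branch length
DEFAULT_TREE_NEWICK = (
    "(((mm:0.08,rn:0.10):0.25,(hs:0.09,pt:0.02):0.20):0.10,"
    "(bt:0.25,cf:0.22):0.08,md:0.60);"
)


def default_tree_newick() -> str:
    return DEFAULT_TREE_NEWICK


@dataclass(frozen=True)
class ShiftedGeometric:
    """Spacing distribution: d = shift + G, G ~ Geometric0(p) on {0, 1, ...}.

    ``shift`` is the minimum start-to-start distance (the motif length, so
    planted words never overlap) and ``mean`` the distribution mean; p
    follows as 1 / (mean - shift + 1).
    """

    shift: int = 4
    mean: float = 8.0

    def __post_init__(self) -> None:
        if self.mean <= self.shift:
            raise ValueError("mean must exceed shift")

    @property
    def p(self) -> float:
        return 1.0 / (self.mean - self.shift + 1.0)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return self.shift + rng.geometric(self.p, size=n) - 1

    def pmf(self, d: int) -> float:
        if d < self.shift:
            return 0.0
        return (1.0 - self.p) ** (d - self.shift) * self.p

    def sf(self, d: int) -> float:
        """P(D >= d)."""
        if d <= self.shift:
            return 1.0
        return (1.0 - self.p) ** (d - self.shift)

    def censored_masses(self, d_cens: int = 30) -> np.ndarray:
        """Exact probability masses on the unit bins 1..d_cens (last censored)."""
        masses = np.array([self.pmf(d) for d in range(1, d_cens)] + [self.sf(d_cens)])
        return masses


def conservation_pmf(
    tree: PhyloTree, ref_species: str, p_keep: float, bins: int = 20
) -> np.ndarray:
    """Exact binned distribution of the branch length score when every
    non-reference species retains the motif independently with ``p_keep``."""
    others = [s for s in tree.leaf_names if s != ref_species]
    masses = np.zeros(bins)
    for code in range(2 ** len(others)):
        kept = {ref_species}
        prob = 1.0
        for i, sp in enumerate(others):
            if code >> i & 1:
                kept.add(sp)
                prob *= p_keep
            else:
                prob *= 1.0 - p_keep
        c = tree.spanning_branch_length(kept) / tree.total_branch_length
        idx = min(int(c * bins), bins - 1)
        masses[idx] += prob
    return masses


def accessibility_pmf(alpha: float, b: float, bins: int = 20) -> np.ndarray:
    """Exact binned Beta(alpha, b) masses on ``bins`` equal-width bins."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    cdf = beta_dist.cdf(edges, alpha, b)
    return np.diff(cdf)


@dataclass(frozen=True)
class SimSpec:
    """Study conditions of one synthetic transcriptome.

    Defaults follow the separation the bound/background contrast shows in
    CLIP-trained feature distributions: bound clusters of >= 3 sites with
    ~8 nt mean spacing, ~0.9 per-species motif retention and
    strongly-accessible Beta(8, 2) sites, against sparse (~80 nt spacing),
    poorly retained (0.3) and indifferent Beta(2, 2) background sites.
    """

    seed: int
    n_genes: int = 40
    gene_length: tuple[int, int] = (3000, 6000)  # uniform inclusive bounds
    consensus: IupacConsensus = field(default_factory=lambda: IupacConsensus("YCAY"))
    cluster_rate: float = 1.5  # Poisson mean clusters per gene
    sites_per_cluster_extra_mean: float = 2.0  # k = 3 + Poisson(.)
    cluster_spacing: ShiftedGeometric = field(
        default_factory=lambda: ShiftedGeometric(shift=4, mean=8.0)
    )
    background_spacing: ShiftedGeometric = field(
        default_factory=lambda: ShiftedGeometric(shift=4, mean=80.0)
    )
    p_keep_pos: float = 0.9
    p_keep_neg: float = 0.3
    acc_pos: tuple[float, float] = (8.0, 2.0)  # Beta(alpha, beta)
    acc_neg: tuple[float, float] = (2.0, 2.0)
    ph_mean: float = 30.0  # PH = 1 + Poisson(ph_mean - 1) over planted clusters
    false_peak_rate: float = 0.0  # Poisson mean spurious peaks per gene
    # when set, each planted cluster draws a strength u ~ Uniform(range):
    # retention and accessibility interpolate between the background and
    # bound laws, and the CLIP peak height scales with u -- emulating the
    # affinity heterogeneity that couples cluster confidence to CLIP support
    cluster_strength_range: tuple[float, float] | None = None
    clip_pad: int = 20  # CLIP cluster interval padding around the planted span
    peak_jitter: int = 0  # +- uniform jitter of the peak position
    species_bg_sub_rate: float = 0.1  # substitutions outside motif spans
    tree_newick: str = DEFAULT_TREE_NEWICK
    ref_species: str = "mm"
    flank_pad: int = 1100  # sequence kept on each side of the gene body
    n_exons: int = 3

    def __post_init__(self) -> None:
        for p in (self.p_keep_pos, self.p_keep_neg, self.species_bg_sub_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.gene_length[0] > self.gene_length[1]:
            raise ValueError("invalid gene length bounds")
        if self.gene_length[0] <= 4 * self.background_spacing.mean:
            raise ValueError("gene length infeasible for the background spacing")
        if self.n_exons < 1:
            raise ValueError("need at least one exon")


@dataclass(frozen=True)
class TruthCluster:
    """One planted cluster: its span, member site starts and strength."""

    interval: GenomicInterval
    member_starts: tuple[int, ...]
    strength: float = 1.0

    @property
    def n_sites(self) -> int:
        return len(self.member_starts)


@dataclass
class TruthSet:
    clusters: list[TruthCluster]
    site_labels: dict[str, list[str]]  # seq_id -> '+'/'-' per planted site
    site_starts: dict[str, list[int]]


@dataclass
class SimData:
    """In-memory view of one simulated dataset."""

    spec: SimSpec
    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    blocks_by_seq: dict[str, list[AlignmentBlock]]
    tree: PhyloTree
    track: AccessibilityTrack
    clip: list[ClipCluster]
    truth: TruthSet

    @property
    def consensus(self) -> IupacConsensus:
        return self.spec.consensus

    @property
    def ref_species(self) -> str:
        return self.spec.ref_species


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


def _broken_word(word: str, consensus: IupacConsensus, rng: np.random.Generator) -> str:
    """A single-substitution neighbor of ``word`` matching no consensus word."""
    candidates = []
    for i in range(len(word)):
        for letter in "ACGT":
            if letter == word[i]:
                continue
            cand = word[:i] + letter + word[i + 1 :]
            if cand not in consensus.words:
                candidates.append(cand)
    if not candidates:
        raise ValueError("consensus matches every point mutation; cannot break motif")
    return candidates[rng.integers(len(candidates))]


def _destroy_unplanned_matches(
    seq: np.ndarray,
    planted_spans: list[tuple[int, int]],
    consensus: IupacConsensus,
    rng: np.random.Generator,
    max_rounds: int = 60,
) -> None:
    """Mutate free bases until the only consensus matches are the planted ones."""
    planted_starts = {s for s, _ in planted_spans}
    occupied = np.zeros(len(seq), dtype=bool)
    for s, e in planted_spans:
        occupied[s:e] = True
    pattern = re.compile("(?=(" + "|".join(sorted(consensus.words)) + "))")
    for _ in range(max_rounds):
        text = seq.tobytes().decode()
        bad = [
            m.start()
            for m in pattern.finditer(text)
            if m.start() not in planted_starts
        ]
        if not bad:
            return
        for start in bad:
            free = [
                i for i in range(start, start + consensus.length) if not occupied[i]
            ]
            if not free:
                continue  # fully inside planted spans; cannot occur for default YCAY
            i = free[rng.integers(len(free))]
            current = seq[i]
            choices = _ACGT[_ACGT != current]
            seq[i] = choices[rng.integers(len(choices))]
    text = seq.tobytes().decode()
    leftover = [
        m.start() for m in pattern.finditer(text) if m.start() not in planted_starts
    ]
    if leftover:
        raise ValueError(
            "could not remove accidental consensus matches; consensus too dense"
        )


def _random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return _ACGT[rng.integers(0, 4, size=n)]


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _plan_gene(
    spec: SimSpec, rng: np.random.Generator
) -> tuple[int, list[list[int]], list[int]]:
    """Gene length, per-cluster member starts, background site starts."""
    L = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
    k_mot = spec.consensus.length
    n_clusters = int(rng.poisson(spec.cluster_rate))
    clusters: list[list[int]] = []
    max_span = 500
    anchors: list[int] = []
    for _ in range(n_clusters):
        for _attempt in range(100):
            a = int(rng.integers(50, max(51, L - max_span - 50)))
            if all(abs(a - b) >= max_span + 100 for b in anchors):
                anchors.append(a)
                break
    anchors.sort()
    for a in anchors:
        k = 3 + int(rng.poisson(spec.sites_per_cluster_extra_mean))
        starts = [a]
        for _ in range(k - 1):
            gap = int(spec.cluster_spacing.sample(rng, 1)[0])
            starts.append(starts[-1] + gap)
        if starts[-1] + k_mot <= L:
            clusters.append(starts)
    # background stream, skipping a guard zone around planted clusters
    zones = [
        (c[0] - 60, c[-1] + k_mot + 60) for c in clusters
    ]
    background: list[int] = []
    pos = int(spec.background_spacing.sample(rng, 1)[0])
    while pos + k_mot <= L:
        if not any(lo <= pos < hi for lo, hi in zones):
            background.append(pos)
        pos += int(spec.background_spacing.sample(rng, 1)[0])
    return L, clusters, background


def _gene_annotation(
    seq_id: str, gene_start: int, gene_end: int, n_exons: int, rng: np.random.Generator
) -> TranscriptModel:
    """A coding multi-exon transcript whose introns stay inside the exon+ext
    mask (introns <= 2 kb), so the whole gene body is trainable sequence."""
    L = gene_end - gene_start
    if n_exons == 1 or L < 2500:
        exons = [GenomicInterval(seq_id, gene_start, gene_end)]
        cds = (gene_start + L // 4, gene_end - L // 4)
    else:
        n_introns = n_exons - 1
        intron_len = min(1800, max(400, L // (2 * n_introns)))
        exon_len = (L - n_introns * intron_len) // n_exons
        bounds = []
        pos = gene_start
        for i in range(n_exons):
            end = gene_end if i == n_exons - 1 else pos + exon_len
            bounds.append((pos, end))
            pos = end + intron_len
        exons = [GenomicInterval(seq_id, s, e) for s, e in bounds]
        cds = (
            exons[0].start + exons[0].length // 2,
            exons[-1].end - exons[-1].length // 2,
        )
    return TranscriptModel(
        id=seq_id,
        interval=GenomicInterval(seq_id, gene_start, gene_end),
        exons=exons,
        cds_start=cds[0],
        cds_end=cds[1],
    )


def simulate_dataset(spec: SimSpec, out_dir: str | Path | None = None) -> SimData:
    """Generate one synthetic transcriptome; optionally write its seven files.

    When ``out_dir`` is given, writes genome.fa, alignment.maf, tree.nwk,
    accessibility.bedgraph, annotation.bed12, clip.bed and truth.bed there.
    All outputs are deterministic functions of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    import io as _io

    from Bio import Phylo as _Phylo

    tree = PhyloTree.from_biopython(
        _Phylo.read(_io.StringIO(spec.tree_newick), "newick")
    )
    if spec.ref_species not in tree.leaf_names:
        raise ValueError(f"reference species {spec.ref_species!r} not in the tree")

    sequences: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    blocks_by_seq: dict[str, list[AlignmentBlock]] = {}
    track = AccessibilityTrack()
    clip: list[ClipCluster] = []
    truth_clusters: list[TruthCluster] = []
    site_labels: dict[str, list[str]] = {}
    site_starts: dict[str, list[int]] = {}
    k_mot = spec.consensus.length
    words = sorted(spec.consensus.words)
    other_species = [s for s in tree.leaf_names if s != spec.ref_species]

    for g in range(spec.n_genes):
        seq_id = f"gene{g:04d}"
        L, cluster_plan, background = _plan_gene(spec, rng)
        pad = spec.flank_pad
        contig_len = L + 2 * pad
        gene_start, gene_end = pad, pad + L

        # per-cluster strength (1.0 = fully bound-like laws)
        if spec.cluster_strength_range is not None:
            lo, hi = spec.cluster_strength_range
            strengths = [float(rng.uniform(lo, hi)) for _ in cluster_plan]
        else:
            strengths = [1.0] * len(cluster_plan)

        # ordered sites with labels and strengths, in contig coordinates
        all_sites: list[tuple[int, str, float]] = []
        for starts, u in zip(cluster_plan, strengths):
            for s in starts:
                all_sites.append((s + pad, "+", u))
        for s in background:
            all_sites.append((s + pad, "-", 0.0))
        all_sites.sort()
        spans = [(s, s + k_mot) for s, _, _ in all_sites]

        # reference sequence with planted words
        seq = _random_seq(contig_len, rng)
        site_words = []
        for s, _label, _u in all_sites:
            w = words[rng.integers(len(words))]
            site_words.append(w)
            seq[s : s + k_mot] = np.frombuffer(w.encode(), dtype="S1")
        _destroy_unplanned_matches(seq, spans, spec.consensus, rng)
        ref_text = seq.tobytes().decode()
        sequences[seq_id] = ref_text

        # annotation
        transcripts.append(
            build_region_segments(
                _gene_annotation(seq_id, gene_start, gene_end, spec.n_exons, rng),
                ext=1000,
            )
        )

        # alignment rows: per-species retention of each planted word
        rows = {spec.ref_species: ref_text}
        for sp in other_species:
            sp_seq = seq.copy()
            if spec.species_bg_sub_rate > 0:
                mask = rng.random(contig_len) < spec.species_bg_sub_rate
                for s, e in spans:
                    mask[s:e] = False
                n_sub = int(mask.sum())
                if n_sub:
                    sp_seq[mask] = _ACGT[rng.integers(0, 4, size=n_sub)]
            for (s, label, u), w in zip(all_sites, site_words):
                if label == "+":
                    p_keep = spec.p_keep_neg + u * (spec.p_keep_pos - spec.p_keep_neg)
                else:
                    p_keep = spec.p_keep_neg
                if rng.random() < p_keep:
                    sp_seq[s : s + k_mot] = np.frombuffer(w.encode(), dtype="S1")
                else:
                    broken = _broken_word(w, spec.consensus, rng)
                    sp_seq[s : s + k_mot] = np.frombuffer(broken.encode(), dtype="S1")
            rows[sp] = sp_seq.tobytes().decode()
        blocks_by_seq[seq_id] = [
            AlignmentBlock(
                ref_species=spec.ref_species,
                interval=GenomicInterval(seq_id, 0, contig_len),
                rows=rows,
            )
        ]

        # accessibility: background fill 0.5, per-site Beta draws over the span
        acc = np.full(contig_len, 0.5)
        for s, label, u in all_sites:
            if label == "+":
                ab = tuple(
                    n + u * (p - n) for p, n in zip(spec.acc_pos, spec.acc_neg)
                )
            else:
                ab = spec.acc_neg
            acc[s : s + k_mot] = rng.beta(ab[0], ab[1])
        track.set_array(seq_id, acc)

        # truth + CLIP peaks
        for starts, u in zip(cluster_plan, strengths):
            lo, hi = starts[0] + pad, starts[-1] + pad + k_mot
            truth_clusters.append(
                TruthCluster(
                    interval=GenomicInterval(seq_id, lo, hi),
                    member_starts=tuple(s + pad for s in starts),
                    strength=u,
                )
            )
            ph = 1 + int(rng.poisson(max(spec.ph_mean * u - 1.0, 0.0)))
            peak = (lo + hi) // 2
            if spec.peak_jitter:
                peak += int(rng.integers(-spec.peak_jitter, spec.peak_jitter + 1))
            c_start = max(0, lo - spec.clip_pad)
            c_end = min(contig_len, hi + spec.clip_pad)
            peak = min(max(peak, c_start), c_end - 1)
            clip.append(
                ClipCluster(GenomicInterval(seq_id, c_start, c_end), peak, ph)
            )
        for _ in range(int(rng.poisson(spec.false_peak_rate))):
            pos = int(rng.integers(gene_start, gene_end))
            ph = 1 + int(rng.poisson(max(spec.ph_mean - 1.0, 0.0)))
            clip.append(
                ClipCluster(
                    GenomicInterval(seq_id, max(0, pos - spec.clip_pad), pos + spec.clip_pad),
                    pos,
                    ph,
                )
            )

        site_labels[seq_id] = [label for _, label, _ in all_sites]
        site_starts[seq_id] = [s for s, _, _ in all_sites]

    data = SimData(
        spec=spec,
        sequences=sequences,
        transcripts=transcripts,
        blocks_by_seq=blocks_by_seq,
        tree=tree,
        track=track,
        clip=clip,
        truth=TruthSet(
            clusters=truth_clusters, site_labels=site_labels, site_starts=site_starts
        ),
    )
    if out_dir is not None:
        _write_dataset(data, Path(out_dir))
    return data


def _write_dataset(data: SimData, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(data.sequences, out_dir / "genome.fa")
    blocks = [b for seq in sorted(data.blocks_by_seq) for b in data.blocks_by_seq[seq]]
    write_maf(blocks, out_dir / "alignment.maf")
    with open(out_dir / "tree.nwk", "w", newline="\n") as fh:
        fh.write(data.spec.tree_newick.strip() + "\n")
    write_bedgraph(data.track, out_dir / "accessibility.bedgraph")
    write_bed12(data.transcripts, out_dir / "annotation.bed12")
    write_bed(data.clip, out_dir / "clip.bed")
    with open(out_dir / "truth.bed", "w", newline="\n") as fh:
        for t in data.truth.clusters:
            iv = t.interval
            starts = ",".join(str(s) for s in t.member_starts)
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\ttruth\t0\t{iv.strand}"
                f"\t{t.n_sites}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# feature-level corpus (for parameter-recovery experiments)
# ---------------------------------------------------------------------------

def simulate_labeled_corpus(
    spec: SimSpec,
    n_pos_sites: int,
    n_neg_sites: int,
    rng: np.random.Generator | None = None,
    sites_per_sequence: int = 8,
    d_cens: int = 30,
):
    """Labeled site sequences drawn directly from the spec's feature laws.

    Bypasses sequence construction: spacing, retention-derived conservation
    and accessibility are drawn per site from the same distributions the
    full generator uses, organized into constant-label sequences of
    ``sites_per_sequence`` sites.  Used for parameter-recovery experiments
    at sample sizes where building sequences would be wasteful.
    """
    from .training import LabeledSiteSequence
    from .io_formats import RegionType

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    import io as _io

    from Bio import Phylo as _Phylo

    tree = PhyloTree.from_biopython(_Phylo.read(_io.StringIO(spec.tree_newick), "newick"))
    others = [s for s in tree.leaf_names if s != spec.ref_species]
    out = []
    for label, n_sites in (("+", n_pos_sites), ("-", n_neg_sites)):
        spacing = spec.cluster_spacing if label == "+" else spec.background_spacing
        p_keep = spec.p_keep_pos if label == "+" else spec.p_keep_neg
        ab = spec.acc_pos if label == "+" else spec.acc_neg
        made = 0
        while made < n_sites:
            m = min(sites_per_sequence, n_sites - made)
            ds = [0] + [
                min(int(x), d_cens) for x in spacing.sample(rng, m - 1)
            ] if m > 1 else [0]
            feats = []
            for d in ds:
                kept = frozenset(
                    {spec.ref_species}
                    | {sp for sp in others if rng.random() < p_keep}
                )
                c = tree.spanning_branch_length(kept) / tree.total_branch_length
                a = float(rng.beta(ab[0], ab[1]))
                feats.append(SiteFeatures(d=d, c=c, a=a, region=RegionType.INTRON))
            out.append(LabeledSiteSequence(features=feats, labels=[label] * m))
            made += m
    return out


def simulate_label_paths(
    trans_probs: dict,
    init_plus: float,
    n_sequences: int,
    mean_length: float,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Label sequences generated from a known transition law.

    ``trans_probs`` gives P(continue) per side as {'+': P(+ -> +),
    '-': P(- -> -)}; switches go through the internal-initiation states.
    Sequence lengths are 1 + Poisson(mean_length - 1).
    """
    out = []
    for _ in range(n_sequences):
        n = 1 + int(rng.poisson(max(mean_length - 1.0, 0.0)))
        labels = ["+" if rng.random() < init_plus else "-"]
        for _ in range(n - 1):
            stay = trans_probs[labels[-1]]
            if rng.random() < stay:
                labels.append(labels[-1])
            else:
                labels.append("+" if labels[-1] == "-" else "-")
        out.append(labels)
    return out


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    precision: float | None
    recall: float
    f1: float | None
    n_matched: int
    n_calls: int
    n_truth: int


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def recovery_report(
    truth: Sequence[TruthCluster] | Sequence[GenomicInterval],
    calls: Sequence[ClusterCall],
    min_overlap: float = 0.5,
) -> RecoveryReport:
    """Precision/recall/F1 of cluster calls against planted clusters.

    A call matches a planted cluster when their reciprocal overlap is at
    least ``min_overlap``; matching is one-to-one, greedy by descending call
    score.  With no calls, recall is 0 and precision undefined (None).
    """
    truth_ivs = [t.interval if isinstance(t, TruthCluster) else t for t in truth]
    order = sorted(range(len(calls)), key=lambda i: -calls[i].score)
    unmatched = set(range(len(truth_ivs)))
    n_matched = 0
    for ci in order:
        iv = calls[ci].interval
        best_j, best_ov = None, min_overlap
        for j in unmatched:
            ov = _reciprocal_overlap(iv, truth_ivs[j])
            if ov >= best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            unmatched.discard(best_j)
            n_matched += 1
    precision = (n_matched / len(calls)) if calls else None
    recall = (n_matched / len(truth_ivs)) if truth_ivs else 0.0
    if precision is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return RecoveryReport(
        precision=precision,
        recall=recall,
        f1=f1,
        n_matched=n_matched,
        n_calls=len(calls),
        n_truth=len(truth_ivs),
    )
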