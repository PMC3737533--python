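"""Per-site observation features for the HMM: spacing d, conservation c,
accessibility a, and the conservation stratum (region type).

d -- start-to-start distance to the preceding site on the same scan
sequence, censored at ``d_cens`` (default 30 nt) to impose an implicit limit
on the spacing allowed inside a cluster.  The first site of a scan sequence
carries the sentinel d = 0, consumed only by the degenerate
sequence-initial HMM states; real inter-site distances are >= 1, so the
sentinel never collides.

c -- branch length score (BLS): the fraction of the phylogeny's total branch
length spanned by the species whose aligned orthologous window retains a
consensus word.  In [0, 1]; 0 when the site is unaligned or conserved in the
reference alone.

a -- probability the site lies in single-stranded (unpaired) RNA: the mean
of the per-base track values over the site span.  Genome tracks are sparse,
so the missing-data policy is explicit; the default drops the a-term for
that site rather than imputing.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    AccessibilityTrack,
    AlignmentBlock,
    GenomicInterval,
    PhyloTree,
    RegionType,
    TranscriptModel,
)
from .motif_scan import IupacConsensus, MotifSite

logger = logging.getLogger(__name__)

__all__ = [
    "SiteFeatures",
    "compute_spacing",
    "compute_bls",
    "compute_accessibility",
    "assign_region",
    "featurize_scan_sequence",
    "featurize_all",
    "BlsCache",
]

D_CENS_DEFAULT = 30

# region priority when isoforms disagree on the base at site.start
_REGION_PRIORITY = (
    RegionType.CDS,
    RegionType.THREE_UTR,
    RegionType.FIVE_UTR,
    RegionType.INTRON,
)


@dataclass(frozen=True)
class SiteFeatures:
    """The observation triple (d, c, a) plus conservation stratum."""

    d: int
    c: float
    a: float | None
    region: RegionType = RegionType.INTRON

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError(f"c = {self.c} outside [0, 1]")
        if self.a is not None and not (0.0 <= self.a <= 1.0):
            raise ValueError(f"a = {self.a} outside [0, 1]")


def compute_spacing(
    sites_or_starts: Sequence[MotifSite] | Sequence[int], d_cens: int = D_CENS_DEFAULT
) -> list[int]:
    """Censored start-to-start distances along one scan sequence.

    d_1 = 0 (sentinel); d_i = min(start_i - start_{i-1}, d_cens) for i > 1.
    Input must be sorted by start.
    """
    starts = [
        s.start if isinstance(s, MotifSite) else int(s) for s in sites_or_starts
    ]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("sites must be strictly sorted by start")
    out = [0]
    for prev, cur in zip(starts, starts[1:]):
        out.append(min(cur - prev, d_cens))
    return out


class BlsCache:
    """Memoizes spanning-subtree sums by retained-species set (tree fixed)."""

    def __init__(self, tree: PhyloTree) -> None:
        self.tree = tree
        self._cache: dict[frozenset[str], float] = {}

    def fraction(self, species: frozenset[str]) -> float:
        if self.tree.total_branch_length == 0.0:
            return 0.0
        bl = self._cache.get(species)
        if bl is None:
            bl = self.tree.spanning_branch_length(species)
            self._cache[species] = bl
        return bl / self.tree.total_branch_length


def compute_bls(
    site: MotifSite | GenomicInterval,
    blocks: Sequence[AlignmentBlock],
    tree: PhyloTree,
    ref_species: str,
    consensus: IupacConsensus,
    slop: int = 0,
    cache: BlsCache | None = None,
) -> float:
    """Branch length score of one motif site.

    A species is counted as retaining the motif when its aligned orthologous
    window (the site span +- ``slop`` on the reference, gaps removed)
    contains a consensus word; the reference always counts.  The score is
    the branch length of the minimal subtree spanning the retaining species
    divided by the tree's total branch length; 0 when the total is 0 or no
    block covers the full site span.
    """
    if ref_species not in tree.leaf_names:
        raise ValueError(f"reference species {ref_species!r} is not a leaf of the tree")
    if tree.total_branch_length == 0.0:
        return 0.0
    iv = site.interval if isinstance(site, MotifSite) else site
    block = None
    for b in blocks:
        if b.interval.seq_id == iv.seq_id and b.interval.start <= iv.start and iv.end <= b.interval.end:
            block = b
            break
    if block is None:
        return 0.0
    retained = {ref_species}
    for sp in block.species:
        if sp == ref_species or sp not in tree.leaf_names:
            continue
        window = block.extract(sp, iv.start - slop, iv.end + slop)
        if window is None:
            continue
        window = window.upper().replace("U", "T")
        if any(w in window for w in consensus.words):
            retained.add(sp)
    s = frozenset(retained)
    if cache is not None:
        return cache.fraction(s)
    return tree.spanning_branch_length(s) / tree.total_branch_length


def compute_accessibility(
    site: MotifSite | GenomicInterval,
    track: AccessibilityTrack,
    missing_policy: str = "drop_feature",
) -> float | None:
    """Mean per-base accessibility over the site span.

    missing_policy='drop_feature' (default): any missing base -> None (the
    emission later skips the a-term for this site in all states
    symmetrically).  'mean_of_present': average over present bases; None
    only if every base is missing.
    """
    if missing_policy not in ("drop_feature", "mean_of_present"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    iv = site.interval if isinstance(site, MotifSite) else site
    values = track.window(iv.seq_id, iv.start, iv.end)
    missing = np.isnan(values)
    if missing.all():
        return None
    if missing.any() and missing_policy == "drop_feature":
        return None
    return float(np.nanmean(values))


class _SegmentIndex:
    """Per-sequence lookup of the region stratum at a base position.

    Each transcript's segments tile a contiguous span, so lookup is one
    bisect per overlapping isoform.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self._by_seq: dict[str, list[tuple[int, int, list[int], list[tuple[int, RegionType]]]]] = {}
        for t in transcripts:
            if not t.region_segments:
                raise ValueError(
                    f"transcript {t.id} lacks region segments; call build_region_segments first"
                )
            segs = sorted(
                ((seg.start, seg.end, label.stratum) for seg, label in t.region_segments)
            )
            span = (segs[0][0], segs[-1][1])
            self._by_seq.setdefault(t.interval.seq_id, []).append(
                (span[0], span[1], [s[0] for s in segs], [(s[1], s[2]) for s in segs])
            )

    def strata_at(self, seq_id: str, pos: int) -> list[RegionType]:
        out = []
        for span_start, span_end, starts, ends_types in self._by_seq.get(seq_id, []):
            if not (span_start <= pos < span_end):
                continue
            j = bisect_right(starts, pos) - 1
            if j >= 0 and pos < ends_types[j][0]:
                out.append(ends_types[j][1])
        return out


def assign_region(
    site: MotifSite | GenomicInterval,
    transcripts: Iterable[TranscriptModel] | _SegmentIndex,
) -> RegionType:
    """Conservation stratum of the base at ``site.start``.

    Conflicting isoforms resolve by priority CDS > 3'UTR > 5'UTR > intron;
    flanks and non-coding exons map to the intron stratum.  A site outside
    every annotation maps to INTRON with a logged warning.
    """
    index = (
        transcripts
        if isinstance(transcripts, _SegmentIndex)
        else _SegmentIndex(transcripts)
    )
    iv = site.interval if isinstance(site, MotifSite) else site
    strata = index.strata_at(iv.seq_id, iv.start)
    if not strata:
        logger.warning(
            "site %s:%d outside all annotation; mapped to intron stratum",
            iv.seq_id,
            iv.start,
        )
        return RegionType.INTRON
    for region in _REGION_PRIORITY:
        if region in strata:
            return region
    return RegionType.INTRON


def featurize_scan_sequence(
    sites: Sequence[MotifSite],
    blocks: Sequence[AlignmentBlock],
    tree: PhyloTree,
    ref_species: str,
    consensus: IupacConsensus,
    track: AccessibilityTrack | None,
    region_index: _SegmentIndex,
    d_cens: int = D_CENS_DEFAULT,
    missing_policy: str = "drop_feature",
    bls_slop: int = 0,
    bls_cache: BlsCache | None = None,
) -> list[SiteFeatures]:
    """Feature triples for one ordered scan sequence of sites."""
    if not sites:
        return []
    ds = compute_spacing(sites, d_cens=d_cens)
    feats = []
    for site, d in zip(sites, ds):
        c = compute_bls(site, blocks, tree, ref_species, consensus, slop=bls_slop, cache=bls_cache)
        a = None if track is None else compute_accessibility(site, track, missing_policy)
        region = assign_region(site, region_index)
        feats.append(SiteFeatures(d=d, c=c, a=a, region=region))
    return feats


def featurize_all(
    sites_by_seq: Mapping[str, Sequence[MotifSite]],
    blocks_by_seq: Mapping[str, Sequence[AlignmentBlock]],
    tree: PhyloTree,
    ref_species: str,
    consensus: IupacConsensus,
    track: AccessibilityTrack | None,
    transcripts: Iterable[TranscriptModel],
    d_cens: int = D_CENS_DEFAULT,
    missing_policy: str = "drop_feature",
    bls_slop: int = 0,
) -> dict[str, list[SiteFeatures]]:
    """Featurize every scan sequence, sharing one BLS cache and region index."""
    cache = BlsCache(tree)
    index = _SegmentIndex(transcripts)
    out = {}
    for seq_id, sites in sites_by_seq.items():
        out[seq_id] = featurize_scan_sequence(
            sites,
            blocks_by_seq.get(seq_id, []),
            tree,
            ref_species,
            consensus,
            track,
            index,
            d_cens=d_cens,
            missing_policy=missing_policy,
            bls_slop=bls_slop,
            bls_cache=cache,
        )
    return out
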