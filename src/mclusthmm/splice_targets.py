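"""Cassette-exon target ranking from cluster scores.

Each cassette exon (an alternatively spliced internal exon with its two
flanking exons) is summarized by six regional cluster scores anchored at the
flanking splice sites -- upstream-intron 5' and 3' ends (UI5'ss, UI3'ss),
the exon-internal ends (E3'ss, E5'ss) and downstream-intron 5' and 3' ends
(DI5'ss, DI3'ss).  A cluster within the window on an anchor's side
contributes its score damped by exponential distance decay exp(-dist/tau);
the regional score is the best contribution and the summarized score the
max of the six, used to rank candidate regulated exons.  The argmax region
is reported alongside (e.g. "DI5" for a downstream-intron 5'-splice-site
cluster), since binding position predicts the direction of splicing change
(downstream-intron binding typically promotes inclusion; upstream/exonic
binding, exclusion).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .hmm_core import ClusterCall
from .io_formats import GenomicInterval

__all__ = [
    "CassetteExonEvent",
    "RegionalScores",
    "TargetCall",
    "REGION_NAMES",
    "regional_scores",
    "rank_and_call_targets",
    "positional_profile",
    "target_overlap_table",
]

REGION_NAMES = ("UI5", "UI3", "E3", "E5", "DI5", "DI3")

W_DEFAULT = 1000
TAU_DEFAULT = 500.0


@dataclass(frozen=True)
class CassetteExonEvent:
    """A three-exon splicing unit on one transcript."""

    id: str
    upstream_exon: GenomicInterval
    cassette_exon: GenomicInterval
    downstream_exon: GenomicInterval

    def __post_init__(self) -> None:
        exons = (self.upstream_exon, self.cassette_exon, self.downstream_exon)
        seqs = {e.seq_id for e in exons}
        strands = {e.strand for e in exons}
        if len(seqs) != 1 or len(strands) != 1:
            raise ValueError(f"event {self.id}: exons on different sequences/strands")
        up, cas, down = exons
        if self.strand == "+":
            ordered = up.end <= cas.start and cas.end <= down.start
        else:
            ordered = down.end <= cas.start and cas.end <= up.start
        if not ordered:
            raise ValueError(
                f"event {self.id}: cassette exon not strictly between its flanking exons"
            )

    @property
    def seq_id(self) -> str:
        return self.cassette_exon.seq_id

    @property
    def strand(self) -> str:
        return self.cassette_exon.strand

    @property
    def upstream_intron(self) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(self.seq_id, self.upstream_exon.end, self.cassette_exon.start, "+")
        return GenomicInterval(self.seq_id, self.cassette_exon.end, self.upstream_exon.start, "-")

    @property
    def downstream_intron(self) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(self.seq_id, self.cassette_exon.end, self.downstream_exon.start, "+")
        return GenomicInterval(self.seq_id, self.downstream_exon.end, self.cassette_exon.start, "-")

    def anchors(self) -> dict[str, tuple[int, GenomicInterval, int]]:
        """Anchor name -> (anchor base position, side region, direction).

        Direction +1 means the eligible side extends toward increasing
        genomic coordinates from the anchor, -1 toward decreasing; the
        anchor base itself is the first base of the side region nearest the
        splice site.
        """
        ui, di, cas = self.upstream_intron, self.downstream_intron, self.cassette_exon
        if self.strand == "+":
            return {
                "UI5": (ui.start, ui, +1),
                "UI3": (ui.end - 1, ui, -1),
                "E3": (cas.start, cas, +1),
                "E5": (cas.end - 1, cas, -1),
                "DI5": (di.start, di, +1),
                "DI3": (di.end - 1, di, -1),
            }
        return {
            "UI5": (ui.end - 1, ui, -1),
            "UI3": (ui.start, ui, +1),
            "E3": (cas.end - 1, cas, -1),
            "E5": (cas.start, cas, +1),
            "DI5": (di.end - 1, di, -1),
            "DI3": (di.start, di, +1),
        }


@dataclass(frozen=True)
class RegionalScores:
    """The six anchored scores; ``summarized`` is always their maximum."""

    UI5: float
    UI3: float
    E3: float
    E5: float
    DI5: float
    DI3: float

    @property
    def summarized(self) -> float:
        return max(self.as_dict().values())

    @property
    def argmax_region(self) -> str:
        d = self.as_dict()
        return max(REGION_NAMES, key=lambda k: d[k])

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in REGION_NAMES}


def _anchor_distance(anchor: int, cluster: GenomicInterval) -> int:
    """nt from the anchor base to the nearest cluster edge (0 if covered)."""
    if cluster.start <= anchor < cluster.end:
        return 0
    if anchor < cluster.start:
        return cluster.start - anchor
    return anchor - (cluster.end - 1)


def regional_scores(
    event: CassetteExonEvent,
    clusters: Sequence[ClusterCall],
    window: int = W_DEFAULT,
    tau: float = TAU_DEFAULT,
) -> RegionalScores:
    """Distance-weighted regional cluster scores for one cassette exon.

    For each anchor, eligible clusters overlap the anchor's side region
    (intron for the four intronic anchors, the cassette exon for the two
    exonic ones) within ``window`` nt of the anchor; each contributes
    score * exp(-dist / tau), and the regional score is the best
    contribution (0 when no cluster is eligible).
    """
    if window <= 0 or tau <= 0:
        raise ValueError("window and tau must be positive")
    by_seq = [c for c in clusters if c.interval.seq_id == event.seq_id]
    out = {}
    for name, (anchor, side, direction) in event.anchors().items():
        if direction > 0:
            eligible_lo, eligible_hi = anchor, min(anchor + window, side.end)
        else:
            eligible_lo, eligible_hi = max(anchor - window + 1, side.start), anchor + 1
        best = 0.0
        for c in by_seq:
            iv = c.interval
            if iv.start < eligible_hi and eligible_lo < iv.end:
                dist = _anchor_distance(anchor, iv)
                best = max(best, c.score * math.exp(-dist / tau))
        out[name] = best
    return RegionalScores(**out)


@dataclass(frozen=True)
class TargetCall:
    event_id: str
    scores: RegionalScores
    summarized: float
    argmax_region: str


def rank_and_call_targets(
    scored_events: Sequence[tuple[CassetteExonEvent, RegionalScores]],
    threshold: float = 10.0,
) -> list[TargetCall]:
    """Events at or above the summarized-score threshold, ranked.

    Sorted by summarized score descending, ties by event id; the argmax
    region annotates where the decisive cluster sits.
    """
    calls = [
        TargetCall(
            event_id=ev.id,
            scores=rs,
            summarized=rs.summarized,
            argmax_region=rs.argmax_region,
        )
        for ev, rs in scored_events
    ]
    calls.sort(key=lambda t: (-t.summarized, t.event_id))
    return [t for t in calls if t.summarized >= threshold]


def positional_profile(
    events: Sequence[CassetteExonEvent],
    clusters: Sequence[ClusterCall],
    flank: int = 500,
    normalize: bool = True,
) -> dict[str, np.ndarray]:
    """Score-weighted cluster coverage around the four splice sites.

    Profiles are anchored at the four intron-adjacent splice sites of the
    event (UI5ss, UI3ss, DI5ss, DI3ss); offset 0 is the intron base adjacent
    to each junction and offsets run -flank..+flank in transcript
    orientation.  Each offset accumulates the scores of clusters covering
    that base, summed across events and divided by the number of events when
    ``normalize``.
    """
    if not events:
        raise ValueError("no events")
    site_keys = ("UI5ss", "UI3ss", "DI5ss", "DI3ss")
    profiles = {k: np.zeros(2 * flank + 1) for k in site_keys}
    by_seq: dict[str, list[ClusterCall]] = {}
    for c in clusters:
        by_seq.setdefault(c.interval.seq_id, []).append(c)
    for ev in events:
        anchors = ev.anchors()
        sign = 1 if ev.strand == "+" else -1
        for key in site_keys:
            center = anchors[key[:-2]][0]
            for c in by_seq.get(ev.seq_id, []):
                iv = c.interval
                # genomic positions covered, translated to transcript offsets
                lo = (iv.start - center) * sign
                hi = (iv.end - 1 - center) * sign
                if sign < 0:
                    lo, hi = hi, lo
                lo = max(lo, -flank)
                hi = min(hi, flank)
                if lo > hi:
                    continue
                profiles[key][lo + flank : hi + flank + 1] += c.score
    if normalize:
        for key in site_keys:
            profiles[key] /= len(events)
    return profiles


def target_overlap_table(
    predicted_targets: Iterable[str],
    reference_positive_set: Iterable[str],
    universe: Iterable[str],
) -> tuple[np.ndarray, float]:
    """2x2 contingency of predicted vs reference targets + Fisher exact p.

    Rows: predicted yes/no; columns: reference yes/no.  The universe must
    contain every member of both sets.
    """
    pred = set(predicted_targets)
    ref = set(reference_positive_set)
    uni = set(universe)
    if not (pred | ref) <= uni:
        raise ValueError("universe smaller than the union of the two sets")
    a = len(pred & ref)
    b = len(pred - ref)
    c = len(ref - pred)
    d = len(uni) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
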