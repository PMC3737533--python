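"""IUPAC-degenerate consensus expansion and exhaustive motif scanning.

The scanner reports *every* match in transcript orientation, including
overlapping ones (``TCATCAT`` holds two YCAY sites): the HMM's spacing
feature, not the scanner, is what penalizes or merges dense runs.  Matching
is case-insensitive; lowercase (repeat-masked) bases set the
``is_repetitive`` flag, which callers apply only where a "nonrepetitive"
filter is required (training positives, reporting) -- never during
prediction.
"""
from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_CODES",
    "IupacConsensus",
    "MotifSite",
    "expand_consensus",
    "scan_sequence",
    "scan_region_set",
    "mark_repetitive",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_consensus(pattern: str, excluded_words: Iterable[str] = ()) -> frozenset[str]:
    """Cartesian expansion of an IUPAC pattern minus excluded exact words.

    U is normalized to T in both the pattern and the exclusions.  Invalid
    IUPAC letters raise a ValueError naming the offending position.
    """
    if not pattern:
        raise ValueError("empty consensus pattern")
    choices = []
    for i, ch in enumerate(pattern.upper()):
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC letter {ch!r} at position {i} of {pattern!r}")
        choices.append(IUPAC_CODES[ch])
    words = {"".join(w) for w in product(*choices)}
    excluded = {w.upper().replace("U", "T") for w in excluded_words}
    bad = excluded - words
    if bad:
        raise ValueError(f"excluded words do not match the pattern: {sorted(bad)}")
    return frozenset(words - excluded)


@dataclass(frozen=True)
class IupacConsensus:
    """A degenerate consensus (e.g. YCAY or YGCY) with optional exclusions.

    ``excluded_words`` removes exact words from the expansion -- e.g. the
    Mbnl consensus YGCY with CGCC excluded.
    """

    pattern: str
    excluded_words: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        pattern = self.pattern.upper().replace("U", "T")
        object.__setattr__(self, "pattern", pattern)
        excluded = frozenset(w.upper().replace("U", "T") for w in self.excluded_words)
        object.__setattr__(self, "excluded_words", excluded)
        words = expand_consensus(pattern, excluded)  # validates
        if not words:
            raise ValueError("consensus excludes every word it matches")
        object.__setattr__(self, "_words", words)

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def words(self) -> frozenset[str]:
        return self._words  # type: ignore[attr-defined]

    def matches(self, word: str) -> bool:
        return word.upper().replace("U", "T") in self.words


@dataclass(frozen=True)
class MotifSite:
    """One exact-word occurrence of the consensus on a scan sequence."""

    seq_id: str
    start: int
    end: int
    word: str
    is_repetitive: bool = False
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.word):
            raise ValueError("site span does not match word length")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end)


def _compiled(consensus: IupacConsensus) -> re.Pattern:
    alternation = "|".join(sorted(consensus.words))
    # lookahead so that overlapping matches are all reported
    return re.compile(f"(?=({alternation}))", re.IGNORECASE)


def scan_sequence(seq: str, consensus: IupacConsensus, seq_id: str = "seq") -> list[MotifSite]:
    """All (possibly overlapping) consensus matches on ``seq``.

    The sequence must already be U->T normalized (as done by the FASTA
    reader).  Lowercase anywhere in a matched word flags the site as
    repetitive.
    """
    pat = _compiled(consensus)
    k = consensus.length
    sites = []
    for ordinal, m in enumerate(pat.finditer(seq)):
        start = m.start()
        word = seq[start : start + k]
        sites.append(
            MotifSite(
                seq_id=seq_id,
                start=start,
                end=start + k,
                word=word.upper(),
                is_repetitive=not word.isupper(),
                ordinal=ordinal,
            )
        )
    return sites


def scan_region_set(
    sequences: Mapping[str, str],
    mask_intervals: Iterable[GenomicInterval],
    consensus: IupacConsensus,
) -> dict[str, list[MotifSite]]:
    """Scan every sequence, keeping only sites fully inside the mask union.

    Masks on unknown sequence ids are skipped with a warning.  Ordinals are
    reassigned per sequence after filtering.
    """
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in mask_intervals:
        if iv.seq_id not in sequences:
            logger.warning("mask interval on unknown sequence %r skipped", iv.seq_id)
            continue
        by_seq.setdefault(iv.seq_id, []).append(iv)
    out: dict[str, list[MotifSite]] = {}
    for seq_id, seq in sequences.items():
        merged = merge_intervals(by_seq.get(seq_id, []))
        starts = [iv.start for iv in merged]
        kept = []
        for site in scan_sequence(seq, consensus, seq_id=seq_id):
            i = bisect_right(starts, site.start) - 1
            if i >= 0 and site.end <= merged[i].end:
                kept.append(replace(site, ordinal=len(kept)))
        out[seq_id] = kept
    return out


def mark_repetitive(
    sites: Sequence[MotifSite], repeat_intervals: Iterable[GenomicInterval]
) -> list[MotifSite]:
    """OR the repetitive flag with overlap (>= 1 nt) against repeat intervals."""
    merged = merge_intervals(repeat_intervals)
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    out = []
    for site in sites:
        ivs = by_seq.get(site.seq_id, [])
        hit = any(iv.start < site.end and site.start < iv.end for iv in ivs)
        out.append(replace(site, is_repetitive=site.is_repetitive or hit))
    return out
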