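"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open (``[start, end)``) -- BED-native --
everywhere in memory and in text output.  MAF ``s``-line fields are converted
on read: minus-strand reference rows are flipped to plus-strand coordinates
and all rows reverse-complemented, so downstream code only ever sees the
reference in plus orientation.  Fixed-step WIG declarations (1-based) are
shifted on read.

Strand: scanning and feature extraction operate on the transcribed (sense)
strand; minus-strand genes are reverse-complemented into transcript
orientation by the callers of these readers.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, Phylo, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RegionType",
    "SegmentLabel",
    "TranscriptModel",
    "PhyloTree",
    "AlignmentBlock",
    "AccessibilityTrack",
    "ClipCluster",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bed12",
    "write_bed12",
    "read_maf",
    "write_maf",
    "read_newick",
    "write_newick",
    "read_accessibility",
    "write_bedgraph",
    "build_region_segments",
    "exon_ext_mask",
    "merge_intervals",
    "intervals_cover",
]

_VALID_SEQ_LETTERS = frozenset("ACGTUNRYSWKMBDHV" + "ACGTUNRYSWKMBDHV".lower())


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


class RegionType(Enum):
    """Conservation stratum of a motif site.

    Basal conservation differs sharply between UTRs, coding sequence and
    introns, so conservation emission distributions are estimated separately
    per stratum.  Flanking and non-coding-exon sequence is pooled with
    introns (the least biased default; see :class:`SegmentLabel`).
    """

    FIVE_UTR = "5utr"
    CDS = "cds"
    THREE_UTR = "3utr"
    INTRON = "intron"


class SegmentLabel(Enum):
    """Fine-grained annotation label of a gene-body segment."""

    FIVE_UTR = "5utr"
    CDS = "cds"
    THREE_UTR = "3utr"
    INTRON = "intron"
    FLANK = "flank"
    NONCODING_EXON = "noncoding_exon"

    @property
    def stratum(self) -> RegionType:
        """Conservation stratum this label maps to."""
        if self is SegmentLabel.FIVE_UTR:
            return RegionType.FIVE_UTR
        if self is SegmentLabel.CDS:
            return RegionType.CDS
        if self is SegmentLabel.THREE_UTR:
            return RegionType.THREE_UTR
        # introns, flanks and non-coding exons share the intron stratum
        return RegionType.INTRON


@dataclass
class TranscriptModel:
    """A transcript with exon structure, optional CDS and region segments.

    ``region_segments`` (filled by :func:`build_region_segments`) tile
    ``[interval.start - ext, interval.end + ext)`` without gaps or overlaps,
    ordered 5'->3' in transcript orientation.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    region_segments: list[tuple[GenomicInterval, SegmentLabel]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        for e in exons:
            if not self.interval.contains(e):
                raise ValueError(f"transcript {self.id}: exon outside transcript span")
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.id}: half-specified CDS")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None and self.cds_end > self.cds_start

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.seq_id, a.end, b.start, self.interval.strand))
        return out


@dataclass
class PhyloTree:
    """A phylogenetic tree with branch lengths in substitutions per site.

    ``edges`` holds, for every non-root clade, its branch length together
    with the set of leaf names below it; this is the representation used for
    branch-length-score computation.
    """

    tree: object  # Bio.Phylo tree
    leaf_names: tuple[str, ...]
    total_branch_length: float
    edges: tuple[tuple[float, frozenset[str]], ...]

    @classmethod
    def from_biopython(cls, tree) -> "PhyloTree":
        leaves = [t.name for t in tree.get_terminals()]
        if len(set(leaves)) != len(leaves):
            dup = sorted({n for n in leaves if leaves.count(n) > 1})
            raise FormatError(f"duplicate leaf names in tree: {dup}")
        edges = []
        total = 0.0
        for clade in tree.find_clades():
            if clade is tree.root:
                continue
            if clade.branch_length is None:
                raise FormatError(
                    f"missing branch length on clade {clade.name or '<internal>'}"
                )
            if clade.branch_length < 0:
                raise FormatError("negative branch length")
            below = frozenset(t.name for t in clade.get_terminals())
            edges.append((float(clade.branch_length), below))
            total += float(clade.branch_length)
        return cls(
            tree=tree,
            leaf_names=tuple(leaves),
            total_branch_length=total,
            edges=tuple(edges),
        )

    def spanning_branch_length(self, species: Iterable[str]) -> float:
        """Branch length of the minimal subtree connecting ``species``.

        An edge belongs to the spanning subtree iff it separates two members
        of the set, i.e. both the leaf set below the edge and its complement
        contain at least one member.
        """
        s = frozenset(species)
        unknown = s - set(self.leaf_names)
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        if len(s) < 2:
            return 0.0
        total = 0.0
        for bl, below in self.edges:
            inside = s & below
            if inside and len(inside) < len(s):
                total += bl
        return total


@dataclass
class AlignmentBlock:
    """One MAF alignment block, reference row in plus-strand coordinates."""

    ref_species: str
    interval: GenomicInterval  # reference span, plus strand
    rows: dict[str, str]  # species -> gapped text (includes the reference)

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"alignment block at {self.interval.seq_id}:{self.interval.start}: "
                f"unequal gapped row lengths {sorted(lengths)}"
            )
        ref = self.rows.get(self.ref_species)
        if ref is None:
            raise FormatError("reference species missing from its own block")
        ungapped = len(ref) - ref.count("-")
        if ungapped != self.interval.length:
            raise FormatError(
                "ungapped reference length does not match interval length"
            )
        self._ref_cols: list[int] | None = None

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def _columns(self) -> list[int]:
        """Alignment column index of each ungapped reference position."""
        if self._ref_cols is None:
            ref = self.rows[self.ref_species]
            if "-" not in ref:
                self._ref_cols = list(range(len(ref)))
            else:
                self._ref_cols = [i for i, ch in enumerate(ref) if ch != "-"]
        return self._ref_cols

    def extract(self, species: str, start: int, end: int) -> str | None:
        """Ungapped text of ``species`` over reference window ``[start, end)``.

        The window is clipped to the block; returns None if the species is
        absent from this block or the clipped window is empty.
        """
        if species not in self.rows:
            return None
        start = max(start, self.interval.start)
        end = min(end, self.interval.end)
        if start >= end:
            return None
        cols = self._columns()
        c0 = cols[start - self.interval.start]
        c1 = cols[end - self.interval.start - 1] + 1
        return self.rows[species][c0:c1].replace("-", "")


@dataclass(frozen=True)
class ClipCluster:
    """A CLIP tag cluster with its peak position and peak height (PH)."""

    interval: GenomicInterval
    peak_position: int
    peak_height: int

    def __post_init__(self) -> None:
        if not self.interval.contains_point(self.peak_position):
            raise ValueError(
                f"peak {self.peak_position} outside cluster "
                f"{self.interval.seq_id}:{self.interval.start}-{self.interval.end}"
            )
        if self.peak_height < 1:
            raise ValueError("peak height must be >= 1")


class AccessibilityTrack:
    """Per-base single-strandedness probabilities in [0, 1].

    Backed by one dense float array per sequence (NaN = missing), which keeps
    lookups O(1) at transcriptome scale while allowing sparse coverage.
    """

    def __init__(self) -> None:
        self._arrays: dict[str, np.ndarray] = {}

    def set_range(self, seq_id: str, start: int, end: int, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"accessibility value {value} outside [0, 1]")
        if start < 0 or end <= start:
            raise ValueError("invalid range")
        arr = self._arrays.get(seq_id)
        if arr is None or len(arr) < end:
            new = np.full(max(end, 256, 2 * len(arr) if arr is not None else 0), np.nan)
            if arr is not None:
                new[: len(arr)] = arr
            self._arrays[seq_id] = arr = new
        arr[start:end] = value

    def set_array(self, seq_id: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("accessibility values outside [0, 1]")
        self._arrays[seq_id] = values.copy()

    def get(self, seq_id: str, pos: int) -> float | None:
        arr = self._arrays.get(seq_id)
        if arr is None or pos < 0 or pos >= len(arr):
            return None
        v = arr[pos]
        return None if np.isnan(v) else float(v)

    def window(self, seq_id: str, start: int, end: int) -> np.ndarray:
        """Values over ``[start, end)``; missing positions are NaN."""
        out = np.full(end - start, np.nan)
        arr = self._arrays.get(seq_id)
        if arr is not None:
            lo = max(start, 0)
            hi = min(end, len(arr))
            if hi > lo:
                out[lo - start : hi - start] = arr[lo:hi]
        return out

    def seq_ids(self) -> tuple[str, ...]:
        return tuple(self._arrays)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{seq_id: sequence}``.

    U/u are normalized to T/t; case is otherwise preserved (lowercase is the
    repeat-masked convention, available to callers).
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head == "":
        raise FormatError(f"{path}: empty FASTA file")
    if not head.startswith(">"):
        raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).replace("U", "T").replace("u", "t")
        bad = set(seq) - _VALID_SEQ_LETTERS
        if bad:
            raise FormatError(
                f"{path}: sequence {rec.id}: invalid letters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_int(text: str, what: str, path: Path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what}: {text!r}") from None


def read_bed(path: str | Path, kind: str = "interval"):
    """Read a BED6(+) file.

    kind='interval' -> list[GenomicInterval]
    kind='clip'     -> list[ClipCluster]   (cols 7-8: peak position, PH)
    kind='cluster'  -> list[ClusterCall]   (score col 5; cols 7-8: n_sites,
                                            comma-separated member starts)

    Records are returned sorted by (seq_id, start).
    """
    if kind not in ("interval", "clip", "cluster"):
        raise ValueError(f"unknown BED kind {kind!r}")
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            seq_id = cols[0]
            start = _parse_int(cols[1], "start", path, lineno)
            end = _parse_int(cols[2], "end", path, lineno)
            strand = cols[5]
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            try:
                iv = GenomicInterval(seq_id, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if kind == "interval":
                out.append(iv)
            elif kind == "clip":
                if len(cols) < 8:
                    raise FormatError(f"{path}:{lineno}: CLIP BED needs 8 columns")
                peak = _parse_int(cols[6], "peak position", path, lineno)
                ph = _parse_int(cols[7], "peak height", path, lineno)
                try:
                    out.append(ClipCluster(iv, peak, ph))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            else:
                from .hmm_core import ClusterCall  # local import: avoids a cycle

                if len(cols) < 8:
                    raise FormatError(f"{path}:{lineno}: cluster BED needs 8 columns")
                n_sites = _parse_int(cols[6], "n_sites", path, lineno)
                starts = tuple(
                    _parse_int(s, "member start", path, lineno)
                    for s in cols[7].split(",")
                    if s
                )
                out.append(
                    ClusterCall(
                        interval=iv,
                        n_sites=n_sites,
                        score=float(cols[4]),
                        member_starts=starts,
                    )
                )
    key = lambda r: (r.interval.seq_id, r.interval.start) if hasattr(r, "interval") else (r.seq_id, r.start)
    out.sort(key=key)
    return out


def write_bed(records: Sequence, path: str | Path) -> None:
    """Write intervals, CLIP clusters or cluster calls as BED6(+)."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                fh.write(
                    f"{rec.seq_id}\t{rec.start}\t{rec.end}\t.\t0\t{rec.strand}\n"
                )
            elif isinstance(rec, ClipCluster):
                iv = rec.interval
                fh.write(
                    f"{iv.seq_id}\t{iv.start}\t{iv.end}\tclip\t0\t{iv.strand}"
                    f"\t{rec.peak_position}\t{rec.peak_height}\n"
                )
            else:  # ClusterCall (duck-typed to avoid importing hmm_core here)
                iv = rec.interval
                starts = ",".join(str(s) for s in rec.member_starts)
                fh.write(
                    f"{iv.seq_id}\t{iv.start}\t{iv.end}\tcluster\t{rec.score:.2f}"
                    f"\t{iv.strand}\t{rec.n_sites}\t{starts}\n"
                )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read BED12 gene annotations (thickStart/thickEnd = CDS bounds)."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            seq_id = cols[0]
            start = _parse_int(cols[1], "start", path, lineno)
            end = _parse_int(cols[2], "end", path, lineno)
            name = cols[3]
            strand = cols[5]
            thick_start = _parse_int(cols[6], "thickStart", path, lineno)
            thick_end = _parse_int(cols[7], "thickEnd", path, lineno)
            n_blocks = _parse_int(cols[9], "blockCount", path, lineno)
            sizes = [int(s) for s in cols[10].rstrip(",").split(",")]
            offsets = [int(s) for s in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [
                GenomicInterval(seq_id, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            ]
            cds_start = cds_end = None
            if thick_end > thick_start:
                cds_start, cds_end = thick_start, thick_end
            out.append(
                TranscriptModel(
                    id=name,
                    interval=GenomicInterval(seq_id, start, end, strand),
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    out.sort(key=lambda t: (t.interval.seq_id, t.interval.start))
    return out


def write_bed12(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for t in transcripts:
            iv = t.interval
            thick_start = t.cds_start if t.is_coding else iv.start
            thick_end = t.cds_end if t.is_coding else iv.start
            sizes = ",".join(str(e.length) for e in t.exons) + ","
            offsets = ",".join(str(e.start - iv.start) for e in t.exons) + ","
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{t.id}\t0\t{iv.strand}"
                f"\t{thick_start}\t{thick_end}\t0\t{len(t.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    """Split a MAF src field 'species.chrom' (chrom may contain dots)."""
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def read_maf(path: str | Path, ref_species: str | None = None) -> list[AlignmentBlock]:
    """Read MAF alignment blocks.

    The first 's' row of each block is the reference.  Minus-strand reference
    rows are converted to plus-strand coordinates with every row
    reverse-complemented.  Blocks are returned sorted by reference
    (seq_id, start).
    """
    path = Path(path)
    blocks = []
    try:
        alignments = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    for aln in alignments:
        if len(aln) == 0:
            continue
        ref = aln[0]
        sp0, chrom = _split_src(ref.id)
        if ref_species is not None and sp0 != ref_species:
            raise FormatError(
                f"{path}: block reference {sp0!r} != expected {ref_species!r}"
            )
        strand = ref.annotations["strand"]
        start = int(ref.annotations["start"])
        size = int(ref.annotations["size"])
        src_size = int(ref.annotations["srcSize"])
        flip = strand in (-1, "-")
        if flip:
            start = src_size - start - size
        rows = {}
        for rec in aln:
            sp, _ = _split_src(rec.id)
            text = str(rec.seq)
            if flip:
                text = reverse_complement(text)
            rows[sp] = text
        blocks.append(
            AlignmentBlock(
                ref_species=sp0,
                interval=GenomicInterval(chrom, start, start + size),
                rows=rows,
            )
        )
    blocks.sort(key=lambda b: (b.interval.seq_id, b.interval.start))
    return blocks


def write_maf(blocks: Sequence[AlignmentBlock], path: str | Path,
              src_sizes: Mapping[str, int] | None = None) -> None:
    """Write alignment blocks as MAF (plus strand).

    ``src_sizes`` maps species to source sequence length; for non-reference
    rows the ungapped row length is used as start-anchor-free placeholder
    coordinates (start 0), which is sufficient for the window extraction done
    here (keyed on the reference row only).
    """
    alignments = []
    for b in blocks:
        recs = []
        ref_len = b.interval.length
        for sp, text in b.rows.items():
            ungapped = len(text) - text.count("-")
            if sp == b.ref_species:
                start, size = b.interval.start, ref_len
                src = f"{sp}.{b.interval.seq_id}"
                src_size = (src_sizes or {}).get(sp, b.interval.end)
            else:
                start, size = 0, ungapped
                src = f"{sp}.{b.interval.seq_id}"
                src_size = (src_sizes or {}).get(sp, ungapped)
            recs.append(
                SeqRecord(
                    Seq(text),
                    id=src,
                    annotations={
                        "start": start,
                        "size": size,
                        "strand": "+",
                        "srcSize": max(src_size, start + size),
                    },
                )
            )
        alignments.append(MultipleSeqAlignment(recs))
    with open(path, "w", newline="\n") as fh:
        AlignIO.write(alignments, fh, "maf")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> PhyloTree:
    tree = Phylo.read(str(path), "newick")
    return PhyloTree.from_biopython(tree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Phylo.write(tree.tree, str(path), "newick")


# ---------------------------------------------------------------------------
# accessibility tracks (bedGraph / fixed-step WIG)
# ---------------------------------------------------------------------------

_FIXEDSTEP_RE = re.compile(r"fixedStep\s+chrom=(\S+)\s+start=(\d+)\s+step=(\d+)(?:\s+span=(\d+))?")


def read_accessibility(path: str | Path) -> AccessibilityTrack:
    """Read a bedGraph or fixed-step WIG track of per-base values in [0, 1]."""
    path = Path(path)
    track = AccessibilityTrack()
    chrom = None
    pos = step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            m = _FIXEDSTEP_RE.match(line)
            if m:
                chrom = m.group(1)
                pos = int(m.group(2)) - 1  # WIG is 1-based
                step = int(m.group(3))
                span = int(m.group(4) or 1)
                continue
            cols = line.split()
            if len(cols) == 1 and chrom is not None:
                value = float(cols[0])
                try:
                    track.set_range(chrom, pos, pos + span, value)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                pos += step
            elif len(cols) == 4:
                start = _parse_int(cols[1], "start", path, lineno)
                end = _parse_int(cols[2], "end", path, lineno)
                if start >= end:
                    raise FormatError(f"{path}:{lineno}: start >= end")
                try:
                    track.set_range(cols[0], start, end, float(cols[3]))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            else:
                raise FormatError(f"{path}:{lineno}: unrecognized track line")
    return track


def write_bedgraph(track: AccessibilityTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging runs of equal value."""
    with open(path, "w", newline="\n") as fh:
        for seq_id in track.seq_ids():
            arr = track._arrays[seq_id]
            n = len(arr)
            i = 0
            while i < n:
                if np.isnan(arr[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                    j += 1
                fh.write(f"{seq_id}\t{i}\t{j}\t{arr[i]:g}\n")
                i = j


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals (per seq_id)."""
    by_seq: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_seq.setdefault((iv.seq_id, iv.strand), []).append(iv)
    out = []
    for (seq_id, strand), ivs in sorted(by_seq.items()):
        ivs.sort(key=lambda i: i.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(seq_id, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(seq_id, cur_start, cur_end, strand))
    out.sort(key=lambda i: (i.seq_id, i.start))
    return out


def intervals_cover(merged: Sequence[GenomicInterval], target: GenomicInterval) -> bool:
    """True iff ``target`` lies fully inside the merged interval union."""
    for iv in merged:
        if iv.seq_id == target.seq_id and iv.start <= target.start and target.end <= iv.end:
            return True
    return False


# ---------------------------------------------------------------------------
# region segmentation
# ---------------------------------------------------------------------------

def build_region_segments(transcript: TranscriptModel, ext: int = 1000) -> TranscriptModel:
    """Attach region segments tiling ``[start - ext, end + ext)``.

    Exonic sequence of coding transcripts is split into 5'UTR / CDS / 3'UTR
    by the CDS bounds; exons of non-coding transcripts are labeled
    NONCODING_EXON (pooled with the intron conservation stratum).  Introns
    are labeled INTRON and the ``ext``-nt regions beyond the transcript ends
    FLANK.  Segments are ordered 5'->3' in transcript orientation.
    """
    if ext < 0:
        raise ValueError("ext must be >= 0")
    iv = transcript.interval
    if transcript.is_coding and not (
        iv.start <= transcript.cds_start < transcript.cds_end <= iv.end
    ):
        raise ValueError(f"transcript {transcript.id}: CDS bounds outside transcript")

    # breakpoints in genomic order
    segments: list[tuple[GenomicInterval, SegmentLabel]] = []
    if ext > 0:
        flank_start = max(0, iv.start - ext)
        if flank_start < iv.start:
            segments.append(
                (GenomicInterval(iv.seq_id, flank_start, iv.start, iv.strand), SegmentLabel.FLANK)
            )
    for i, exon in enumerate(transcript.exons):
        segments.extend(_exon_segments(transcript, exon))
        if i + 1 < len(transcript.exons):
            nxt = transcript.exons[i + 1]
            if nxt.start > exon.end:
                segments.append(
                    (GenomicInterval(iv.seq_id, exon.end, nxt.start, iv.strand), SegmentLabel.INTRON)
                )
    if ext > 0:
        segments.append(
            (GenomicInterval(iv.seq_id, iv.end, iv.end + ext, iv.strand), SegmentLabel.FLANK)
        )
    segments.sort(key=lambda s: s[0].start)
    if iv.strand == "-":
        segments.reverse()
    return replace(transcript, region_segments=segments)


def _exon_segments(
    t: TranscriptModel, exon: GenomicInterval
) -> list[tuple[GenomicInterval, SegmentLabel]]:
    iv = t.interval
    if not t.is_coding:
        return [(exon, SegmentLabel.NONCODING_EXON)]
    # genomic-left of the CDS is 5'UTR on plus strand, 3'UTR on minus strand
    left_label = SegmentLabel.FIVE_UTR if iv.strand == "+" else SegmentLabel.THREE_UTR
    right_label = SegmentLabel.THREE_UTR if iv.strand == "+" else SegmentLabel.FIVE_UTR
    pieces = []
    cuts = [
        (exon.start, min(exon.end, max(exon.start, t.cds_start)), left_label),
        (max(exon.start, t.cds_start), min(exon.end, t.cds_end), SegmentLabel.CDS),
        (max(exon.start, min(exon.end, t.cds_end)), exon.end, right_label),
    ]
    for s, e, label in cuts:
        if e > s:
            pieces.append((GenomicInterval(iv.seq_id, s, e, iv.strand), label))
    return pieces


def exon_ext_mask(transcript: TranscriptModel, ext: int = 1000) -> list[GenomicInterval]:
    """The exon+ext mask: exons, the first/last ``ext`` nt of each intron,
    and the ``ext``-nt flanks beyond the transcript ends, merged."""
    iv = transcript.interval
    parts = list(transcript.exons)
    if ext > 0:
        for intron in transcript.introns:
            parts.append(
                GenomicInterval(iv.seq_id, intron.start, min(intron.end, intron.start + ext), iv.strand)
            )
            parts.append(
                GenomicInterval(iv.seq_id, max(intron.start, intron.end - ext), intron.end, iv.strand)
            )
    if ext > 0:
        if iv.start > 0:
            parts.append(GenomicInterval(iv.seq_id, max(0, iv.start - ext), iv.start, iv.strand))
        parts.append(GenomicInterval(iv.seq_id, iv.end, iv.end + ext, iv.strand))
    return merge_intervals(parts)
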