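"""End-to-end wiring: dataset -> scan -> featurize -> train -> predict.

A :class:`Dataset` bundles the in-memory inputs every stage needs; it can be
built from a simulated dataset or loaded from the standard files.  The
functions here are thin compositions of the per-module operations and are
what the command-line interface and the validation experiments call.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .features import SiteFeatures, featurize_all
from .hmm_core import ClusterCall, HmmModel, call_clusters, viterbi
from .io_formats import (
    AccessibilityTrack,
    AlignmentBlock,
    ClipCluster,
    GenomicInterval,
    PhyloTree,
    TranscriptModel,
    build_region_segments,
    exon_ext_mask,
    read_accessibility,
    read_bed,
    read_bed12,
    read_fasta,
    read_maf,
    read_newick,
)
from .motif_scan import IupacConsensus, MotifSite, mark_repetitive, scan_region_set
from .simulate import SimData
from .training import (
    LabeledSiteSequence,
    TrainingConfig,
    build_labeled_sequences,
    build_training_sets,
    train,
)

__all__ = ["Dataset", "scan_dataset", "featurize_dataset", "train_model", "predict"]


@dataclass
class Dataset:
    """All inputs of a prediction run, in memory."""

    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    blocks_by_seq: dict[str, list[AlignmentBlock]]
    tree: PhyloTree
    ref_species: str
    track: AccessibilityTrack | None
    clip: list[ClipCluster]
    consensus: IupacConsensus
    repeats: list[GenomicInterval] | None = None

    @classmethod
    def from_sim(cls, data: SimData) -> "Dataset":
        return cls(
            sequences=data.sequences,
            transcripts=data.transcripts,
            blocks_by_seq=data.blocks_by_seq,
            tree=data.tree,
            ref_species=data.ref_species,
            track=data.track,
            clip=data.clip,
            consensus=data.consensus,
        )

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        annotation_bed12: str | Path,
        maf: str | Path,
        tree_newick: str | Path,
        ref_species: str,
        consensus: IupacConsensus,
        accessibility: str | Path | None = None,
        clip_bed: str | Path | None = None,
        repeats_bed: str | Path | None = None,
        ext: int = 1000,
    ) -> "Dataset":
        sequences = read_fasta(fasta)
        transcripts = [
            build_region_segments(t, ext=ext) for t in read_bed12(annotation_bed12)
        ]
        blocks_by_seq: dict[str, list[AlignmentBlock]] = {}
        for b in read_maf(maf):
            blocks_by_seq.setdefault(b.interval.seq_id, []).append(b)
        return cls(
            sequences=sequences,
            transcripts=transcripts,
            blocks_by_seq=blocks_by_seq,
            tree=read_newick(tree_newick),
            ref_species=ref_species,
            track=read_accessibility(accessibility) if accessibility else None,
            clip=read_bed(clip_bed, kind="clip") if clip_bed else [],
            consensus=consensus,
            repeats=read_bed(repeats_bed, kind="interval") if repeats_bed else None,
        )

    def subset(self, gene_ids: Sequence[str]) -> "Dataset":
        """Restrict to the given transcripts (and their sequences)."""
        keep = set(gene_ids)
        transcripts = [t for t in self.transcripts if t.id in keep]
        seqs = {t.interval.seq_id for t in transcripts}
        return Dataset(
            sequences={k: v for k, v in self.sequences.items() if k in seqs},
            transcripts=transcripts,
            blocks_by_seq={k: v for k, v in self.blocks_by_seq.items() if k in seqs},
            tree=self.tree,
            ref_species=self.ref_species,
            track=self.track,
            clip=[c for c in self.clip if c.interval.seq_id in seqs],
            consensus=self.consensus,
            repeats=self.repeats,
        )


def scan_dataset(
    ds: Dataset, ext: int = 1000, mask: str = "genic_ext"
) -> dict[str, list[MotifSite]]:
    """Scan all sequences, masked to extended genic regions.

    mask='genic_ext' (prediction): the contiguous gene body plus ``ext`` nt
    on each side.  mask='exon_ext' (training-set construction): exons plus
    the first/last ``ext`` nt of each intron plus flanks.
    """
    if mask == "genic_ext":
        intervals = []
        for t in ds.transcripts:
            iv = t.interval
            intervals.append(
                GenomicInterval(
                    iv.seq_id, max(0, iv.start - ext), iv.end + ext, iv.strand
                )
            )
    elif mask == "exon_ext":
        intervals = [m for t in ds.transcripts for m in exon_ext_mask(t, ext)]
    else:
        raise ValueError(f"unknown mask kind {mask!r}")
    sites = scan_region_set(ds.sequences, intervals, ds.consensus)
    if ds.repeats:
        sites = {k: mark_repetitive(v, ds.repeats) for k, v in sites.items()}
    return sites


def featurize_dataset(
    ds: Dataset,
    sites_by_seq: Mapping[str, Sequence[MotifSite]],
    d_cens: int = 30,
    missing_policy: str = "drop_feature",
    bls_slop: int = 0,
) -> dict[str, list[SiteFeatures]]:
    return featurize_all(
        sites_by_seq,
        ds.blocks_by_seq,
        ds.tree,
        ds.ref_species,
        ds.consensus,
        ds.track,
        ds.transcripts,
        d_cens=d_cens,
        missing_policy=missing_policy,
        bls_slop=bls_slop,
    )


def train_model(
    ds: Dataset,
    sites_by_seq: Mapping[str, Sequence[MotifSite]],
    feats_by_seq: Mapping[str, Sequence[SiteFeatures]],
    feature_set: Sequence[str] = ("d", "c", "a"),
    config: TrainingConfig = TrainingConfig(),
) -> HmmModel:
    """Supervised training from the dataset's CLIP clusters."""
    positives, negatives = build_training_sets(
        ds.clip, ds.transcripts, ds.repeats or (), config
    )
    labeled = build_labeled_sequences(
        positives, negatives, sites_by_seq, feats_by_seq, config
    )
    return train(labeled, feature_set=feature_set, config=config)


def predict(
    model: HmmModel,
    sites_by_seq: Mapping[str, Sequence[MotifSite]],
    feats_by_seq: Mapping[str, Sequence[SiteFeatures]],
    min_sites: int = 3,
    min_score: float | None = None,
) -> list[ClusterCall]:
    """Viterbi-decode every scan sequence and extract scored cluster calls."""
    calls: list[ClusterCall] = []
    for seq_id in sorted(sites_by_seq):
        sites = sites_by_seq[seq_id]
        if not sites:
            continue
        feats = feats_by_seq[seq_id]
        path = viterbi(model, feats)
        calls.extend(
            call_clusters(
                model, path, sites, feats, min_sites=min_sites, min_score=min_score
            )
        )
    return calls
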