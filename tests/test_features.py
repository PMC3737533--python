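"""Spacing censoring, branch-length-score conservation, accessibility and
region assignment."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import tree_from_newick
from mclusthmm.features import (
    BlsCache,
    SiteFeatures,
    assign_region,
    compute_accessibility,
    compute_bls,
    compute_spacing,
)
from mclusthmm.io_formats import (
    AccessibilityTrack,
    AlignmentBlock,
    GenomicInterval,
    RegionType,
    TranscriptModel,
    build_region_segments,
)
from mclusthmm.motif_scan import IupacConsensus, MotifSite


class TestSpacing:
    @pytest.mark.parametrize(
        "starts,expected",
        [
            ([0, 10, 55], [0, 10, 30]),
            ([7], [0]),
            ([0, 2], [0, 2]),
            ([5, 35, 36], [0, 30, 1]),
        ],
    )
    def test_censored_distances(self, starts, expected):
        assert compute_spacing(starts, d_cens=30) == expected

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            compute_spacing([10, 5])

    def test_censoring_idempotence(self):
        # any distance >= the censor point yields identical features
        a = compute_spacing([0, 30, 60])
        b = compute_spacing([0, 30, 5000])
        assert a == b


# ---------------------------------------------------------------------------
# BLS
# ---------------------------------------------------------------------------

CONS = IupacConsensus("YCAY")


def _block(rows: dict[str, str], start=0) -> AlignmentBlock:
    length = len(rows["A"]) - rows["A"].count("-")
    return AlignmentBlock(
        ref_species="A",
        interval=GenomicInterval("g", start, start + length),
        rows=rows,
    )


def _site(start=0) -> MotifSite:
    return MotifSite(seq_id="g", start=start, end=start + 4, word="TCAT")


class TestBls:
    def test_conserved_in_two_of_three_species(self, toy_tree):
        block = _block({"A": "TCAT", "B": "TCAC", "C": "GGGG"})
        c = compute_bls(_site(), [block], toy_tree, "A", CONS)
        assert c == pytest.approx(0.375, abs=1e-12)

    def test_full_conservation(self, toy_tree):
        block = _block({"A": "TCAT", "B": "TCAT", "C": "CCAC"})
        assert compute_bls(_site(), [block], toy_tree, "A", CONS) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_reference_only_is_zero(self, toy_tree):
        block = _block({"A": "TCAT", "B": "GGGG", "C": "GGGG"})
        assert compute_bls(_site(), [block], toy_tree, "A", CONS) == 0.0

    def test_unaligned_site_is_zero(self, toy_tree):
        assert compute_bls(_site(500), [], toy_tree, "A", CONS) == 0.0

    def test_zero_length_tree_is_zero(self):
        tree = tree_from_newick("(A:0.0,B:0.0);")
        block = _block({"A": "TCAT", "B": "TCAT"})
        assert compute_bls(_site(), [block], tree, "A", CONS) == 0.0

    def test_unknown_reference_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="reference"):
            compute_bls(_site(), [], toy_tree, "Z", CONS)

    def test_species_gap_handling(self, toy_tree):
        # B has a deletion spanning the site; its ungapped window TCT has no match
        block = _block({"A": "TCAT", "B": "TC-T", "C": "TCAC"})
        c = compute_bls(_site(), [block], toy_tree, "A", CONS)
        # retained = {A, C}: edges A(0.1), AB(0.1), C(0.4) -> 0.6/0.8
        assert c == pytest.approx(0.75, abs=1e-12)


def _random_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology with random branch lengths, as newick."""
    nodes = [f"L{i}:{rng.uniform(0.01, 1.0):.4f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b});")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.01, 1.0):.4f}")
    return nodes[0]


def _oracle_spanning_length(tree, members: set[str]) -> float:
    """Edge belongs to the spanning subtree iff it lies on a path between
    two members: checked per edge via explicit root-to-leaf paths."""
    paths = {t.name: tree.tree.get_path(t) for t in tree.tree.get_terminals()}
    total = 0.0
    seen = set()
    for x, y in itertools.combinations(sorted(members), 2):
        px = set(id(c) for c in paths[x])
        py = set(id(c) for c in paths[y])
        for c in paths[x] + paths[y]:
            if (id(c) in px) != (id(c) in py) and id(c) not in seen:
                seen.add(id(c))
                total += c.branch_length
    return total


class TestBlsProperties:
    def test_matches_edge_path_oracle_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(3, 12))
            tree = tree_from_newick(_random_tree(rng, n))
            k = int(rng.integers(1, n + 1))
            members = set(rng.choice(tree.leaf_names, size=k, replace=False))
            got = tree.spanning_branch_length(members)
            want = _oracle_spanning_length(tree, members)
            assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(3, 10))
            tree = tree_from_newick(_random_tree(rng, n))
            members: set[str] = {tree.leaf_names[0]}
            prev = tree.spanning_branch_length(members)
            for leaf in tree.leaf_names[1:]:
                members.add(leaf)
                cur = tree.spanning_branch_length(members)
                assert cur >= prev - 1e-12
                prev = cur


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------

class TestAccessibilityFeature:
    def _track(self, values, start=0):
        track = AccessibilityTrack()
        arr = np.full(start + len(values), np.nan)
        arr[start:] = values
        track.set_array("g", arr)
        return track

    def test_mean_over_site(self):
        track = self._track([0.2, 0.4, 0.6, 0.8])
        assert compute_accessibility(_site(), track) == pytest.approx(0.5)

    def test_all_ones(self):
        assert compute_accessibility(_site(), self._track([1, 1, 1, 1])) == 1.0

    def test_missing_base_drop_feature(self):
        track = self._track([0.2, np.nan, 0.6, 0.8])
        assert compute_accessibility(_site(), track, "drop_feature") is None

    def test_missing_base_mean_of_present(self):
        track = self._track([0.2, np.nan, 0.6, 0.7])
        assert compute_accessibility(_site(), track, "mean_of_present") == pytest.approx(0.5)

    def test_fully_missing_is_none_under_both_policies(self):
        track = AccessibilityTrack()
        for policy in ("drop_feature", "mean_of_present"):
            assert compute_accessibility(_site(), track, policy) is None


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def _coding_transcript(seq_id="g"):
    return build_region_segments(
        TranscriptModel(
            id="t",
            interval=GenomicInterval(seq_id, 100, 300),
            exons=[GenomicInterval(seq_id, 100, 180), GenomicInterval(seq_id, 240, 300)],
            cds_start=120,
            cds_end=260,
        ),
        ext=50,
    )


class TestAssignRegion:
    def test_start_base_rule_spanning_boundary(self):
        # site starts in CDS (at 178) and ends in the intron
        t = _coding_transcript()
        site = MotifSite("g", 178, 182, "TCAT")
        assert assign_region(site, [t]) is RegionType.CDS

    def test_isoform_conflict_priority(self):
        t1 = _coding_transcript()
        t2 = build_region_segments(
            TranscriptModel(
                id="t2",
                interval=GenomicInterval("g", 100, 300),
                exons=[GenomicInterval("g", 100, 300)],
            ),
            ext=50,
        )  # calls everything the intron stratum
        site = MotifSite("g", 130, 134, "TCAT")
        assert assign_region(site, [t1, t2]) is RegionType.CDS

    def test_flank_maps_to_intron(self):
        site = MotifSite("g", 60, 64, "TCAT")
        assert assign_region(site, [_coding_transcript()]) is RegionType.INTRON

    def test_outside_annotation_warns_and_maps_to_intron(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mclusthmm.features"):
            region = assign_region(MotifSite("g", 5000, 5004, "TCAT"), [_coding_transcript()])
        assert region is RegionType.INTRON
        assert any("outside all annotation" in r.message for r in caplog.records)


def test_site_features_validate_ranges():
    with pytest.raises(ValueError):
        SiteFeatures(d=-1, c=0.5, a=0.5)
    with pytest.raises(ValueError):
        SiteFeatures(d=0, c=1.5, a=0.5)
    with pytest.raises(ValueError):
        SiteFeatures(d=0, c=0.5, a=-0.1)


def test_bls_cache_consistent_with_direct_computation(toy_tree):
    cache = BlsCache(toy_tree)
    block = _block({"A": "TCAT", "B": "TCAC", "C": "GGGG"})
    direct = compute_bls(_site(), [block], toy_tree, "A", CONS)
    cached = compute_bls(_site(), [block], toy_tree, "A", CONS, cache=cache)
    assert direct == cached == pytest.approx(0.375)
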