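"""Training-set construction, emission/transition estimation and full
supervised training."""
from __future__ import annotations

import numpy as np
import pytest

from mclusthmm.features import SiteFeatures
from mclusthmm.hmm_core import ALLOWED_EDGES, HmmState, score_cluster
from mclusthmm.io_formats import ClipCluster, GenomicInterval, TranscriptModel
from mclusthmm.simulate import ShiftedGeometric, SimSpec, simulate_labeled_corpus
from mclusthmm.training import (
    FeatureDistribution,
    LabeledSiteSequence,
    TrainingConfig,
    build_training_sets,
    estimate_distribution,
    estimate_transitions,
    labels_to_states,
    train,
)


class TestEstimateDistribution:
    def test_laplace_smoothing_by_hand(self):
        dist = estimate_distribution([1, 1, 3], "d", pseudocount=1.0, d_cens=3)
        assert dist.masses == pytest.approx([3 / 6, 1 / 6, 2 / 6])

    def test_empty_bins_keep_positive_mass(self):
        dist = estimate_distribution([0.05] * 10, "c", bins=4, pseudocount=0.5)
        assert np.all(dist.masses > 0)
        assert dist.masses[0] == pytest.approx((10 + 0.5) / (10 + 4 * 0.5))

    def test_all_identical_values(self):
        dist = estimate_distribution([7] * 50, "d", pseudocount=1.0, d_cens=10)
        assert dist.bin_index(7) == np.argmax(dist.masses)
        assert dist.masses.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "values,feature", [([0], "d"), ([31], "d"), ([-0.1], "c"), ([1.1], "a")]
    )
    def test_out_of_range_rejected(self, values, feature):
        with pytest.raises(ValueError):
            estimate_distribution(values, feature)

    def test_zero_values_rejected(self):
        with pytest.raises(ValueError):
            estimate_distribution([], "c")

    def test_censored_bin_absorbs_larger_values(self):
        dist = estimate_distribution([5, 30], "d", d_cens=30)
        assert dist.bin_index(30) == 29
        assert dist.bin_index(400) == 29  # lookups censor too
        assert dist.logpmf(30) == dist.logpmf(1000)


class TestTransitions:
    def test_label_to_state_mapping(self):
        states = labels_to_states(["-", "-", "+", "+", "-"])
        assert states == [
            HmmState.S_MINUS,
            HmmState.MINUS,
            HmmState.I_PLUS,
            HmmState.PLUS,
            HmmState.I_MINUS,
        ]

    def test_switch_counts(self):
        trans, initial = estimate_transitions([["-", "-", "+", "+", "-"]], pseudocount=1.0)
        # count(- -> I+) = 1, count(- -> -) = 0; pseudocount 1 on both edges
        assert trans[(HmmState.MINUS, HmmState.I_PLUS)] == pytest.approx((1 + 1) / (1 + 2))
        assert trans[(HmmState.PLUS, HmmState.I_MINUS)] == pytest.approx((1 + 1) / (1 + 2))

    def test_all_negative_corpus(self):
        seqs = [["-"] * 50 for _ in range(20)]
        trans, initial = estimate_transitions(seqs, pseudocount=0.01)
        assert initial[HmmState.S_MINUS] > 0.99
        assert trans[(HmmState.MINUS, HmmState.MINUS)] > 0.99

    def test_single_positive_site_updates_initials_only(self):
        trans, initial = estimate_transitions([["+"]], pseudocount=1.0)
        assert initial[HmmState.S_PLUS] == pytest.approx(2 / 3)
        # every transition row is pure pseudocount -> uniform over 2 targets
        for src, dsts in ALLOWED_EDGES.items():
            for d in dsts:
                assert trans[(src, d)] == pytest.approx(0.5)

    def test_rows_normalize_over_allowed_edges_only(self):
        rng = np.random.default_rng(0)
        seqs = [
            ["+" if x < 0.5 else "-" for x in rng.random(rng.integers(1, 30))]
            for _ in range(50)
        ]
        trans, initial = estimate_transitions(seqs)
        for src, dsts in ALLOWED_EDGES.items():
            assert sum(trans[(src, d)] for d in dsts) == pytest.approx(1.0, abs=1e-12)
        assert set(trans) == {(s, d) for s, ds in ALLOWED_EDGES.items() for d in ds}
        assert sum(initial.values()) == pytest.approx(1.0, abs=1e-12)


def _gene(seq_id: str, start: int = 1000, length: int = 3000) -> TranscriptModel:
    from mclusthmm.io_formats import build_region_segments

    return build_region_segments(
        TranscriptModel(
            id=seq_id,
            interval=GenomicInterval(seq_id, start, start + length),
            exons=[GenomicInterval(seq_id, start, start + length)],
        ),
        ext=1000,
    )


def _clip(seq_id: str, start: int, end: int, ph: int) -> ClipCluster:
    return ClipCluster(GenomicInterval(seq_id, start, end), (start + end) // 2, ph)


class TestBuildTrainingSets:
    def test_peak_height_threshold(self):
        genes = [_gene("g1"), _gene("g2")]
        clips = [_clip("g1", 1100, 1140, 3), _clip("g1", 1300, 1340, 15), _clip("g1", 1500, 1540, 40)]
        pos, neg = build_training_sets(clips, genes, config=TrainingConfig(ph_min=15))
        assert len(pos) == 2
        assert set(neg) == {"g2"}

    def test_repeat_overlap_excludes_positive(self):
        genes = [_gene("g1"), _gene("g2")]
        clips = [_clip("g1", 1100, 1140, 20), _clip("g1", 1300, 1340, 20)]
        repeats = [GenomicInterval("g1", 1139, 1141)]  # 1-nt overlap with first
        pos, _ = build_training_sets(clips, genes, repeats=repeats)
        assert pos == [GenomicInterval("g1", 1300, 1340)]

    def test_gene_with_any_tag_not_negative_eligible(self):
        # a tag in g2 far beyond the mask still disqualifies g2 as negative
        genes = [_gene("g1"), TrainingHelperIntronGene(), _gene("g3")]
        clips = [
            _clip("g1", 1100, 1140, 20),
            _clip("g2", 6000, 6040, 2),  # mid-intron, outside exon+ext mask
        ]
        pos, neg = build_training_sets(clips, genes)
        assert set(neg) == {"g3"}

    def test_empty_positive_set_rejected(self):
        genes = [_gene("g1")]
        with pytest.raises(ValueError, match="positive"):
            build_training_sets([_clip("g1", 1100, 1140, 2)], genes)


def TrainingHelperIntronGene() -> TranscriptModel:
    """Two long exons around a 8-kb intron whose middle escapes the mask."""
    from mclusthmm.io_formats import build_region_segments

    return build_region_segments(
        TranscriptModel(
            id="g2",
            interval=GenomicInterval("g2", 1000, 11000),
            exons=[GenomicInterval("g2", 1000, 2000), GenomicInterval("g2", 10000, 11000)],
        ),
        ext=1000,
    )


def _const_label_seqs(rng, n_seqs, n_sites, label, d_mean):
    seqs = []
    for _ in range(n_seqs):
        ds = [0] + list(
            np.minimum(rng.geometric(1 / d_mean, size=n_sites - 1) + 3, 30)
        )
        feats = [
            SiteFeatures(d=int(d), c=float(rng.random()), a=float(rng.random()))
            for d in ds
        ]
        seqs.append(LabeledSiteSequence(features=feats, labels=[label] * n_sites))
    return seqs


class TestTrain:
    def test_feature_subset_model_ignores_other_features(self):
        rng = np.random.default_rng(1)
        seqs = _const_label_seqs(rng, 10, 5, "+", 4) + _const_label_seqs(rng, 10, 5, "-", 20)
        model = train(seqs, feature_set=("d",))
        assert set(k[0] for k in model.dists) == {"d"}

    def test_identical_corpora_give_zero_cluster_scores(self):
        rng = np.random.default_rng(2)
        shared = _const_label_seqs(rng, 8, 6, "+", 8)
        mirrored = [
            LabeledSiteSequence(features=s.features, labels=["-"] * len(s.labels))
            for s in shared
        ]
        model = train(shared + mirrored, feature_set=("d", "c", "a"))
        feats = shared[0].features
        assert score_cluster(model, feats, [1, 2, 3]) == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_improves_with_sample_size(self):
        spec = SimSpec(seed=99)
        truth = spec.cluster_spacing.censored_masses(30)
        kls = []
        for n in (1_000, 10_000, 100_000):
            rng = np.random.default_rng(1234)
            corpus = simulate_labeled_corpus(spec, n, 100, rng=rng)
            model = train(corpus, feature_set=("d",))
            est = model.dists[("d", "+")].masses
            kls.append(float(np.sum(truth[truth > 0] * np.log(truth[truth > 0] / est[truth > 0]))))
        assert kls[0] > kls[1] > kls[2]

    def test_distributions_strictly_positive_and_normalized(self):
        rng = np.random.default_rng(3)
        corpus = simulate_labeled_corpus(SimSpec(seed=5), 2000, 2000, rng=rng)
        model = train(corpus)
        for dist in model.dists.values():
            assert np.all(dist.masses > 0)
            assert dist.masses.sum() == pytest.approx(1.0, abs=1e-9)


def test_feature_distribution_rejects_zero_mass_bins():
    with pytest.raises(ValueError, match="smoothing"):
        FeatureDistribution("c", np.linspace(0, 1, 5), np.array([0.5, 0.5, 0.0, 0.0]))


def test_shifted_geometric_pmf_sums_to_censored_masses():
    sg = ShiftedGeometric(shift=4, mean=8.0)
    masses = sg.censored_masses(30)
    assert masses.sum() == pytest.approx(1.0, abs=1e-12)
    assert masses[:3] == pytest.approx([0.0, 0.0, 0.0])  # below the shift
    rng = np.random.default_rng(0)
    draws = sg.sample(rng, 200_000)
    assert draws.mean() == pytest.approx(8.0, rel=0.02)
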