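"""Six-state HMM: emissions per the state table, Viterbi vs exhaustive
enumeration, cluster extraction and log-likelihood-ratio scoring."""
from __future__ import annotations

import numpy as np
import pytest

from conftest import random_distribution, random_feats, random_model
from mclusthmm.features import SiteFeatures
from mclusthmm.hmm_core import (
    ALLOWED_EDGES,
    CLUSTER_STATES,
    HmmModel,
    HmmState,
    StatePath,
    brute_force_decode,
    call_clusters,
    emission_logprob,
    score_cluster,
    viterbi,
)
from mclusthmm.io_formats import RegionType
from mclusthmm.motif_scan import MotifSite
from mclusthmm.training import FeatureDistribution


def _uniform_dist(feature, d_cens=8, bins=5, stratum=None):
    if feature == "d":
        edges = np.arange(1, d_cens + 2, dtype=float)
        masses = np.full(d_cens, 1.0 / d_cens)
    else:
        edges = np.linspace(0, 1, bins + 1)
        masses = np.full(bins, 1.0 / bins)
    return FeatureDistribution(feature=feature, bin_edges=edges, masses=masses, stratum=stratum)


def symmetric_model(feature_set=("d", "c", "a")) -> HmmModel:
    """'+' and '-' components identical, transitions/initials symmetric."""
    dists = {}
    for sign in "+-":
        if "d" in feature_set:
            dists[("d", sign)] = _uniform_dist("d")
        if "c" in feature_set:
            for region in RegionType:
                dists[("c", sign, region)] = _uniform_dist("c", stratum=region)
        if "a" in feature_set:
            dists[("a", sign)] = _uniform_dist("a")
    log_trans = {
        (src, dst): float(np.log2(0.5)) for src, dsts in ALLOWED_EDGES.items() for dst in dsts
    }
    log_initial = {HmmState.S_PLUS: -1.0, HmmState.S_MINUS: -1.0}
    return HmmModel(
        feature_set=tuple(feature_set), dists=dists, log_trans=log_trans,
        log_initial=log_initial,
    )


def _sites_for(feats, seq_id="g", spacing=20):
    return [
        MotifSite(seq_id=seq_id, start=i * spacing, end=i * spacing + 4, word="TCAT", ordinal=i)
        for i in range(len(feats))
    ]


class TestEmissions:
    def test_initial_states_have_degenerate_spacing_term(self):
        model = symmetric_model()
        f = SiteFeatures(d=0, c=0.5, a=0.5)
        # S+ and S- differ only through c and a terms; both uniform -> equal
        assert emission_logprob(model, HmmState.S_PLUS, f) == emission_logprob(
            model, HmmState.S_MINUS, f
        )

    def test_initial_state_cannot_emit_real_distance(self):
        model = symmetric_model()
        f = SiteFeatures(d=3, c=0.5, a=0.5)
        assert emission_logprob(model, HmmState.S_PLUS, f) == float("-inf")

    def test_noninitial_state_cannot_emit_sentinel(self):
        model = symmetric_model()
        f = SiteFeatures(d=0, c=0.5, a=0.5)
        assert emission_logprob(model, HmmState.PLUS, f) == float("-inf")

    def test_internal_initiation_shares_background_spacing_component(self):
        rng = np.random.default_rng(0)
        model = random_model(rng, feature_set=("d",))
        for d in range(1, 9):
            f = SiteFeatures(d=d, c=0.5, a=0.5)
            assert emission_logprob(model, HmmState.I_PLUS, f) == emission_logprob(
                model, HmmState.I_MINUS, f
            )
            assert emission_logprob(model, HmmState.I_PLUS, f) == emission_logprob(
                model, HmmState.MINUS, f
            )

    def test_spacing_only_model_distinguishes_states_via_d_alone(self):
        rng = np.random.default_rng(1)
        model = random_model(rng, feature_set=("d",))
        f1 = SiteFeatures(d=2, c=0.1, a=0.9)
        f2 = SiteFeatures(d=2, c=0.9, a=0.1)
        for s in (HmmState.PLUS, HmmState.MINUS):
            assert emission_logprob(model, s, f1) == emission_logprob(model, s, f2)

    def test_missing_accessibility_skipped_symmetrically(self):
        rng = np.random.default_rng(2)
        model = random_model(rng)
        f = SiteFeatures(d=2, c=0.4, a=None)
        diff_full = emission_logprob(model, HmmState.PLUS, f) - emission_logprob(
            model, HmmState.MINUS, f
        )
        # difference must equal the d+c difference alone
        model_dc = HmmModel(
            feature_set=("d", "c"),
            dists={k: v for k, v in model.dists.items() if k[0] != "a"},
            log_trans=model.log_trans,
            log_initial=model.log_initial,
        )
        diff_dc = emission_logprob(model_dc, HmmState.PLUS, f) - emission_logprob(
            model_dc, HmmState.MINUS, f
        )
        assert diff_full == pytest.approx(diff_dc, abs=1e-12)


class TestViterbi:
    def test_tie_break_prefers_background(self):
        model = symmetric_model()
        feats = random_feats(np.random.default_rng(3), 6, with_missing_a=False)
        path = viterbi(model, feats)
        assert all(s not in CLUSTER_STATES for s in path.states)

    def test_strong_positive_emissions_yield_cluster_path(self):
        # '+' components put ~all mass where the observations fall
        d_edges = np.arange(1, 10, dtype=float)
        plus_d = np.full(8, 1e-6)
        plus_d[1] = 1 - plus_d.sum() + plus_d[1]
        minus_d = np.full(8, 1.0 / 8)
        dists = {
            ("d", "+"): FeatureDistribution("d", d_edges, plus_d / plus_d.sum()),
            ("d", "-"): FeatureDistribution("d", d_edges, minus_d),
        }
        model = HmmModel(
            feature_set=("d",),
            dists=dists,
            log_trans={(s, d): float(np.log2(0.5)) for s, ds in ALLOWED_EDGES.items() for d in ds},
            log_initial={HmmState.S_PLUS: -1.0, HmmState.S_MINUS: -1.0},
        )
        feats = [SiteFeatures(d=0, c=0.5, a=None), SiteFeatures(d=2, c=0.5, a=None),
                 SiteFeatures(d=2, c=0.5, a=None)]
        path = viterbi(model, feats)
        assert list(path.states) == [HmmState.S_PLUS, HmmState.PLUS, HmmState.PLUS]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            feature_set = [("d", "c", "a"), ("d", "c"), ("d",), ("c", "a")][rng.integers(4)]
            model = random_model(rng, feature_set=tuple(feature_set))
            feats = random_feats(rng, int(rng.integers(1, 9)))
            fast = viterbi(model, feats)
            slow = brute_force_decode(model, feats)
            assert fast.logprob == pytest.approx(slow.logprob, abs=1e-9)

    def test_decoded_paths_use_only_allowed_edges(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            model = random_model(rng)
            feats = random_feats(rng, int(rng.integers(2, 12)))
            path = viterbi(model, feats)
            assert path.states[0] in (HmmState.S_PLUS, HmmState.S_MINUS)
            for a, b in zip(path.states, path.states[1:]):
                assert b in ALLOWED_EDGES[a]

    def test_brute_force_refuses_long_sequences(self):
        rng = np.random.default_rng(4)
        model = random_model(rng)
        with pytest.raises(ValueError, match="8"):
            brute_force_decode(model, random_feats(rng, 9))

    def test_single_site_argmax_over_initial_states(self):
        rng = np.random.default_rng(5)
        model = random_model(rng)
        feats = random_feats(rng, 1)
        path = brute_force_decode(model, feats)
        assert len(path.states) == 1
        assert path.states[0] in (HmmState.S_PLUS, HmmState.S_MINUS)


class TestClusterCalls:
    def _path(self, *names):
        return StatePath(
            states=tuple(HmmState(n) for n in names), logprob=0.0
        )

    def test_run_extraction(self):
        model = symmetric_model()
        feats = random_feats(np.random.default_rng(6), 7, with_missing_a=False)
        sites = _sites_for(feats)
        path = self._path("S-", "-", "I+", "+", "+", "I-", "-")
        calls = call_clusters(model, path, sites, feats, min_sites=3)
        assert len(calls) == 1
        assert calls[0].n_sites == 3
        assert calls[0].member_starts == (40, 60, 80)

    def test_min_sites_filter_drops_small_candidates(self):
        model = symmetric_model()
        feats = random_feats(np.random.default_rng(7), 5, with_missing_a=False)
        sites = _sites_for(feats)
        path = self._path("S-", "-", "I+", "+", "I-")
        assert call_clusters(model, path, sites, feats, min_sites=3) == []
        assert len(call_clusters(model, path, sites, feats, min_sites=2)) == 1

    def test_clusters_separated_by_background_never_merged(self):
        model = symmetric_model()
        feats = random_feats(np.random.default_rng(8), 8, with_missing_a=False)
        sites = _sites_for(feats)
        path = self._path("S+", "+", "+", "I-", "I+", "+", "+", "I-")
        calls = call_clusters(model, path, sites, feats, min_sites=3)
        assert len(calls) == 2


class TestScoreCluster:
    def test_symmetric_model_scores_zero(self):
        model = symmetric_model()
        feats = random_feats(np.random.default_rng(9), 6, with_missing_a=False)
        for members in ([0, 1, 2], [2, 3, 4], [1, 2, 3, 4, 5]):
            assert score_cluster(model, feats, members) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_of_positive_contributions(self):
        rng = np.random.default_rng(10)
        model = random_model(rng)
        feats = random_feats(rng, 8, with_missing_a=False)
        trans_inc = model.log_trans[(HmmState.PLUS, HmmState.PLUS)] - model.log_trans[
            (HmmState.MINUS, HmmState.MINUS)
        ]
        for k in range(3, 7):
            s_k = score_cluster(model, feats, list(range(1, k + 1)))
            s_k1 = score_cluster(model, feats, list(range(1, k + 2)))
            f = feats[k + 1]
            per_site = emission_logprob(model, HmmState.PLUS, f) - emission_logprob(
                model, HmmState.MINUS, f
            )
            assert s_k1 == pytest.approx(s_k + per_site + trans_inc, abs=1e-9)

    def test_initiating_site_spacing_term_cancels(self):
        rng = np.random.default_rng(11)
        m1 = random_model(rng, feature_set=("d",))
        feats = random_feats(rng, 5, with_missing_a=False)
        # replace the '+' spacing distribution: only non-initiating members
        # consume it, so a single-member internal cluster is unaffected
        m2 = HmmModel(
            feature_set=("d",),
            dists={("d", "+"): random_distribution(rng, "d"), ("d", "-"): m1.dists[("d", "-")]},
            log_trans=m1.log_trans,
            log_initial=m1.log_initial,
        )
        s1 = score_cluster(m1, feats, [2])
        s2 = score_cluster(m2, feats, [2])
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_score_invariant_to_nonmember_features(self):
        rng = np.random.default_rng(12)
        model = random_model(rng)
        feats = random_feats(rng, 7, with_missing_a=False)
        members = [2, 3, 4]
        base = score_cluster(model, feats, members)
        perturbed = list(feats)
        perturbed[0] = SiteFeatures(d=0, c=0.99, a=0.01, region=RegionType.CDS)
        perturbed[6] = SiteFeatures(d=7, c=0.01, a=0.99, region=RegionType.FIVE_UTR)
        assert score_cluster(model, perturbed, members) == base

    def test_noncontiguous_members_rejected(self):
        model = symmetric_model()
        feats = random_feats(np.random.default_rng(13), 5, with_missing_a=False)
        with pytest.raises(ValueError, match="contiguous"):
            score_cluster(model, feats, [1, 3])


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(14)
    model = random_model(rng)
    p = tmp_path / "model.json"
    model.to_json(p)
    back = HmmModel.from_json(p)
    feats = random_feats(rng, 6)
    for f in feats:
        for s in HmmState:
            assert emission_logprob(back, s, f) == pytest.approx(
                emission_logprob(model, s, f), abs=1e-12
            )
    assert viterbi(back, feats).logprob == pytest.approx(
        viterbi(model, feats).logprob, abs=1e-12
    )
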