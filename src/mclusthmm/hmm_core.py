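"""The six-state HMM over motif-site observation sequences.

States
------
Each motif site along a scan sequence (one gene plus flanks) is one
observation.  Three states describe sites inside an RBP-bound cluster and
three describe background sites:

========  =====================================================  ========  =================
state     description                                            Pr(d|s)   Pr(c|s), Pr(a|s)
========  =====================================================  ========  =================
``S+``    site initiating an input sequence, in a bound cluster  Pr(0)=1   '+'
``S-``    site initiating an input sequence, background          Pr(0)=1   '-'
``+``     succeeding site in a bound cluster                     '+'       '+'
``-``     succeeding site in background                          '-'       '-'
``I+``    site initiating an internal bound cluster              '-'       '+'
``I-``    site initiating an internal background region          '-'       '-'
========  =====================================================  ========  =================

('+'/'-' denote the emission components estimated from positive/negative
training sites.)  Note the internal-initiation states take the *background*
spacing component: the distance from the preceding site belongs to the
stretch being left, not the cluster being entered.  The allowed transitions
follow from the state definitions: a cluster can only be continued (``+``)
or left (``I-``), background continued (``-``) or left (``I+``); the
sequence-initial states are never transition targets.

Decoding is windowed per scan sequence (no cross-gene paths).  Ties are
broken toward background, so a completely uninformative model predicts
nothing.

Cluster calls are maximal runs of cluster states, scored by the
log-likelihood ratio log2[P(x | cluster) / P(x | background)]: per-site
emission log-ratios against the homologous background state plus, for every
within-cluster step, the transition log-ratio log2 P(+ -> +) - log2
P(- -> -).  The transition term makes longer tightly-spaced clusters score
higher even under flat emissions; it can be disabled per call.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Protocol, Sequence

from .features import SiteFeatures
from .io_formats import GenomicInterval, RegionType
from .motif_scan import MotifSite

__all__ = [
    "HmmState",
    "ALLOWED_EDGES",
    "TIE_ORDER",
    "CLUSTER_STATES",
    "HOMOLOG",
    "HmmModel",
    "StatePath",
    "ClusterCall",
    "emission_logprob",
    "viterbi",
    "brute_force_decode",
    "call_clusters",
    "score_cluster",
]

NEG_INF = float("-inf")


class HmmState(Enum):
    S_PLUS = "S+"
    S_MINUS = "S-"
    PLUS = "+"
    MINUS = "-"
    I_PLUS = "I+"
    I_MINUS = "I-"


# directed edges determined by the state definitions
ALLOWED_EDGES: dict[HmmState, tuple[HmmState, ...]] = {
    HmmState.S_PLUS: (HmmState.PLUS, HmmState.I_MINUS),
    HmmState.S_MINUS: (HmmState.MINUS, HmmState.I_PLUS),
    HmmState.PLUS: (HmmState.PLUS, HmmState.I_MINUS),
    HmmState.MINUS: (HmmState.MINUS, HmmState.I_PLUS),
    HmmState.I_PLUS: (HmmState.PLUS, HmmState.I_MINUS),
    HmmState.I_MINUS: (HmmState.MINUS, HmmState.I_PLUS),
}

INITIAL_STATES = (HmmState.S_PLUS, HmmState.S_MINUS)

# fixed tie-break order: background preferred
TIE_ORDER = (
    HmmState.S_MINUS,
    HmmState.MINUS,
    HmmState.I_MINUS,
    HmmState.S_PLUS,
    HmmState.PLUS,
    HmmState.I_PLUS,
)

CLUSTER_STATES = frozenset({HmmState.S_PLUS, HmmState.PLUS, HmmState.I_PLUS})

# cluster state <-> homologous background state
HOMOLOG = {
    HmmState.S_PLUS: HmmState.S_MINUS,
    HmmState.PLUS: HmmState.MINUS,
    HmmState.I_PLUS: HmmState.I_MINUS,
    HmmState.S_MINUS: HmmState.S_PLUS,
    HmmState.MINUS: HmmState.PLUS,
    HmmState.I_MINUS: HmmState.I_PLUS,
}

# emission component ('+'/'-'/None=degenerate Pr(0)=1) per state and feature
D_COMPONENT: dict[HmmState, str | None] = {
    HmmState.S_PLUS: None,
    HmmState.S_MINUS: None,
    HmmState.PLUS: "+",
    HmmState.MINUS: "-",
    HmmState.I_PLUS: "-",
    HmmState.I_MINUS: "-",
}

CA_COMPONENT: dict[HmmState, str] = {
    HmmState.S_PLUS: "+",
    HmmState.PLUS: "+",
    HmmState.I_PLUS: "+",
    HmmState.S_MINUS: "-",
    HmmState.MINUS: "-",
    HmmState.I_MINUS: "-",
}


class EmissionComponent(Protocol):
    """Anything exposing a base-2 log pmf over one feature's value range."""

    def logpmf(self, value: float) -> float: ...


@dataclass
class HmmModel:
    """A trained six-state model.

    ``dists`` maps component keys to emission distributions:
    ``('d', '+')``, ``('d', '-')``, ``('a', '+')``, ``('a', '-')`` and
    ``('c', sign, region)`` for every :class:`RegionType` (conservation is
    region-stratified on both sides).  ``log_trans``/``log_initial`` hold
    base-2 log probabilities over the allowed edges and initial states.
    """

    feature_set: tuple[str, ...]
    dists: dict[tuple, EmissionComponent]
    log_trans: dict[tuple[HmmState, HmmState], float]
    log_initial: dict[HmmState, float]
    log_base: float = 2.0
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.feature_set) <= {"d", "c", "a"}:
            raise ValueError(f"invalid feature set {self.feature_set}")
        for src, dst in self.log_trans:
            if dst not in ALLOWED_EDGES[src]:
                raise ValueError(f"transition {src.value} -> {dst.value} is not allowed")
        for state in self.log_initial:
            if state not in INITIAL_STATES:
                raise ValueError(f"initial state {state.value} must be S+ or S-")

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        from .training import FeatureDistribution  # deferred: one-way import

        def dist_payload(dist) -> dict:
            return {
                "feature": dist.feature,
                "bin_edges": list(map(float, dist.bin_edges)),
                "masses": list(map(float, dist.masses)),
                "stratum": dist.stratum.value if dist.stratum else None,
            }

        payload = {
            "feature_set": list(self.feature_set),
            "log_base": self.log_base,
            "distributions": [
                {"key": [k if isinstance(k, str) else k.value for k in key],
                 **dist_payload(dist)}
                for key, dist in self.dists.items()
            ],
            "log_transitions": [
                [a.value, b.value, lp] for (a, b), lp in self.log_trans.items()
            ],
            "log_initial": {s.value: lp for s, lp in self.log_initial.items()},
            "config": self.config,
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmModel":
        import numpy as np

        from .training import FeatureDistribution

        with open(path) as fh:
            payload = json.load(fh)
        dists = {}
        for entry in payload["distributions"]:
            key = list(entry["key"])
            if len(key) == 3:
                key[2] = RegionType(key[2])
            dist = FeatureDistribution(
                feature=entry["feature"],
                bin_edges=np.asarray(entry["bin_edges"]),
                masses=np.asarray(entry["masses"]),
                stratum=RegionType(entry["stratum"]) if entry["stratum"] else None,
            )
            dists[tuple(key)] = dist
        return cls(
            feature_set=tuple(payload["feature_set"]),
            dists=dists,
            log_trans={
                (HmmState(a), HmmState(b)): lp
                for a, b, lp in payload["log_transitions"]
            },
            log_initial={
                HmmState(s): lp for s, lp in payload["log_initial"].items()
            },
            log_base=payload["log_base"],
            config=payload.get("config", {}),
        )


@dataclass(frozen=True)
class StatePath:
    """A decoded state path with its joint base-2 log probability."""

    states: tuple[HmmState, ...]
    logprob: float

    def __post_init__(self) -> None:
        if self.states:
            if self.states[0] not in INITIAL_STATES:
                raise ValueError("path must start in S+ or S-")
            for a, b in zip(self.states, self.states[1:]):
                if b not in ALLOWED_EDGES[a]:
                    raise ValueError(f"disallowed transition {a.value} -> {b.value}")


@dataclass(frozen=True)
class ClusterCall:
    """A predicted cluster: span of its member sites plus the LLR score."""

    interval: GenomicInterval
    n_sites: int
    score: float
    member_starts: tuple[int, ...] = ()
    member_ordinals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("cluster must contain at least one site")


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def emission_logprob(model: HmmModel, state: HmmState, feats: SiteFeatures) -> float:
    """Base-2 log emission probability of one site's features under ``state``.

    The sequence-initial states carry the degenerate spacing distribution
    Pr(0) = 1: they emit the sentinel d = 0 with log probability 0 and any
    real distance with probability 0; conversely the non-initial states
    cannot emit the sentinel.  A missing accessibility value drops the
    a-term symmetrically in every state.
    """
    total = 0.0
    if "d" in model.feature_set:
        comp = D_COMPONENT[state]
        if comp is None:
            if feats.d != 0:
                return NEG_INF
        else:
            if feats.d == 0:
                return NEG_INF
            total += model.dists[("d", comp)].logpmf(feats.d)
    if "c" in model.feature_set:
        comp = CA_COMPONENT[state]
        total += model.dists[("c", comp, feats.region)].logpmf(feats.c)
    if "a" in model.feature_set and feats.a is not None:
        comp = CA_COMPONENT[state]
        total += model.dists[("a", comp)].logpmf(feats.a)
    return total


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def viterbi(model: HmmModel, feats_seq: Sequence[SiteFeatures]) -> StatePath:
    """Maximum joint log-probability state path over the allowed edges.

    Ties are broken by the fixed order S- < - < I- < S+ < + < I+ (background
    preferred): among equally likely alternatives the earlier state in that
    order wins, at every position.
    """
    n = len(feats_seq)
    if n == 0:
        raise ValueError("cannot decode an empty site sequence")
    score: dict[HmmState, float] = {s: NEG_INF for s in TIE_ORDER}
    back: list[dict[HmmState, HmmState]] = []
    for s in INITIAL_STATES:
        score[s] = model.log_initial.get(s, NEG_INF) + emission_logprob(
            model, s, feats_seq[0]
        )
    for t in range(1, n):
        new_score = {s: NEG_INF for s in TIE_ORDER}
        pointers: dict[HmmState, HmmState] = {}
        for dst in TIE_ORDER:
            if dst in INITIAL_STATES:
                continue
            best = NEG_INF
            best_src = None
            for src in TIE_ORDER:  # tie-break: first (most background) wins
                if dst not in ALLOWED_EDGES[src]:
                    continue
                lp = score[src] + model.log_trans.get((src, dst), NEG_INF)
                if lp > best:
                    best = lp
                    best_src = src
            if best_src is not None and best > NEG_INF:
                e = emission_logprob(model, dst, feats_seq[t])
                new_score[dst] = best + e
                pointers[dst] = best_src
        score = new_score
        back.append(pointers)
    # final state: first in tie order among the maxima
    final = TIE_ORDER[0]
    for s in TIE_ORDER[1:]:
        if score[s] > score[final]:
            final = s
    if score[final] == NEG_INF:
        raise ValueError("no legal path has positive probability")
    states = [final]
    for pointers in reversed(back):
        states.append(pointers[states[-1]])
    states.reverse()
    return StatePath(states=tuple(states), logprob=score[final])


def brute_force_decode(model: HmmModel, feats_seq: Sequence[SiteFeatures]) -> StatePath:
    """Exact maximization by enumerating every legal path (test oracle).

    Refuses sequences longer than 8 sites.  Under ties this returns the same
    joint log probability as :func:`viterbi` (not necessarily the same path).
    """
    n = len(feats_seq)
    if n == 0:
        raise ValueError("cannot decode an empty site sequence")
    if n > 8:
        raise ValueError("brute-force decoding is limited to 8 sites")
    emit = [
        {s: emission_logprob(model, s, f) for s in TIE_ORDER} for f in feats_seq
    ]
    best_path: list[HmmState] | None = None
    best_lp = NEG_INF

    def recurse(path: list[HmmState], lp: float) -> None:
        nonlocal best_path, best_lp
        if lp == NEG_INF:
            return
        if len(path) == n:
            if lp > best_lp:
                best_lp = lp
                best_path = list(path)
            return
        candidates = (
            INITIAL_STATES
            if not path
            else ALLOWED_EDGES[path[-1]]
        )
        for s in TIE_ORDER:
            if s not in candidates:
                continue
            if not path:
                step = model.log_initial.get(s, NEG_INF)
            else:
                step = model.log_trans.get((path[-1], s), NEG_INF)
            path.append(s)
            recurse(path, lp + step + emit[len(path) - 1][s])
            path.pop()

    recurse([], 0.0)
    if best_path is None:
        raise ValueError("no legal path has positive probability")
    return StatePath(states=tuple(best_path), logprob=best_lp)


# ---------------------------------------------------------------------------
# cluster extraction and scoring
# ---------------------------------------------------------------------------

def score_cluster(
    model: HmmModel,
    feats_seq: Sequence[SiteFeatures],
    members: Sequence[int],
    path: StatePath | None = None,
    include_transitions: bool = True,
) -> float:
    """Log-likelihood-ratio score log2[P(x|cluster) / P(x|background)].

    ``members`` are contiguous indices into the scan sequence.  Each member
    contributes its emission log-ratio between the assigned cluster state
    and the homologous background state (S+/S-, +/-, I+/I-); each
    within-cluster step adds log2 P(+ -> +) - log2 P(- -> -).  The initiating
    site's d-term cancels exactly (I+ and I- share the '-' spacing component;
    S+ and S- are both degenerate), so the score only depends on the members'
    features.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    if any(b != a + 1 for a, b in zip(members, members[1:])):
        raise ValueError("cluster members must be contiguous")
    if path is not None:
        states = [path.states[i] for i in members]
        if any(s not in CLUSTER_STATES for s in states):
            raise ValueError("member not in a cluster state")
    else:
        first = HmmState.S_PLUS if members[0] == 0 else HmmState.I_PLUS
        states = [first] + [HmmState.PLUS] * (len(members) - 1)
    score = 0.0
    for idx, state in zip(members, states):
        f = feats_seq[idx]
        score += emission_logprob(model, state, f) - emission_logprob(
            model, HOMOLOG[state], f
        )
    if include_transitions and len(members) > 1:
        ratio = model.log_trans[(HmmState.PLUS, HmmState.PLUS)] - model.log_trans[
            (HmmState.MINUS, HmmState.MINUS)
        ]
        score += ratio * (len(members) - 1)
    return score


def call_clusters(
    model: HmmModel,
    path: StatePath,
    sites: Sequence[MotifSite],
    feats_seq: Sequence[SiteFeatures],
    min_sites: int = 3,
    min_score: float | None = None,
    include_transitions: bool = True,
) -> list[ClusterCall]:
    """Extract and score maximal runs of cluster states from a decoded path.

    Candidate clusters are maximal runs matching ``(S+|I+)(+)*``; runs with
    fewer than ``min_sites`` sites (default 3, the canonical minimum for
    functional binding) or scoring below ``min_score`` are dropped.
    """
    if len(path.states) != len(sites) or len(sites) != len(feats_seq):
        raise ValueError("path, sites and features must have equal length")
    calls = []
    i = 0
    n = len(sites)
    while i < n:
        if path.states[i] in CLUSTER_STATES:
            j = i
            while j + 1 < n and path.states[j + 1] is HmmState.PLUS:
                j += 1
            members = list(range(i, j + 1))
            if len(members) >= min_sites:
                score = score_cluster(
                    model, feats_seq, members, path=path,
                    include_transitions=include_transitions,
                )
                if min_score is None or score >= min_score:
                    first, last = sites[i], sites[j]
                    calls.append(
                        ClusterCall(
                            interval=GenomicInterval(
                                first.seq_id, first.start, last.end
                            ),
                            n_sites=len(members),
                            score=score,
                            member_starts=tuple(sites[k].start for k in members),
                            member_ordinals=tuple(sites[k].ordinal for k in members),
                        )
                    )
            i = j + 1
        else:
            i += 1
    calls.sort(key=lambda c: (c.interval.seq_id, c.interval.start))
    return calls
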