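"""Shared fixtures: a toy phylogeny, random-model builders and a small
simulated dataset reused (read-only) across test modules."""
from __future__ import annotations

import io

import numpy as np
import pytest
from Bio import Phylo

from mclusthmm.features import SiteFeatures
from mclusthmm.hmm_core import ALLOWED_EDGES, INITIAL_STATES, HmmModel, HmmState
from mclusthmm.io_formats import PhyloTree, RegionType
from mclusthmm.pipeline import Dataset, featurize_dataset, scan_dataset, train_model
from mclusthmm.simulate import SimSpec, simulate_dataset
from mclusthmm.training import FeatureDistribution

TOY_NEWICK = "((A:0.1,B:0.2):0.1,C:0.4);"


@pytest.fixture(scope="session")
def toy_tree() -> PhyloTree:
    return PhyloTree.from_biopython(Phylo.read(io.StringIO(TOY_NEWICK), "newick"))


def tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree.from_biopython(Phylo.read(io.StringIO(newick), "newick"))


def random_distribution(
    rng: np.random.Generator, feature: str, d_cens: int = 8, bins: int = 5,
    stratum: RegionType | None = None,
) -> FeatureDistribution:
    if feature == "d":
        edges = np.arange(1, d_cens + 2, dtype=float)
        n = d_cens
    else:
        edges = np.linspace(0.0, 1.0, bins + 1)
        n = bins
    masses = rng.dirichlet(np.full(n, 0.8)) + 1e-4
    masses /= masses.sum()
    return FeatureDistribution(feature=feature, bin_edges=edges, masses=masses, stratum=stratum)


def random_model(
    rng: np.random.Generator,
    feature_set: tuple[str, ...] = ("d", "c", "a"),
    d_cens: int = 8,
    bins: int = 5,
) -> HmmModel:
    """A random but structurally valid six-state model."""
    dists = {}
    if "d" in feature_set:
        for sign in "+-":
            dists[("d", sign)] = random_distribution(rng, "d", d_cens=d_cens)
    if "c" in feature_set:
        for sign in "+-":
            for region in RegionType:
                dists[("c", sign, region)] = random_distribution(
                    rng, "c", bins=bins, stratum=region
                )
    if "a" in feature_set:
        for sign in "+-":
            dists[("a", sign)] = random_distribution(rng, "a", bins=bins)
    log_trans = {}
    for src, dsts in ALLOWED_EDGES.items():
        probs = rng.dirichlet(np.ones(len(dsts)))
        for dst, p in zip(dsts, probs):
            log_trans[(src, dst)] = float(np.log2(p + 1e-12))
    p0 = rng.dirichlet(np.ones(2))
    log_initial = {
        s: float(np.log2(p + 1e-12)) for s, p in zip(INITIAL_STATES, p0)
    }
    return HmmModel(
        feature_set=feature_set,
        dists=dists,
        log_trans=log_trans,
        log_initial=log_initial,
    )


def random_feats(
    rng: np.random.Generator, n: int, d_cens: int = 8, with_missing_a: bool = True
) -> list[SiteFeatures]:
    """A random observation sequence (first site carries the d = 0 sentinel)."""
    feats = []
    regions = list(RegionType)
    for i in range(n):
        d = 0 if i == 0 else int(rng.integers(1, d_cens + 1))
        a = None
        if not with_missing_a or rng.random() > 0.2:
            a = float(rng.random())
        feats.append(
            SiteFeatures(
                d=d,
                c=float(rng.random()),
                a=a,
                region=regions[rng.integers(len(regions))],
            )
        )
    return feats


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset with its scan, features and trained model."""
    spec = SimSpec(seed=20240915, n_genes=20, cluster_rate=2.0)
    data = simulate_dataset(spec)
    ds = Dataset.from_sim(data)
    sites = scan_dataset(ds)
    feats = featurize_dataset(ds, sites)
    model = train_model(ds, sites, feats)
    return {
        "data": data,
        "ds": ds,
        "sites": sites,
        "feats": feats,
        "model": model,
    }
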