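# Methods

## Model

`mclusthmm` treats the ordered motif sites of one scan sequence (a gene
body plus flanking sequence) as an observation sequence for a six-state
hidden Markov model.  The states factor binding status (bound cluster vs
background) against position in a run (sequence-initial, run-continuing,
run-opening), which is what lets transition probabilities express the
*clustering* of sites while emissions express their individual quality.
Two conventions are load-bearing:

* The sequence-initial states S± carry a degenerate spacing distribution
  Pr(0) = 1.  The first site of every scan sequence is assigned the
  sentinel distance d = 0; real inter-site distances are ≥ 1, so the
  sentinel can never be emitted by a non-initial state (and vice versa —
  both directions are enforced as hard zeros in the emission function).
* The run-opening states I± take the **background** spacing component: the
  gap that precedes a run's first site belongs to the stretch being left,
  not to the run being entered.  A corollary used by the scorer is that an
  initiating site's spacing term cancels exactly in the cluster/background
  log-likelihood ratio.

Spacing is the start-to-start distance (stable under overlapping sites,
which the scanner deliberately reports in full), censored at `d_cens` = 30
nt.  Censoring makes every distance ≥ 30 indistinguishable by construction;
the test suite asserts that stretching any such gap leaves decoded paths
and scores bit-identical.

Conservation is the branch length score (BLS): the branch length of the
minimal subtree spanning the species that retain a consensus word in the
aligned orthologous window, divided by the tree's total branch length.
"Retains" means an exact consensus match within the site span (slop = 0 by
default, configurable); this is the strictest, most reproducible reading —
motif movement within a window is not credited.  BLS distributions are
estimated per region stratum (5′UTR / CDS / 3′UTR / intron) on both the
positive and negative side, because basal conservation differs by an amount
that would otherwise swamp the binding signal.  Spacing and accessibility
are region-pooled.  Non-coding exons and flanking sequence fall into the
intron stratum — the least biased default for sequence with no UTR/CDS
identity.  Accessibility is the mean per-base single-strandedness over the
site; with a sparse track, the default policy drops the a-term for sites
with any missing base (symmetrically in all states) rather than imputing.

## Training

Training is fully supervised; there is no Baum–Welch step.  Positive
regions are CLIP tag clusters with peak height ≥ `ph_min` (default 15; 7 is
the appropriate choice for shallower libraries), fully inside the exon+ext
mask (exons plus the first/last `ext` = 1000 nt of each intron plus flanks)
and free of repeat overlap.  Negative regions are the exon+ext masks of
genes with **no** CLIP cluster anywhere in the gene ± ext — a single tag
anywhere disqualifies the gene, even outside the mask.  Sites inside
positive clusters are labeled '+'; sites in tagged genes outside clusters
are excluded from training entirely; sites in tag-free genes are '−'.
Spacing is recomputed within each training region, so each region's first
site carries the sentinel.

Emissions are smoothed histograms: unit bins 1..30 for spacing (the last
bin absorbs censored distances) and 20 equal-width bins on [0, 1] for
conservation and accessibility, with additive pseudocount 1 —
`mass = (count + 1) / (N + B)`.  These bin counts and the pseudocount are
declared package defaults, exposed in `TrainingConfig`.  A stratum with no
sites on one side falls back to that side's pooled conservation histogram
with a logged warning.  Transition and initial probabilities are smoothed
maximum-likelihood counts over the state paths induced by the labels.

A consequence worth knowing: because training regions are wholly '+' or
wholly '−', the cluster entry/exit edges (− → I+, + → I−) are never
observed and carry pseudocount-only mass, so the cost of entering a cluster
during decoding grows with the size of the negative corpus (≈ log2 of the
background transition count).  This acts as a data-driven penalty against
spurious clusters; its practical effect is that a spacing-only model is
conservative, which is visible in the ablation experiment below.

## Decoding and scoring

Viterbi decoding runs per scan sequence; ties are broken toward background
in the fixed order S− < − < I− < S+ < + < I+, so a completely uninformative
model predicts nothing.  Maximal runs of cluster states with ≥ 3 sites (the
canonical minimum for functional binding) become cluster calls, scored in
log base 2 as the sum of per-site emission log-ratios against the
homologous background state plus, per within-cluster step, the ratio
log2 P(+→+) − log2 P(−→−).  Including the transition term (switchable via
`include_transitions`) makes longer, tighter clusters outscore equal-sized
emission evidence spread thin.  Scores are decoded-path quantities, not
forward sums over all cluster-consistent paths.  Printed score thresholds
are user choices, not portable constants — they depend on the log base and
on the training corpus.

Cassette-exon ranking uses six regional scores anchored at the splice
sites flanking the exon (upstream-intron 5′/3′, exon 3′/5′, downstream-
intron 5′/3′).  Eligible clusters lie on the anchor's own side (intron-side
anchors take intronic clusters, exonic anchors exon-internal ones) within a
1000-nt window, contributing `score · exp(−dist/τ)` with τ = 500 nt and
dist the distance from the anchor base to the nearest cluster edge.  The
exponential decay with a regional **max** (not sum) was chosen as the
smoothest monotone anchor-local summary consistent with using the maximum
of the six as the exon's summarized score; both the window and τ are
exposed.  The positional profile is a deliberately simple score-weighted
coverage around the four splice-site junctions, averaged over events; it is
not a normalized complexity map.

## Synthetic data

The generator emulates exactly the statistical structure the model
exploits.  Per gene (default 3–6 kb, three coding exons with introns short
enough that the exon+ext mask covers the whole body): bound clusters
(Poisson count per gene; ≥ 3 sites each) with within-cluster spacing
4 + Geometric (mean 8 nt), background sites at 4 + Geometric (mean 80 nt);
per-species motif retention i.i.d. given the label (0.9 bound / 0.3
background) on a fixed seven-species mammal-like tree; accessibility drawn
per site from Beta(8, 2) vs Beta(2, 2) over a 0.5 background; CLIP peaks at
planted-cluster midpoints with Poisson peak heights.  The reference
sequence is built so that the planted sites are the *only* consensus
matches (accidental matches are mutated away), which makes spacing laws
exact and lets tests assert scanned == planted.  An optional per-cluster
strength u ∈ [0, 1] interpolates retention and accessibility between the
background and bound laws and scales peak height — emulating affinity
heterogeneity, where peak height is a composite of affinity and abundance.
Everything derives from a single seeded generator; equal seeds give
byte-identical files.

What the generator does **not** emulate: phylogenetically correlated motif
loss, alignment indels, read-level CLIP noise, overlapping genes,
minus-strand genes (strand handling is exercised in unit tests), and any
realistic sequence composition beyond uniform background.  Recovery results
on this data therefore demonstrate correctness of estimation and decoding
under the model's own assumptions — not robustness to real-genome
confounders such as repeat-driven motif density or alignment error.

## Validation experiments and problem sizes

All experiments live in `mclusthmm.protocols`, are driven by one seed, and
are sized to finish in seconds on one core while leaving statistical
margin:

* **Decoding exactness** — 1000 random models × observation sequences of
  ≤ 8 sites: Viterbi log probability equals exhaustive path enumeration to
  1e−9.
* **Parameter recovery** — 50 000 sites/side drawn at the feature level
  (sequence construction adds nothing when the estimator is the unit under
  test): every emission histogram within total variation 0.05 of its exact
  generating law (in practice < 0.01); transition estimates within 0.02 of
  generating rates (label paths simulated from a known chain).
* **Planted-cluster recovery** — three independent 60-gene replicates:
  train on one, pick the F1-maximizing threshold on the second, report on
  the third.  Typical precision ≈ 0.98–1.0, recall ≈ 0.89–0.95.
* **Feature ablation** — 10 paired replicates under the default separation:
  the full model's footprint/background AUC never falls below the
  spacing-only model's (typically ≈ 0.99 vs ≈ 0.7), sign test p < 0.01.
* **Score–overlap trend** — 400 genes with heterogeneous cluster strength:
  the fraction of calls overlapping CLIP footprints rises across nine
  score-quantile bins (Spearman ρ ≈ 0.84–0.99).  Nine bins at ~45 calls
  each keep the rank test well powered against per-bin binomial noise.
* **Cross-validation consistency** — 250 genes, gene-level two-fold split:
  out-of-fold cluster scores vs full-model scores give R² ≈ 0.98 on
  coordinate-matched clusters.  At smaller corpus sizes R² degrades
  (≈ 0.94 at 120 genes) because half-corpus histograms and
  pseudocount-dominated transitions drift — the experiment is a convergence
  statement, so it is run where the folds have converged.

## Numerical choices and degenerate inputs

Log base 2 throughout; scores printed to two decimals.  Emission lookups on
empty histograms are impossible by construction (smoothing keeps every bin
positive); hard zeros occur only for the sentinel/real-distance mismatch
and are represented as −inf, never subtracted from each other.  Sequences
with a single site decode over {S+, S−} only.  BLS is 0 for unaligned
sites, single-species sets and zero-length trees.  Reciprocal-overlap
matching in recovery reports is greedy by descending score; with disjoint
planted clusters this equals the exhaustive optimal assignment (asserted in
tests).  An empty positive or negative training set raises rather than
producing a silently degenerate model.

## Known limitations

Viterbi-path scoring understates uncertainty relative to posterior
decoding (out of scope).  The entry/exit pseudocount barrier couples
sensitivity to training-corpus size; a principled alternative would model
cluster frequency explicitly.  Accessibility is consumed as a track, not
computed from sequence; a uniform-0.5 fallback keeps pipelines runnable but
carries no signal.  The splice-site distance weighting is a declared
default (exponential, τ = 500 nt), not a fitted quantity.
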