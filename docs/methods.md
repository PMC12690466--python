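# Methods

## Problem setting

Common essential genes — those whose knockout produces a growth defect in
most cell lines — are predicted from two data modalities: the topology of a
protein–protein interaction (PPI) network and gene-expression profiles.
Prediction is node classification on the PPI graph, with the deliberate
constraint that the classifier must be *inductive*: it may only ever consume
a sampled local neighborhood of a node, so that genes absent from the
training graph (newly discovered interactions, new network versions, other
species' orthologs) can be scored without retraining.

## Label construction from knockout screens

Screens report a per-gene, per-cell-line viability effect (more negative =
stronger depletion).  The labeling pipeline follows the percentile-rank
logic used for large screen compendia:

1. **Percentile ranks.** Within each cell line, genes are ranked ascending by
   effect (most depleted = rank 1), ties averaged, normalized by the number
   of scored genes; values lie in (0, 1].  Missing entries (gene unscreened
   in a line) are excluded from that gene's vector, not imputed.
2. **Rank summary.** Each gene's ranks across lines are summarized by their
   0.90-quantile (linear interpolation).  A small summary means the gene sits
   among the most depleted in at least 90% of its lines.  The coverage is a
   parameter because "most lines" admits other operationalizations (e.g. the
   fraction of lines below a fixed rank); the quantile reading makes the
   summary continuous and threshold-free until the final call.
3. **KDE valley threshold.** When common essential genes exist, the summary
   distribution is bimodal.  A Gaussian KDE (Scott's-rule bandwidth,
   overridable) is evaluated on a 512-point grid over [0, 1]; local maxima
   with prominence ≥ 5% of the peak density count as modes — the prominence
   floor rejects sampling-noise shoulders that would otherwise make unimodal
   data look bimodal — and the density minimum strictly between the two
   highest modes is the threshold.  Ties across grid points return the
   midpoint of the tied run; fewer than two modes raises "no valley found"
   rather than guessing.  On real screen compendia this threshold lands
   around 0.3.
4. **Intersection and exclusion.** Calls are made per screening technology
   (CRISPR, RNAi) and intersected, which trades recall for precision against
   technology-specific artifacts.  Conditionally essential genes (essential
   in only some lines) are neither positives nor negatives: they become
   *unlabeled*, participate in message passing as neighbors, and contribute
   no loss terms.  Essential takes precedence when a gene appears in both
   lists.

## Node features

Expression (FPKM-like, genes × samples) is mapped to fixed-length node
vectors: log2(x+1) → PCA → per-component min–max scaling, in that order.
Genes are the observations and samples the variables, so any gene with an
expression row can be projected.  Choices worth stating:

- log2(x+1) is the standard variance-stabilizing transform for FPKM before
  PCA; `none` and per-gene z-score are available as switches.
- The PCA may be fitted on a *subset* of genes (the training set) and applied
  to all — this is what makes the unseen-gene scenarios meaningful.  Min–max
  bounds come from the fit set, so fitted genes span [0, 1] per component
  while unseen genes may land outside; they are deliberately not clamped,
  preserving linearity of the projection.
- Component signs are fixed by making each loading vector's
  largest-magnitude entry positive, so features are identical across BLAS
  implementations and platforms.
- The default dimensionality is 50 components (supported scan range 10–300).

## The classifier

Layer k computes, for node v with sampled neighbor set S(v):

    h_N(v)^k = mean{ h_u^(k-1) : u ∈ S(v) }          (zero vector if S empty)
    h_v^k    = ReLU( W^k · concat(h_v^(k-1), h_N(v)^k) )

with depth K = 3 and per-hop sample sizes (30, 25, 10) — hop 1 (a target's
direct neighbors) gets 30.  The reverse ordering (10 innermost) is the other
defensible reading of a three-number budget; sizes are config-exposed so
either is reproducible.  Sampling is uniform without replacement, take-all
when degree < size.  A final learnable linear map sends h^K to one logit.

Training: class-weighted binary cross-entropy (4 for essential, 1 for
nonessential), computed in logit space (softplus form) for stability; Adam
at learning rate 0.01; at most 200 epochs; minibatches of 512 targets with
neighborhoods resampled every epoch; early stopping when validation loss
fails to improve by more than `min_delta` = 1e-4 for `patience` = 10 epochs,
returning the best-validation-loss parameters.  The min-delta exists because
with a pure "any improvement" rule, runs chase 1e-6-scale improvements for
dozens of epochs with no measurable effect on test metrics.

The network is implemented directly in numpy: vectorized per-hop sampling
(random-key sort within CSR adjacency rows), sparse-matrix neighbor
averaging, analytic backprop, and a hand-rolled Adam.  Gradients are
verified against central finite differences in the test suite.  Hidden
widths default to (64, 64, 64); on the synthetic reference problem widths of
128 change no metric, only cost, and width is config-exposed.

At prediction time one seeded neighborhood sample is drawn (no retraining);
repeated prediction with different seeds quantifies sampling variance.  The
prediction graph may be a strict supergraph of the training graph — the
inductive contract.

## Evaluation protocol

- **4:1 pool.** All essential genes plus round(4·n) uniformly sampled
  nonessential genes, enforced across training, validation, and test.  This
  fixes the random-classifier AUPRC baseline at 0.2 — every AUPRC in this
  package should be read against 0.2, not against the raw prevalence.
- **Splits.** Stratified 5-fold test partition; within each fold, 10% of the
  remainder (stratified) is validation.
- **Metrics.** AUPRC uses the step-interpolation PR area (linear PR
  interpolation overestimates); AUROC is the midrank Mann–Whitney statistic.
  Both are checked against exhaustive all-threshold brute-force
  implementations in the tests.  Fold-mean aggregation is the default;
  pooled concatenated-prediction scores are available
  (`EvalResult.pooled_scores`).  Stratified folds are used throughout;
  unstratified folds risk one-class test sets at these pool sizes.
- **Youden cutoff.** The decision threshold maximizes J = TPR − FPR over the
  distinct score values ("score ≥ threshold" calls positive); the smallest
  maximizer is returned on ties.
- **Unseen-gene scenarios.** Four exposure regimes: `mask-labels-only`
  (standard CV), `drop-test-from-graph` (test nodes deleted from the
  training graph), `pca-train-only` (full graph, feature transform fitted
  without test genes), `drop-test-completely` (both; test nodes re-enter
  only at scoring).  The expected ordering is mask ≥ drop-graph ≥ pca-only ≈
  drop-completely: removing the test genes' expression rows from the PCA fit
  costs more than removing their edges.

## Perturbation experiments

To attribute performance to topology vs features: a fraction of edges is
replaced by uniformly random novel edges (both endpoints redrawn; a
rewire-one-endpoint variant is provided), and a fraction of nodes has
feature vectors swapped pairwise.  Replacement rejects self-loops,
duplicates, and original edges, so node/edge counts are conserved and the
number of changed edges is exact; feature swapping conserves the row
multiset.  Edge counts round half-away-from-zero; the feature-node count
rounds down to even so all selected nodes pair.  A fresh perturbation is
drawn per repeat, before cross-validation.  Full combined perturbation
should collapse AUPRC to the 0.2 baseline; partial perturbation should
degrade monotonically.

## Synthetic data: what it emulates and what it does not

Generators provide the statistical structure the method assumes, with gene
symbols ("G000001"…) exercising the same string-keyed paths as real inputs:

- **Graph:** preferential attachment with attachment count
  m = ⌊edges/nodes⌋, then degree-proportional extra edges to hit the
  requested edge count exactly.  This reproduces the heavy-tailed degree
  distribution of PPI networks, not their community structure or clustering.
- **Labels:** essential genes drawn with probability ∝ degree^hub_bias
  (default 1), reflecting the known enrichment of essential genes among
  hubs.
- **Expression:** latent log2 signal = class shift (default 1.5 sd for
  essential genes) + unit Gaussian noise per sample, then one
  neighbor-averaging pass with weight 0.3 couples features to topology
  (a single pass, not full diffusion, so the perturbation experiments can
  still separate the two signals), then 2^x gives FPKM-like positives.
- **Gene effects:** essential N(−1.0, 0.2²), nonessential N(0, 0.2²) per
  line, yielding the bimodal rank-summary distribution the labeler needs.

The reference experiment uses 2,000 nodes, 10,000 edges, 10% essential,
100 expression samples, 100 screen lines — sizes at which the repeated-CV
experiments run in minutes on one CPU while leaving every pipeline stage
non-trivial.  A scaling grid (10k–30k nodes × 200k–1.8M edges, 45 networks)
is available for size experiments.

**What passing tests show:** that the implementation recovers planted
structure, respects its contracts (inductive isolation, conservation laws,
determinism), and degrades to chance when the signal is destroyed.  **What
they do not show:** real-data performance.  Real expression has correlated
samples and batch structure, real PPI networks have assortativity and
community structure, and real essentiality signal is far weaker than a
1.5-sd planted shift — synthetic AUPRC near 1.0 is a property of the
generator, not a forecast.

## Numerical and degenerate-input choices

- All randomness flows from `numpy` `SeedSequence` spawning; seeded runs are
  bit-identical, including training histories and metrics JSON.
- Duplicate edges keep the maximum confidence; self-loops are dropped (the
  node's own representation enters via the concatenation, not an adjacency
  self-edge).  Node order is lexicographic at graph construction.
- Confidence filtering is explicit about strict (>) vs inclusive (≥)
  comparison, defaulting to strict for CPDB-style 0.5 ("higher than") and
  inclusive for STRING-style 0.85.
- Scores on a 0–1000 scale (STRING detailed links) are rescaled by /1000
  when any score exceeds 1.
- Isolated nodes aggregate the zero vector; empty validation improvement
  histories stop at `max_epochs`; `max_epochs=0` returns initialized
  parameters with empty history.

## Known limitations

- The KDE valley's location depends on bandwidth; Scott's rule on strongly
  separated modes is stable, but weakly separated screens may need a manual
  bandwidth, and whether the density should be estimated on per-gene
  summaries or pooled ranks is a modeling choice (summaries here).
- Mean aggregation discards degree information by construction; tasks where
  absolute connectivity matters would need degree features.
- The negative pool is resampled per repeat, so repeat-to-repeat variance
  mixes sampling and training noise.
- Single-CPU numpy training is practical to tens of thousands of nodes;
  the implementation trades raw speed for exact reproducibility and
  dependency-free gradients.
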