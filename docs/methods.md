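# Methods

This note documents the models, parameter choices and numerical conventions
behind each module, and what the synthetic-data tests do and do not
demonstrate about real amplicon data.

## Synthetic data

**Factorial communities.** A sample grid of cultivar × treatment × replicate
× niche (default 2 × 5 × 3 × 4 = 120 samples, 300 taxa). Taxon abundances
follow a log-normal latent model: per-taxon base log-mean ~ N(0, 1.5),
plus a cultivar-specific biomarker effect (log-fold enrichment, default 2.0
on 5 taxa per cultivar), a module-level random effect shared by all taxa of
a latent module within a sample (σ = 0.8, 6 modules — this induces the
block-correlation structure co-occurrence networks detect), and independent
taxon noise (σ = 0.5). Reads are a multinomial draw at a Poisson per-sample
depth (mean 2,000, floored at 50) so rarefaction is non-trivial. Real per-sample
depths vary by platform and run; the default is a desk-scale choice and is
configurable.

**Niche filtering** is nested: each taxon receives one uniform score and is
present in niche *k* iff the score is below that niche's retention fraction
(default 1.0 → 0.25 linearly). Because retention is non-increasing, each
niche's taxon set is a subset of the previous one, which produces the
declining alpha-diversity gradient and the "gradually filtered" nesting that
source tracking expects. Planted biomarkers are force-retained in every
niche so cultivar contrasts are testable along the whole continuum.

**Phylogeny.** Random coalescent topology (exponential waiting times at
rate k(k−1)/2) with a log-normal rate jitter (σ = 0.25) on each branch, so
trees are binary, non-ultrametric and give non-degenerate cophenetic
distances.

**Known-process community pairs** for null-model calibration (150 taxa,
1,200 reads, log-normal pool σ = 1.2):

- *drift*: each community is a Dirichlet-multinomial draw around the shared
  pool (concentration 1,000). The Dirichlet layer is genuine demographic
  drift in composition; plain multinomial resampling of a fixed pool makes
  pairs far more similar than the Raup–Crick null's occupancy-draw
  construction and drives RC to −1 for every pair, at any sparsity. The
  chosen concentration puts the observed dissimilarity on the null's own
  scale (drift pairs: |RC| > 0.95 in ≤ 10%, typically 0–7%).
- *selection*: a Brownian trait is simulated along the tree; the two pair
  members draw from the pool reweighted by Gaussian trait filters at
  contrasting optima (±1.2 sd, width 0.35 sd). Communities are
  phylogenetically clustered and divergent; |βNTI| > 2 essentially always.
- *dispersal limitation*: the two members draw from disjoint random halves
  of the pool — no phylogenetic signal (βNTI ~ null) but overlap far below
  the null (RC → +1).
- *homogenizing dispersal*: the second member resamples the first's realized
  composition — overlap far above the null (RC → −1).

**Cd measurements.** Per plot (cultivar × treatment × replicate): grain Cd
= 0.5 mg/kg + Σ coefficients × standardized biomarker relative abundance in
the plot's rhizosphere sample + N(0, 0.05) noise, floored at 0.001 mg/kg;
soil total Cd is log-normal around 0.6 mg/kg, available Cd a uniform
0.3–0.6 fraction of it. With the default coefficient (0.15 per sd) the
planted link is recoverable by Spearman correlation at n = 30 plots.

## Diversity

Shannon uses the natural log (the base is unstated in common practice;
configurable by transforming the output). Chao1 uses the bias-corrected
form F₁(F₁−1)/(2(F₂+1)) so the absence of doubletons never divides by zero.
Rarefaction is a single multivariate-hypergeometric draw per sample
(without replacement), seed recorded; row sums are exactly the target
depth. NMDS is rank-based SMACOF (scikit-learn) with 20 seeded random
restarts at k = 2, reporting Kruskal stress-1; an all-equal distance matrix
is degenerate and returns origin coordinates with a warning. PERMANOVA is
single-factor with free permutation of labels; the pseudo-F uses the
standard partition of squared distances (total SS = Σd²/n), and the p-value
is (1 + #{F_perm ≥ F_obs})/(1 + n_perm). The pseudo-F agrees exactly with
scikit-bio's implementation, which the tests use as an independent
cross-check.

## Assembly null models

βMNTD is abundance-weighted by default (an unweighted switch exists): for
each taxon in one community, the minimum cophenetic distance to any taxon
of the other, weighted by relative abundance and averaged over both
directions. The βNTI null shuffles taxa across all tree tips in the
analyzed pool (not per-pair tips), keeping the null pool constant across
pairs; 999 randomizations by default. Pairs whose null has zero spread
(the two communities share every taxon, so every shuffle gives βMNTD ≈ 0)
have no defined z-score and are flagged — raised by default, skipped with a
warning in the group driver.

RC_bray fixes each community's observed richness and total abundance: the
null draws species with probability proportional to pool occupancy
(implemented as Gumbel top-k, equivalent to sequential weighted sampling
without replacement), gives each one individual, and fills the remainder
multinomially in proportion to pool relative abundance. Ties in the
empirical CDF count at half weight. RC = 2·[(#below + ½·#ties)/n_null] − 1.

The five-way partition's default (`as_printed`) rule set is:
βNTI > 2 → homogeneous selection, βNTI < −2 → variable selection, then
RC > 0.95 → dispersal limitation, RC < −0.95 → homogenizing dispersal,
else undominated. This orientation is reversed relative to the
Stegen-lineage convention (where βNTI > 2 is *variable* selection);
`orientation="stegen"` swaps the two selection labels; both conventions
circulate in the literature, so the choice is explicit rather than guessed. Pairing scope is within each
cultivar × niche group, with that group's samples as the Raup–Crick pool.

Calibration of the null (mean ≈ 0, sd ≈ 1 across pairs) is measured with
`bnti_self_null`, which randomizes each pair's taxon-to-tip assignment
before scoring — i.e. the data are generated by the tip-shuffle mechanism
itself. Scoring raw drift pairs against one shared tree assignment leaves
all pairs correlated through the single realized pool and cannot have unit
spread across pairs; this is a property of the statistic, not of the
implementation.

## Co-occurrence networks

Taxa are kept when detected in ≥ 75% of samples (inclusive) AND mean
relative abundance strictly > 0.01%. Edges are Spearman correlations
(t-approximation p-values with midrank ties) passing |ρ| > 0.7 and BH-FDR
q < 0.05, adjusted across all tested pairs of the network. Constant taxa
are excluded with a warning. Networks are built per cultivar × niche
subset.

Modules come from greedy modularity maximization (deterministic); the
partition is injectable so Zi–Pi is testable independently. Zi is the
within-module degree z-score against the node's own module; Pi = 1 −
Σ_t (k_it/k_i)². Roles: module hub (Zi > 2.5, Pi ≤ 0.62), network hub
(both high), connector (Pi > 0.62 only), else non-hub. Modules with uniform
within-module degree get Zi = 0 with a warning.

Natural connectivity is ln((1/N) Σ e^{λᵢ}) over the eigenvalues of the
unweighted, unsigned adjacency (negative-correlation edges count as edges;
robustness is treated as a structural property). It is computed with a
log-sum-exp so large graphs do not overflow. The removal curve sorts nodes
by betweenness once on the intact network (static ordering; a
recompute-each-step option exists), ties broken by node id, removing up to
80% of nodes; an optional per-N normalization (−ln N) is exposed but off by
default. Random references are Erdős–Rényi G(n, m) with the empirical node
and edge counts.

## Source tracking

Collapsed Gibbs over per-read source assignments. For a sink of N reads,
P(z = v) ∝ (n_v + α_v N) · (m_vt + n_vt + β)/(m_v + n_v + Tβ), where m are
the pooled source counts (zero for the Unknown source) and n the currently
assigned sink reads. Defaults α₁ = α₂ = 0.001, β = 0.01 — the classic
SourceTracker values. Large β (e.g. 10) lets the freely learned Unknown
profile bootstrap onto the sink and absorb nearly all reads (3-source
mixture MAE 0.30 vs 0.017 at β = 0.01), so it is not the default. Sinks are
rarefied to a common depth first (configurable); 100 burn-in sweeps, 100
recorded sweeps, 10 restarts averaged by default (the inner loop is
numba-compiled, so 1,000-draw chains remain cheap). Credible intervals are
2.5/97.5 percentiles of pooled draws.

One behavior worth knowing: when a sink is a strictly filtered subset of a
source (nested niches), the sink's own empirical profile always has higher
per-read likelihood than the superset source, so the Unknown source takes
the largest share regardless of priors — this is inherent to the mixture
model. The recovery property that is well-posed, and the one the tests
assert, is that the adjacent upstream niche dominates among the *known*
sources.

## Biomarker machine learning

Features are per-niche relative abundances; the label is the cultivar. The
70/30 split and all CV folds are stratified and seeded; all six models see
identical folds. Fixed hyperparameters (no search, none is warranted at
these sample sizes): ANN = one hidden layer of 16 units, max_iter 2000;
DT/RF with seeded randomness, RF 500 trees by default; KNN k = 5; logistic
regression max_iter 5000; SVM radial with scale gamma. Best model =
lowest mean CV error, ties resolved in the fixed order ANN, DT, RF, KNN,
LR, SVM.

MDA is held-out permutation importance: over 10 stratified 75/25 splits of
the training data, a forest fit on the sub-train part is scored on the
validation part before and after permuting each feature column; MDA is the
mean accuracy drop, ranked descending with taxon-id tie-break. (OOB-based
MDA would need scikit-learn's private bootstrap-index API; repeated
held-out splits measure the same quantity.) The CV error curve refits the
best model on the top-k features for each k (default grid 1..30 then every
5th to 100) and selects the smallest k attaining the minimal error; an
``n_repeats`` option averages repeated seeded CV splits, because on a flat
plateau a single split's noise (sd ≈ 0.045 at n = 80) would otherwise
decide the argmin. Two facts matter when interpreting minimal-biomarker
counts: compositional closure makes nominally uninformative taxa carry
class signal (the denominators shift), and a random forest's error barely
rises with extra noise features, so its curve plateaus rather than turning
up — the planted-dimensionality calibration therefore uses non-compositional
pure-noise features and a KNN curve, for which feature count genuinely
matters.
Biomarker–Cd correlations join samples to plots (cultivar × treatment ×
replicate), Z-score the per-plot relative abundances (sample sd) and report
Spearman ρ and p against grain Cd; Z-scoring does not change ρ (rank
invariance) and is kept for parity with the plotted convention.

## Pipeline

Stage seeds derive from one master seed as (seed × 1009 + offset) mod
2³¹−1 with a fixed per-stage offset, so toggling stages never shifts
another stage's stream. The manifest (JSON) records versions, seeds,
parameters and SHA-256 of every input and output; wall-clock timings go to
`run.log` so re-runs are byte-identical. Problem sizes in the test suite
and the acceptance script (e.g. 100 pairs × 999 randomizations for βNTI
calibration, 500–1,000 null datasets for PERMANOVA type-I, 12–20 repeats
for ML recovery, a 48-sample pipeline round-trip) are chosen as desk-scale
defaults that keep every estimate's Monte-Carlo error well inside the
asserted tolerance.

## What the synthetic fixtures do not show

The generators emulate compositional sparsity, overdispersion, niche
nesting, modular correlation and planted effects — not sequencing error,
chimeras, primer bias, contamination, or phylogenetic signal in abundances
(except where planted). Passing recovery tests therefore demonstrates that
the estimators are correct and calibrated under their own assumptions, not
that those assumptions hold for any particular real dataset. Known
limitations: βNTI on very dense communities (every taxon shared) is
undefined and such pairs are flagged rather than scored; the Unknown-source
behavior above; PERMANOVA is single-factor with free permutations (no
strata), matching the reported use but not replacing a mixed-design
analysis.
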