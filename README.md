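# rhizomics

Community-ecology inference for root-associated microbiomes, built around the
question of how two rice cultivars with contrasting cadmium accumulation
recruit and filter their bacterial communities along the soil–root continuum
(bulk soil → rhizosphere → rhizoplane → endosphere). The package implements
the full statistical chain such a study runs on an ASV count table, sample
metadata, a phylogeny and per-plot Cd measurements:

- **Diversity and ordination** — rarefaction, Shannon *H* = −Σ pᵢ ln pᵢ,
  bias-corrected Chao1 *S*₍obs₎ + F₁(F₁−1)/(2(F₂+1)), Bray–Curtis distances,
  non-metric MDS, and single-factor PERMANOVA (pseudo-*F*, *R*², permutation
  *P*).
- **Assembly null models** — between-community mean nearest taxon distance
  (βMNTD), its tip-shuffle z-score βNTI, the abundance-based Raup–Crick
  metric RC_bray, and the five-way partition of pairs into homogeneous
  selection (βNTI > 2), variable selection (βNTI < −2), dispersal limitation
  (|βNTI| < 2, RC > 0.95), homogenizing dispersal (|βNTI| < 2, RC < −0.95)
  and undominated.
- **Co-occurrence networks** — prevalence/abundance filtering, Spearman
  correlations with BH-FDR edge selection (|ρ| > 0.7, q < 0.05), topology vs
  Erdős–Rényi G(n, m) ensembles, robustness as natural connectivity
  ln((1/N) Σ e^{λᵢ}) under betweenness-ordered node removal, and Zi–Pi
  module-hub detection (Zi > 2.5, Pi ≤ 0.62).
- **Source tracking** — a collapsed-Gibbs Bayesian mixture model estimating
  what fraction of each sink community derives from each source environment
  (plus an explicit Unknown source).
- **Biomarker selection** — six classifiers (ANN, decision tree, random
  forest, KNN, logistic regression, radial SVM) compared by stratified
  five-fold CV on a 70/30 split, mean-decrease-accuracy feature ranking, a
  CV error curve choosing the minimal biomarker set, a held-out confusion
  matrix, Z-scored biomarker–grain-Cd Spearman correlations, and the
  bioaccumulation factor (grain Cd / bulk-soil total Cd).
- **Synthetic data** — seeded generators for the 2-cultivar × 5-treatment ×
  3-replicate × 4-niche design with declining richness along the continuum,
  planted cultivar biomarkers, modular correlation structure, known-process
  community pairs, nested niche profiles, and Cd tables linearly linked to
  planted biomarkers; everything downstream is testable without any
  sequencing data.

## Worked example

```python
from rhizomics import StudyDesign, default_truth, generate_communities, generate_phylogeny
from rhizomics import diversity as dv
from rhizomics import assembly as asm

design = StudyDesign(seed=1)                      # 120-sample factorial grid
truth = default_truth(design)                     # 5 planted biomarkers per cultivar
matrix, metadata = generate_communities(design, truth)
tree = generate_phylogeny(design.n_taxa, design.seed)

rarefied = dv.rarefy(matrix, depth="min", seed=1)
alpha = dv.alpha_diversity(rarefied).merge(metadata, on="sample_id")
print(alpha.groupby("niche")["shannon"].mean().round(2))
# niche
# bulk           4.15
# endosphere     2.99
# rhizoplane     3.62
# rhizosphere    3.92

bc = dv.bray_curtis(rarefied)
res = dv.permanova(bc, metadata.set_index("sample_id").loc[bc.index, "niche"],
                   n_permutations=999, seed=1)
print(f"PERMANOVA niche: R2={res.r_squared:.2f} p={res.p_value:.3f}")
# PERMANOVA niche: R2=0.41 p=0.001
```

Shannon diversity declines monotonically from bulk soil to the endosphere —
the planted niche-filtering gradient — and the niche factor explains a
significant share of the Bray–Curtis variance.

The same pipeline runs end-to-end from a YAML config:

```bash
rhizomics synth --seed 1 --outdir fixtures/          # write ASV/metadata/tree/Cd
rhizomics run --config config.yaml                   # all stages + manifest.json
```

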