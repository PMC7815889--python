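# Methods

## Study design the package implements

Two cohorts are analyzed throughout: a general-population control cohort
and an IBD patient cohort (defaults 920 and 435 samples). Association
between host genotype and microbial abundance is established by a
two-stage design — discovery in one cohort, same-direction replication in
the other — followed by a signed weighted-Z meta-analysis, because a
single pooled analysis would confound genetic effects with the large
compositional differences between patients and controls. Four stages
share this machinery: exome-wide common variants, a targeted set (common
protein-truncating variants plus variants in known IBD loci), gene-based
rare-variant and CNV burden scores, and a disease×genotype interaction
stage run on signals seen in exactly one cohort.

## Statistical components

**Hardy-Weinberg exact test.** Conditional on the observed allele counts,
the heterozygote count h under HWE has probability

    P(h) ∝ 2^h · n! / (h! · n_AA(h)! · n_aa(h)!)

over counts of the same parity. The two-sided p sums P(h') over all h'
with P(h') ≤ P(h_obs). Computed in log-gamma space and normalized per
table, so it is exact up to float rounding (verified against an
exact-rational enumeration oracle for every table with ≤ 50 genotypes;
max |Δp| ≈ 2×10⁻¹⁴). Monomorphic variants return p = 1 by convention.

**Inverse-rank (Blom) transform.** score = Φ⁻¹((r − 3/8)/(n + 1/4)) with
average ranks for ties; the offset is configurable. Scores are
mean-centered afterwards: with ties (zeros share the bottom rank) the raw
scores of average ranks are not symmetric, and a zero-mean transformed
scale is part of the FeatureTable contract. Centering preserves ranks and
is absorbed by the regression intercept downstream. The transform is
applied within cohort over all retained samples *including* zeros;
zero-abundance samples are instead excluded later, at test time, via the
non-zero mask of the raw abundances. This order (filter → transform →
residualize, association masked to non-zero) keeps residuals comparable
across samples while honoring the non-zero restriction of the tests.
Applying the transform per cohort rather than pooled matches the
meta-analytic design, which models each cohort separately.

**Spearman mbQTL test.** Average-rank Spearman ρ with the t-distribution
two-sided p; an exact full-enumeration permutation p is available for
n ≤ 9. Pairs with fewer than 10 usable samples (configurable), or a
constant dosage or abundance after masking, are flagged untestable and
excluded from multiple-testing denominators. Missing genotypes are
dropped pairwise.

**Weighted-Z meta-analysis.** z_i = sign_i·Φ⁻¹(1 − p_i/2) with weights
√n_i; p_meta = 2(1 − Φ(|z_meta|)). The signed two-sided conversion was
validated against the published worked example (per-cohort p 1.47×10⁻⁵
and 1.43×10⁻³, both negative): with √920 and √435 weights it returns
meta p = 7.57×10⁻⁸ vs the printed 7.50×10⁻⁸ (0.9% relative, input
p-values printed at 3 significant figures); a one-sided conversion
misses by more than 2×. Weights default to the per-test n_used; a config
switch substitutes full cohort sizes (needed to reproduce the printed
example exactly, where prevalence ≈ 1). "FDR" in all outputs is the
Bonferroni-adjusted meta p, min(1, p_meta · n_tests), matching the
study's usage. All threshold comparisons are strict inequalities.

**Two-stage selection.** Gates in order: discovery p < p_d; replication
p < p_r with equal direction; meta p < α/n_tests. Stage presets:
exome-wide (5×10⁻⁵, 0.05), targeted (0.001, 0.05), PTV burden
(0.005, 0.05), CNV burden (0.05, 0.05); n_tests is the stage's unit
count. Every stage also runs with discovery and replication cohorts
swapped.

**Burden scores.** Per gene, the unweighted sum of minor-allele dosages
over qualifying PTVs (MAF < 5%, stop-gain/frameshift/splice-disrupting);
missing genotypes contribute 0. CNV scores count deletion and duplication
events per gene separately, and the two are never pooled into one
statistic. Madsen-Browning-style MAF weighting exists as an option but is
off by default, since the emulated procedure used plain counts; a
variance-component (SKAT-type) test is a deliberate non-goal.

**Interaction stage.** Candidates are pairs reaching the stage's meta
cutoff as a per-cohort p in exactly one cohort while failing replication
(p > 0.05) in the other; the interaction threshold is 0.05/n_candidates.
The pooled model `feature ~ g + disease + g×disease + shared covariates`
is fit by OLS on non-zero samples (disease location is dropped — it is
undefined for controls). The permutation statistic is |β_interaction|
(two-sided by absolute value; the procedure being emulated does not name
its statistic), the disease label alone is permuted so covariate-genotype
linkage is preserved, and the empirical p uses the add-one estimator
(1 + #{|β_perm| ≥ |β_obs|})/(B + 1) with B = 999 by default — it cannot
be zero. Both asymptotic and empirical p are reported, since which one
the emulated analysis published is ambiguous. Covariate columns are
z-scored inside the fit (read depth is ~10⁷ on its raw scale and would
otherwise dominate the normal equations); this leaves the genotype,
disease and interaction coefficients unchanged.

## Genotype and sample QC choices

- HWE is computed on the control cohort only (disease can distort
  genotype proportions at trait-associated loci); configurable to all
  samples. MAF is computed on non-missing genotypes pooled across
  cohorts; configurable.
- PCA outliers: study and reference-panel dosages are merged over shared
  variants, mean-imputed, scaled to unit variance per variant (the
  emulated procedure does not state its scaling; unit variance chosen),
  and a sample is removed only if outside mean ± 3 SD on both PC1 and
  PC2. Note the AND rule is conservative by construction: a lone
  divergent sample aligns PC1 with itself and is typically *not* outside
  3 SD on PC2, so single outliers can survive; the rule targets groups of
  ancestry outliers off-diagonal in PC space.
- Relatedness: pi-hat is an input (real studies compute it with
  dedicated IBD tooling); pruning greedily removes the sample in the most
  over-threshold pairs, breaking ties toward lower call rate, then the
  lexicographically later id. A genomic-relationship moment estimator is
  provided for synthetic data only — its noise scales as 1/√markers, so
  the pipeline skips relatedness pruning below 300 QC'd variants.
- The X-inbreeding coefficient is an input column, same rationale.
- MAF exactly 0.05 is assigned to the common partition.

## Synthetic-data generator

The generator emulates the study's structure, not any real cohort's
values: what passes on it shows the pipeline's statistical machinery is
correct and calibrated, not that real-data findings would reproduce.

- **Genotypes**: each variant drawn i.i.d. in Hardy-Weinberg proportions
  at a MAF uniform in its configured range; genotypes missing completely
  at random at rate 0.002 (call rate ≈ 0.998). No linkage
  disequilibrium, so every variant is an independent test — real exomes
  have correlated tests and effective test counts below the nominal
  Bonferroni denominator.
- **Rare PTVs**: genes carry 1-10 PTVs each; rare MAF uniform in
  (0.005, 0.049).
- **CNVs**: every requested gene receives deletion and/or duplication
  events with carrier counts capped strictly below the 1% site-frequency
  bound (defaults to 267 genes, the scale of the emulated call set).
- **Abundances**: zero-inflated log-normal. Per feature: log-mean
  uniform in (−14, −5) (relative abundances ~10⁻⁶-10⁻²), noise SD σ_f
  uniform in (0.6, 1.4), structural-zero probability uniform in a
  configured range (default (0, 0.8); the emulated cohorts publish no
  per-feature zero statistics, so it is a free parameter). Zeros are
  independent of genotype, so planted-null data give uniform association
  p-values. Covariate and planted-effect slopes are expressed in units of
  σ_f so that after inverse-rank normalization a planted `effect_size` is
  the slope per minor allele on the transformed (SD = 1) scale. Feature
  counts default to 242 taxa + 301 pathways, the emulated panel size.
- **Not modeled** (documented limitations): compositional
  renormalization after planting effects (it would couple features and
  blur ground truth), LD, strain-level variation, longitudinal sampling,
  genotype-dependent zero inflation, overdispersed or correlated features.
- **Covariates**: age ~ U(20, 70) y, 60% female, BMI ~ N(25, 4),
  binary medication flags at realistic prevalences (PPI and antibiotic
  use more frequent in patients), read depth log-normal around 2×10⁷
  reads, CD/UC/IBDU subtypes at 55/35/10%, disease location for patients
  only. Any distributions satisfying the pipeline's contracts would do;
  these mirror typical cohort descriptions.
- Fixed seed ⇒ byte-identical datasets and pipeline outputs
  (per-component independent PCG64 streams seeded as (stream, seed)).

## Problem sizes in tests and the acceptance script

Simulated scale is chosen for desk-scale reproducibility while keeping
the cohort sizes real: recovery experiments use 920/435 samples but
60 variants × 10 features per seed (the Bonferroni denominator then uses
the simulated variant count, as the thresholds are n_tests-relative);
calibration uses 1000-2000 null draws at n = 100-200. The full published
variant panel (73 164 common variants) enters only through the threshold
arithmetic, which is scale-exact.

## Known numerical conventions

- Degenerate rankings (all values tied) raise rather than return scores.
- Zero p-values are rejected by the z-conversion; callers clamp at the
  float minimum (the meta p itself is clamped at 5×10⁻³²⁴).
- Logistic fits flag complete or quasi-complete separation (optimizer
  failure, non-finite SE, or |log OR| > 15) instead of reporting Wald
  statistics.
- Rank-deficient residualization designs warn and project anyway (the
  least-squares projection is unique even when coefficients are not).
- Report tables round to 6 significant digits; manifests hash the
  written files, so determinism claims are about bytes on disk.
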