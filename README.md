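# mbqtl

Two-cohort microbial quantitative trait locus (mbQTL) analysis: mapping
host genetic variants to the abundance of gut microbial taxa and MetaCyc
pathways with a discovery/replication design, and asking whether those
genetic effects depend on disease status.

The package is aimed at statistical-genetics and microbiome researchers
who have, for two cohorts (here: a general-population cohort and an IBD
patient cohort), exome genotypes (VCF), rare CNV calls, MetaPhlAn/
HUMAnN2-style relative-abundance tables and a covariate table — or who
want to prototype and validate such an analysis on synthetic data with
known planted effects, which the package generates itself.

## What it computes

**QC.** Variants are dropped at call rate < 0.99 or Hardy-Weinberg exact
p < 1e-4 (an in-package two-sided exact test conditional on allele
counts); samples are dropped as ancestry outliers (outside mean ± 3 SD on
*both* of the first two PCs against a reference panel), sex mismatches
(X-inbreeding f < 0.4 for females, > 0.7 for males) or relatives
(pi-hat > 0.185, greedy pruning). Variants partition into common
(MAF ≥ 5%) and rare protein-truncating (MAF < 5%) sets; CNVs are kept
below 1% site frequency.

**Feature preparation.** Per cohort: prevalence filter (taxa ≥ 10%,
pathways ≥ 25% of samples, intersected across cohorts), inverse-rank
(Blom) normalization, then OLS residualization on age, sex, BMI, smoking,
PPI/laxative/antibiotic use, read depth and (patients only) disease
location.

**Association and meta-analysis.** Within each cohort, Spearman
correlation between minor-allele dosage g ∈ {0,1,2} and the residualized
abundance, confined to samples with non-zero raw abundance. Signals with
discovery p < 5×10⁻⁵ that replicate in the other cohort (p < 0.05, same
direction) are combined with a signed Stouffer weighted-Z statistic,

    z_i = sign(ρ_i) · Φ⁻¹(1 − p_i/2),   w_i = √n_i,
    z_meta = Σ w_i z_i / √(Σ w_i²),      p_meta = 2(1 − Φ(|z_meta|)),

and kept below the Bonferroni cutoff α/n_tests (0.05/73 164 = 6.83×10⁻⁷
at the exome-wide scale). The run is repeated with cohorts swapped, and a
targeted stage restricts to common PTVs and variants in known
IBD-associated loci.

**Burden tests.** Rare PTVs collapse to per-gene, per-sample scores
(unweighted sum of minor-allele dosages); rare CNVs collapse to per-gene
deletion and duplication counts, analyzed separately. Scores replace the
dosage in the same Spearman/meta machinery.

**Interaction.** mbQTLs significant in exactly one cohort are re-fit on
the pooled cohorts as
`feature ~ g + disease + g×disease + covariates`, with the asymptotic
interaction p calibrated by 999 permutations of the disease label
(add-one empirical p). Recessive genotype coding and CD/UC subgroup
re-analyses are included.

## Worked example

```python
from mbqtl import weighted_z_meta, bonferroni_threshold, hwe_exact_test

m = weighted_z_meta([(1.47e-5, -1, 920), (1.43e-3, -1, 435)])
print(f"z_meta = {m.z:.3f}, meta p = {m.p:.3g}")
print(f"exome-wide cutoff = {bonferroni_threshold(0.05, 73164):.3g}")
print(f"HWE p (5 hom-major, 0 het, 5 hom-minor) = {hwe_exact_test(5,0,5):.5f}")
```

prints

```
z_meta = -5.377, meta p = 7.57e-08
exome-wide cutoff = 6.83e-07
HWE p (5 hom-major, 0 het, 5 hom-minor) = 0.00136
```

The first two lines combine per-cohort p-values of 1.47×10⁻⁵ (n = 920)
and 1.43×10⁻³ (n = 435), both with decreasing abundance, into a meta
p ≈ 7.6×10⁻⁸ — well below the exome-wide significance cutoff, so this
variant–pathway pair would be reported as an mbQTL. The third line shows
the exact Hardy-Weinberg test flagging a complete heterozygote deficit.

End-to-end on synthetic data:

```bash
mbqtl simulate --out demo_data          # two-cohort dataset + ground truth
mbqtl all --seed 7 --out demo_run       # QC → prep → steps 1-4
```

Each stage writes a TSV result table plus a `run_manifest.json` of
SHA-256 hashes; rerunning with the same seed reproduces every file
byte-for-byte. `mbqtl report --stage step1` formats the selected signals
as a publication-style table (Chr, Pos, Allele, SNP, Gene symbol,
Annotation, Feature, Meta P, Meta FDR, per-cohort p and r).

## Layout

- `mbqtl.simulate` — synthetic two-cohort generator with planted effects
- `mbqtl.qc` — variant/sample QC and MAF partitioning
- `mbqtl.features` — prevalence filter, Blom transform, residualization
- `mbqtl.assoc` — Spearman mbQTL, case-control feature and variant tests
- `mbqtl.meta` — thresholds, weighted-Z meta, two-stage selection
- `mbqtl.burden` — gene PTV and CNV burden scores and tests
- `mbqtl.interaction` — interaction models, permutations, subgroups
- `mbqtl.pipeline` / `mbqtl.cli` — orchestration and the `mbqtl` command

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
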