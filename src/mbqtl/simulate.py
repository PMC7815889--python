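"""Two-cohort synthetic dataset generator with known planted effects.

Emulates the study design the pipeline targets: a general-population control
cohort (~920 samples) and an IBD patient cohort (~435 samples) with

* common biallelic variants drawn in Hardy-Weinberg proportions at a
  configurable MAF, plus rare protein-truncating variants (MAF < 5%)
  grouped into genes,
* rare gene-level CNV events (site frequency < 1%),
* zero-inflated log-normal microbial relative abundances (taxa and
  pathways) carrying covariate effects and, optionally, planted genotype
  and genotype x disease effects,
* the nine association covariates (age, sex, BMI, smoking, PPI/laxative/
  antibiotic use, read depth, disease location for patients).

Every planted effect is recorded in a ground-truth manifest so downstream
stages can be tested for parameter recovery. A fixed seed reproduces the
dataset exactly, file-for-file.

Effect-size convention: ``PlantedEffect.effect_size`` is the slope per
minor allele on the inverse-rank transformed scale, i.e. in units of the
feature's log-scale noise SD. Internally the generator multiplies by the
feature's own noise SD so the convention holds whatever SD was drawn.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    COHORT_IBD,
    COHORT_POPULATION,
    CnvCallSet,
    FeatureTable,
    GenotypeMatrix,
    PTV_CLASSES,
    validate_sample_table,
)

_NON_PTV_ANNOTATIONS = ("missense", "synonymous", "intron", "intergenic", "other")
_NON_PTV_WEIGHTS = (0.25, 0.27, 0.30, 0.13, 0.05)
_PTV_ANNOTATIONS = tuple(sorted(PTV_CLASSES))
_DISEASE_LOCATIONS = ("ileal", "colonic", "ileocolonic")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect of one variant (or gene score) on one feature.

    ``effect_size`` is the additive slope per minor allele on the
    transformed (noise-SD) scale; ``mode`` selects additive or recessive
    genotype coding; with ``interaction_with_disease`` the slope differs
    between patients and controls by ``interaction_size``.
    """

    target_feature: str
    source: str
    effect_size: float
    mode: str = "additive"
    interaction_with_disease: bool = False
    interaction_size: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic two-cohort study.

    Cohort sizes default to the scale of the emulated study (920 population
    controls, 435 IBD patients); variant and feature counts default to a
    scaled-down exome that keeps simulation tractable while exercising every
    pipeline stage (242 taxa and 301 pathways match the study's feature
    panel).
    """

    n_controls: int = 920
    n_cases: int = 435
    n_common_variants: int = 500
    n_rare_ptvs: int = 400
    n_cnv_genes: int = 267
    maf_range: tuple[float, float] = (0.05, 0.5)
    rare_maf_range: tuple[float, float] = (0.005, 0.049)
    cnv_site_freq_max: float = 0.01
    n_taxa: int = 242
    n_pathways: int = 301
    zero_inflation_range: tuple[float, float] = (0.0, 0.8)
    covariate_effect_sizes: dict = field(
        default_factory=lambda: {
            "age": 0.10,
            "sex": 0.10,
            "bmi": 0.05,
            "smoking": 0.05,
            "ppi": 0.05,
            "laxative": 0.05,
            "antibiotic": 0.10,
            "read_depth": 0.10,
            "disease": 0.20,
        }
    )
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0
    # secondary knobs
    missing_rate: float = 0.002
    ibd_locus_fraction: float = 0.04
    common_ptv_fraction: float = 0.05
    noise_sd_range: tuple[float, float] = (0.6, 1.4)
    log_mean_range: tuple[float, float] = (-14.0, -5.0)
    n_reference: int = 200

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_cases", "n_common_variants", "n_rare_ptvs",
                     "n_cnv_genes", "n_taxa", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        lo, hi = self.rare_maf_range
        if not (0 < lo <= hi < 0.05):
            raise ValueError(f"rare_maf_range {self.rare_maf_range} outside (0, 0.05)")
        if not (0 < self.cnv_site_freq_max < 1):
            raise ValueError("cnv_site_freq_max must lie in (0, 1)")
        lo, hi = self.zero_inflation_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("zero_inflation_range must lie within [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))

    @property
    def n_samples(self) -> int:
        return self.n_controls + self.n_cases


@dataclass
class SimulatedDataset:
    """Complete simulated study: all inputs plus the ground-truth manifest."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    reference: GenotypeMatrix
    cnv: CnvCallSet
    features: FeatureTable
    samples: pd.DataFrame


def _rng(stream: int, config: SimulationConfig) -> np.random.Generator:
    # independent, seed-deterministic streams per component
    return np.random.default_rng([stream, config.seed])


# ---------------------------------------------------------------------------
# samples / covariates
# ---------------------------------------------------------------------------

def simulate_samples(config: SimulationConfig) -> pd.DataFrame:
    """Covariate table for both cohorts.

    Distributions follow common population-cohort descriptions: age uniform
    20-70 y, 60% female, BMI ~ N(25, 4), low-prevalence binary medication
    use, log-normal sequencing depth; disease subtype and location are drawn
    for patients only. The X-chromosome inbreeding coefficient is generated
    consistent with the recorded sex (used by the sex-check QC step).
    """
    rng = _rng(0, config)
    n = config.n_samples
    ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    cohort = np.array(
        [COHORT_POPULATION] * config.n_controls + [COHORT_IBD] * config.n_cases,
        dtype=object,
    )
    is_case = cohort == COHORT_IBD

    sex = np.where(rng.random(n) < 0.6, "female", "male").astype(object)
    f = np.where(
        sex == "female",
        rng.normal(0.02, 0.10, n),
        rng.normal(0.88, 0.05, n),
    ).clip(-1.0, 1.0)
    subtype = np.full(n, "none", dtype=object)
    subtype[is_case] = rng.choice(("CD", "UC", "IBDU"), size=is_case.sum(),
                                  p=(0.55, 0.35, 0.10))
    location = np.full(n, np.nan, dtype=object)
    location[is_case] = rng.choice(_DISEASE_LOCATIONS, size=is_case.sum(),
                                   p=(0.3, 0.4, 0.3))

    samples = pd.DataFrame(
        {
            "cohort": cohort,
            "subtype": subtype,
            "age": rng.uniform(20, 70, n),
            "sex": sex,
            "bmi": rng.normal(25, 4, n),
            "smoking": rng.random(n) < 0.25,
            "ppi": rng.random(n) < (0.10 + 0.15 * is_case),
            "laxative": rng.random(n) < 0.05,
            "antibiotic": rng.random(n) < (0.05 + 0.10 * is_case),
            "read_depth": np.exp(rng.normal(np.log(2.0e7), 0.3, n)),
            "disease_location": location,
            "inbreeding_f": f,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return validate_sample_table(samples)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_genotypes(rng, mafs: np.ndarray, n: int) -> np.ndarray:
    # Hardy-Weinberg: dosage ~ Binomial(2, maf) independently per sample
    return rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Common variants plus rare PTVs, in Hardy-Weinberg proportions.

    Common variants carry mostly non-truncating annotations with a small
    PTV fraction and an IBD-locus flag on ~4% of them (mirroring the share
    of known disease loci in an exome panel); rare PTVs are grouped into
    genes of 1-10 variants each so gene burden scores have realistic
    sparsity. A ``missing_rate`` fraction of genotype entries is set
    missing at random.
    """
    rng = _rng(1, config)
    n = config.n_samples
    n_common, n_rare = config.n_common_variants, config.n_rare_ptvs

    maf_common = rng.uniform(*config.maf_range, n_common)
    maf_rare = rng.uniform(*config.rare_maf_range, n_rare)
    mafs = np.concatenate([maf_common, maf_rare])
    dosage = _draw_genotypes(rng, mafs, n)

    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan

    # annotations: common variants mostly non-PTV, rare variants all PTV
    ann_common = rng.choice(_NON_PTV_ANNOTATIONS, n_common, p=_NON_PTV_WEIGHTS)
    is_common_ptv = rng.random(n_common) < config.common_ptv_fraction
    ann_common[is_common_ptv] = rng.choice(_PTV_ANNOTATIONS, is_common_ptv.sum())
    ann_rare = rng.choice(_PTV_ANNOTATIONS, n_rare)

    # rare PTVs fill genes with 1-10 variants each
    rare_genes: list[str] = []
    gene_no = 0
    while len(rare_genes) < n_rare:
        gene_no += 1
        size = int(rng.integers(1, 11))
        rare_genes.extend([f"GENE{gene_no:04d}"] * size)
    rare_genes = rare_genes[:n_rare]
    common_genes = [f"CGENE{i // 5:04d}" for i in range(n_common)]

    n_total = n_common + n_rare
    pos = np.sort(rng.choice(np.arange(1, 50_000_000), n_total, replace=False))
    alleles = np.array(list("ACGT"))
    ref = rng.choice(alleles, n_total)
    alt = np.array([rng.choice([a for a in "ACGT" if a != r]) for r in ref])

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": common_genes + rare_genes,
            "annotation": np.concatenate([ann_common, ann_rare]),
            "ibd_locus": np.concatenate(
                [rng.random(n_common) < config.ibd_locus_fraction,
                 np.zeros(n_rare, dtype=bool)]
            ),
            "sim_maf": mafs,
        },
        index=pd.Index([f"v{i:05d}" for i in range(n_total)], name="variant_id"),
    )
    g = GenotypeMatrix(
        sample_ids=np.array([f"S{i:05d}" for i in range(n)], dtype=object),
        variants=variants,
        dosage=dosage,
    )
    g.recompute_stats()
    return g


def simulate_reference_panel(genotypes: GenotypeMatrix,
                             config: SimulationConfig) -> GenotypeMatrix:
    """Reference-panel genotypes at the same variants and allele frequencies.

    Stands in for an external ancestry panel in the PCA outlier step: drawn
    from the same per-variant MAFs, so study samples and panel share one
    ancestry distribution.
    """
    rng = _rng(4, config)
    mafs = genotypes.variants["sim_maf"].to_numpy()
    dosage = _draw_genotypes(rng, mafs, config.n_reference)
    ref = GenotypeMatrix(
        sample_ids=np.array([f"R{i:05d}" for i in range(config.n_reference)], dtype=object),
        variants=genotypes.variants.copy(),
        dosage=dosage,
    )
    ref.recompute_stats()
    return ref


# ---------------------------------------------------------------------------
# CNVs
# ---------------------------------------------------------------------------

def simulate_cnv_calls(config: SimulationConfig) -> CnvCallSet:
    """Rare gene-level deletion/duplication events.

    Every requested gene receives at least one event type; carrier counts
    are capped so each (gene, type) site frequency stays strictly below
    ``cnv_site_freq_max``.
    """
    rng = _rng(3, config)
    n = config.n_samples
    ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    max_carriers = int(np.ceil(n * config.cnv_site_freq_max)) - 1
    if max_carriers < 1:
        raise ValueError(
            "cohort too small to place any CNV below the site-frequency bound"
        )
    rows = []
    for gi in range(config.n_cnv_genes):
        gene = f"CNVG{gi:04d}"
        which = rng.random()
        types = (["deletion"] if which < 0.4
                 else ["duplication"] if which < 0.8
                 else ["deletion", "duplication"])
        for t in types:
            m = min(1 + rng.poisson(1.0), max_carriers)
            carriers = rng.choice(ids, size=m, replace=False)
            rows.extend({"sample_id": s, "gene": gene, "type": t} for s in carriers)
    events = pd.DataFrame(rows, columns=["sample_id", "gene", "type"])
    return CnvCallSet(events=events, n_samples=n)


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_abundances(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
) -> FeatureTable:
    """Zero-inflated log-normal relative abundances with planted effects.

    Each feature draws a log-scale mean, a noise SD, and a zero-inflation
    probability; non-zero samples get log-abundance = mean + covariate
    effects + planted genotype (and genotype x disease) effects + Gaussian
    noise, exponentiated and clipped to [0, 1]. Covariate and planted
    slopes are expressed in noise-SD units (see module docstring), and the
    structural zeros are independent of genotype, so planted-null datasets
    give uniform association p-values downstream.
    """
    if not np.array_equal(genotypes.sample_ids, samples.index.to_numpy()):
        raise ValueError("genotypes and samples must share sample ids, in order")
    rng = _rng(2, config)
    n = len(samples)
    n_feat = config.n_taxa + config.n_pathways
    taxa = [f"t__Taxon{i:04d}" for i in range(config.n_taxa)]
    pathways = [f"PWY-{1000 + i}" for i in range(config.n_pathways)]
    feat_ids = pd.Index(taxa + pathways, name="feature_id")
    kinds = ["taxon"] * config.n_taxa + ["pathway"] * config.n_pathways

    # per-feature parameters
    mu = rng.uniform(*config.log_mean_range, n_feat)
    sigma = rng.uniform(*config.noise_sd_range, n_feat)
    zero_frac = rng.uniform(*config.zero_inflation_range, n_feat)

    # covariate design on the log scale, standardized per covariate
    cov_cols = {}
    for name, size in config.covariate_effect_sizes.items():
        if size == 0:
            continue
        if name == "disease":
            col = (samples["cohort"] == COHORT_IBD).to_numpy(float)
        elif name == "sex":
            col = (samples["sex"] == "female").to_numpy(float)
        elif name in ("smoking", "ppi", "laxative", "antibiotic"):
            col = samples[name].to_numpy(float)
        else:
            col = samples[name].to_numpy(float)
        cov_cols[name] = (_standardize(col), float(size))

    # random sign per (feature, covariate) so effects are heterogeneous
    log_y = mu[None, :] + np.zeros((n, n_feat))
    for col, size in cov_cols.values():
        signs = rng.choice((-1.0, 1.0), n_feat)
        log_y += col[:, None] * (signs * size * sigma)[None, :]

    # planted genotype and genotype x disease effects
    disease = (samples["cohort"] == COHORT_IBD).to_numpy(float)
    feat_pos = {f: i for i, f in enumerate(feat_ids)}
    for eff in config.planted_effects:
        if eff.target_feature not in feat_pos:
            raise ValueError(f"planted effect targets unknown feature {eff.target_feature!r}")
        if eff.source not in genotypes.variants.index:
            raise ValueError(f"planted effect references unknown variant {eff.source!r}")
        j = feat_pos[eff.target_feature]
        dos = genotypes.dosage_series(eff.source).to_numpy()
        x = np.where(np.isfinite(dos), dos, 0.0)
        if eff.mode == "recessive":
            x = (x == 2).astype(float)
        log_y[:, j] += eff.effect_size * sigma[j] * x
        if eff.interaction_with_disease:
            log_y[:, j] += eff.interaction_size * sigma[j] * x * disease

    log_y += rng.normal(0.0, sigma[None, :], size=(n, n_feat))
    raw = np.minimum(np.exp(log_y), 1.0)
    raw[rng.random((n, n_feat)) < zero_frac[None, :]] = 0.0

    meta = pd.DataFrame(
        {
            "kind": kinds,
            "rank": ["species"] * config.n_taxa + ["pathway"] * config.n_pathways,
            "sim_zero_inflation": zero_frac,
            "sim_noise_sd": sigma,
        },
        index=feat_ids,
    )
    table = FeatureTable(
        raw=pd.DataFrame(raw.T, index=feat_ids, columns=samples.index),
        meta=meta,
    )
    table.provenance["generator"] = "zero-inflated log-normal"
    return table


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the complete two-cohort study from one config."""
    samples = simulate_samples(config)
    genotypes = simulate_genotypes(config)
    reference = simulate_reference_panel(genotypes, config)
    cnv = simulate_cnv_calls(config)
    features = simulate_abundances(config, genotypes, samples)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        reference=reference,
        cnv=cnv,
        features=features,
        samples=samples,
    )


def manifest_dict(config: SimulationConfig) -> dict:
    """JSON-ready ground-truth manifest: config plus every planted effect."""
    cfg = dataclasses.asdict(config)
    cfg["planted_effects"] = [dataclasses.asdict(e) for e in config.planted_effects]
    return cfg
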