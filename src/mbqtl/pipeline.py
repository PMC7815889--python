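"""End-to-end orchestration of the four-step mbQTL analysis.

From one YAML config the pipeline runs: genotype/sample QC -> feature
preparation -> step 1 (exome-wide common-variant mbQTLs) -> step 2
(targeted common PTVs + IBD-locus variants) -> step 3 (gene-based PTV and
CNV burden) -> step 4 (disease x genotype interaction on single-cohort
signals, permutation-calibrated). Inputs come either from files written by
:func:`mbqtl.io.write_dataset` or from the synthetic generator directly;
every stage writes its result table as TSV and the run manifest records a
SHA-256 per output so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .assoc import mbqtl_scan
from .burden import burden_two_stage, gene_cnv_score, gene_ptv_score
from .containers import COHORT_IBD, COHORT_POPULATION
from .features import prepare_features
from .interaction import (
    interaction_design_from_samples,
    permutation_calibration,
    select_interaction_candidates,
)
from .meta import StageThresholds, run_both_directions, targeted_variant_set
from .qc import estimate_pihat, filter_variants, partition_by_maf, run_sample_qc
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("mbqtl")

ALL_STAGES = ("qc", "prep", "step1", "step2", "step3", "step4")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML losslessly."""

    out_dir: str = "mbqtl_run"
    data_dir: str | None = None  # dataset written by write_dataset
    simulation: dict = field(default_factory=dict)  # used when data_dir is None
    seed: int = 0
    # QC thresholds
    call_rate_min: float = 0.99
    hwe_alpha: float = 1e-4
    pca_k_sd: float = 3.0
    pihat_threshold: float = 0.185
    # moment-based pi-hat has SD ~ 1/sqrt(markers); below this many QC'd
    # variants the estimates cannot separate relatives from noise, so the
    # relatedness filter is skipped (real studies supply pi-hat externally)
    min_variants_for_pihat: int = 300
    cnv_site_freq_max: float = 0.01
    # feature preparation
    taxon_prevalence_min: float = 0.10
    pathway_prevalence_min: float = 0.25
    blom_offset: float = 0.375
    log_read_depth: bool = False
    # association stages
    discovery_p: dict = field(default_factory=lambda: {
        "step1": 5e-5, "step2": 0.001, "step3_ptv": 0.005, "step3_cnv": 0.05,
    })
    replication_p: float = 0.05
    alpha: float = 0.05
    weight_mode: str = "n_used"
    min_n_used: int = 10
    # interaction stage
    n_permutations: int = 999
    max_interaction_pairs: int = 200  # cap on permutation-calibrated pairs

    def __post_init__(self) -> None:
        # YAML has no tuple type; normalize so serialization round-trips
        self.simulation = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in self.simulation.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        """Check referenced inputs exist before any stage runs."""
        if self.data_dir is not None:
            root = Path(self.data_dir)
            required = ("genotypes.vcf", "abundances.tsv", "covariates.tsv",
                        "cnv_calls.tsv")
            missing = [f for f in required if not (root / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"data_dir {root} lacks input file(s): {missing}"
                )
        for k, v in self.discovery_p.items():
            if not 0 < v <= 1:
                raise ValueError(f"discovery threshold {k}={v} outside (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest[path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Execute the requested stages in order; returns the result bundle.

    The bundle maps stage names to their in-memory tables and carries the
    run manifest (output file name -> SHA-256). Earlier stages a later one
    depends on are always (re)computed; a fixed seed makes the whole bundle
    reproducible byte-for-byte.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    bundle: dict = {"manifest": manifest}

    # ------------------------------------------------------------ inputs
    if config.data_dir is not None:
        dataset = mio.read_dataset(config.data_dir)
    else:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        dataset = simulate_dataset(SimulationConfig(**sim_kwargs))
    samples = dataset.samples
    cohorts = (COHORT_POPULATION, COHORT_IBD)

    # ---------------------------------------------------------------- QC
    log.info("QC: %d variants, %d samples", dataset.genotypes.n_variants,
             dataset.genotypes.n_samples)
    g_filt, var_report = filter_variants(
        dataset.genotypes, config.call_rate_min, config.hwe_alpha,
        samples=samples,
    )
    if g_filt.n_variants >= config.min_variants_for_pihat:
        pihat = estimate_pihat(g_filt)
    else:
        log.info("skipping relatedness pruning: only %d variants",
                 g_filt.n_variants)
        pihat = None
    g_clean, samples_clean, sample_report = run_sample_qc(
        g_filt, samples, dataset.reference, pihat=pihat,
        k_sd=config.pca_k_sd, pihat_threshold=config.pihat_threshold,
    )
    common, rare_ptv = partition_by_maf(g_clean)
    cnv = dataset.cnv.filter_by_frequency(config.cnv_site_freq_max)
    bundle["qc"] = {
        "genotypes": g_clean, "common": common, "rare_ptv": rare_ptv,
        "cnv": cnv, "samples": samples_clean,
        "variant_report": var_report, "sample_report": sample_report,
    }
    _write(var_report.removed_variants, out_dir / "qc_removed_variants.tsv", manifest)
    _write(sample_report.removed_samples, out_dir / "qc_removed_samples.tsv", manifest)
    if stages[-1] == "qc":
        return bundle

    # -------------------------------------------------------------- prep
    features = prepare_features(
        dataset.features.subset_samples(samples_clean.index), samples_clean,
        taxon_min=config.taxon_prevalence_min,
        pathway_min=config.pathway_prevalence_min,
        blom_offset=config.blom_offset,
        log_read_depth=config.log_read_depth,
    )
    bundle["prep"] = {"features": features}
    _write(
        features.residual.reset_index(),
        out_dir / "prepared_features.tsv", manifest,
    )
    if stages[-1] == "prep":
        return bundle

    # ------------------------------------------------------------- scans
    scans = {
        c: mbqtl_scan(common, features, samples_clean, c, min_n=config.min_n_used)
        for c in cohorts
    }

    # step 1: exome-wide
    if "step1" in stages or "step4" in stages:
        thr1 = StageThresholds(config.discovery_p["step1"],
                               config.replication_p, common.n_variants,
                               alpha=config.alpha)
        step1 = run_both_directions(
            scans[COHORT_POPULATION], scans[COHORT_IBD], thr1,
            COHORT_POPULATION, COHORT_IBD, weight_mode=config.weight_mode,
            cohort_sizes={c: int((samples_clean["cohort"] == c).sum())
                          for c in cohorts},
        )
        step1["thresholds"] = thr1
        bundle["step1"] = step1
        _write(step1["primary"], out_dir / "step1_meta_primary.tsv", manifest)
        _write(step1["swapped"], out_dir / "step1_meta_swapped.tsv", manifest)

    # step 2: targeted set
    if "step2" in stages or "step4" in stages:
        targeted = targeted_variant_set(common)
        thr2 = StageThresholds(config.discovery_p["step2"],
                               config.replication_p, len(targeted),
                               alpha=config.alpha)
        sub = {c: s[s["unit"].isin(targeted)] for c, s in scans.items()}
        step2 = run_both_directions(
            sub[COHORT_POPULATION], sub[COHORT_IBD], thr2,
            COHORT_POPULATION, COHORT_IBD, weight_mode=config.weight_mode,
            cohort_sizes={c: int((samples_clean["cohort"] == c).sum())
                          for c in cohorts},
        )
        step2["thresholds"] = thr2
        step2["variant_ids"] = targeted
        bundle["step2"] = step2
        _write(step2["primary"], out_dir / "step2_meta_primary.tsv", manifest)
        _write(step2["swapped"], out_dir / "step2_meta_swapped.tsv", manifest)

    # step 3: burden
    if "step3" in stages:
        ptv_scores = gene_ptv_score(rare_ptv) if rare_ptv.n_variants else []
        step3: dict = {}
        if ptv_scores:
            step3["ptv"] = burden_two_stage(
                ptv_scores, features, samples_clean, *cohorts,
                kind="ptv", min_n=config.min_n_used,
            )
            _write(step3["ptv"]["primary"], out_dir / "step3_ptv_meta.tsv", manifest)
        cnv_scores = gene_cnv_score(cnv, samples_clean.index,
                                    config.cnv_site_freq_max)
        if cnv_scores:
            step3["cnv"] = burden_two_stage(
                cnv_scores, features, samples_clean, *cohorts,
                kind="cnv", min_n=config.min_n_used,
            )
            _write(step3["cnv"]["primary"], out_dir / "step3_cnv_meta.tsv", manifest)
        bundle["step3"] = step3
    if stages[-1] == "step3":
        return bundle

    # step 4: interaction on single-cohort signals
    if "step4" in stages:
        rng = np.random.default_rng(config.seed)
        design = interaction_design_from_samples(samples_clean)
        disease = (samples_clean["cohort"] == COHORT_IBD).to_numpy(float)
        rows = []
        for stage_name in ("step1", "step2"):
            if stage_name not in bundle:
                continue
            st = bundle[stage_name]
            cand, thr = select_interaction_candidates(
                st["primary"], st["swapped"],
                discovery_p_max=st["thresholds"].p_meta_max,
                replication_p_min=config.replication_p,
                alpha=config.alpha,
            )
            cand = cand.head(config.max_interaction_pairs)
            for _, row in cand.iterrows():
                dos = common.dosage_series(row["unit"]).reindex(samples_clean.index)
                fid = row["feature"]
                res = permutation_calibration(
                    features.transformed.loc[fid].to_numpy(),
                    dos.to_numpy(), disease, design,
                    nonzero_mask=features.nonzero.loc[fid].to_numpy(),
                    n_permutations=config.n_permutations,
                    seed=rng, unit=row["unit"], feature=fid,
                    candidate_origin=row["candidate_origin"],
                )
                rows.append({
                    "stage": stage_name, "unit": res.unit, "feature": res.feature,
                    "candidate_origin": res.candidate_origin,
                    "beta_genotype": res.beta_genotype,
                    "beta_disease": res.beta_disease,
                    "beta_interaction": res.beta_interaction,
                    "p_interaction": res.p_interaction,
                    "p_empirical": res.p_empirical,
                    "n_permutations": res.n_permutations,
                    "n_used": res.n_used,
                    "interaction_threshold": thr,
                    "untestable": res.untestable,
                })
        step4 = pd.DataFrame(rows)
        bundle["step4"] = step4
        _write(step4, out_dir / "step4_interactions.tsv", manifest)

    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle


REPORT_COLUMNS = [
    "Chr", "Pos", "Allele", "SNP", "Gene symbol", "Annotation", "Feature",
    "Meta P", "Meta FDR", "P discovery", "r discovery",
    "P replication", "r replication",
]


def make_report(meta_table: pd.DataFrame, genotypes=None,
                stage: str = "exome_wide") -> pd.DataFrame:
    """Publication-style result table for one stage's selected signals.

    Columns mirror the study's result tables (chromosome, position,
    alleles, variant/gene id, annotation, feature, meta p, Bonferroni-
    adjusted meta p, per-cohort p and correlation); burden stages add the
    per-cohort linear effect sizes (Beta) when present.
    """
    sel = meta_table[meta_table.get("selected", pd.Series(dtype=bool))
                     .astype(bool)] if len(meta_table) else meta_table
    rows = []
    for _, r in sel.iterrows():
        meta_row = {
            "Chr": "", "Pos": "", "Allele": "", "SNP": r["unit"],
            "Gene symbol": "", "Annotation": "",
            "Feature": r["feature"],
            "Meta P": r["p_meta"], "Meta FDR": r["adjusted_p"],
            "P discovery": r["p_disc"], "r discovery": r["estimate_disc"],
            "P replication": r["p_rep"], "r replication": r["estimate_rep"],
        }
        if genotypes is not None and r["unit"] in genotypes.variants.index:
            v = genotypes.variants.loc[r["unit"]]
            meta_row.update({
                "Chr": v["chrom"], "Pos": v["pos"],
                "Allele": f"{v['ref']}/{v['alt']}",
                "Gene symbol": v["gene"], "Annotation": v["annotation"],
            })
        if "beta_disc" in r.index:
            meta_row["Beta discovery"] = r["beta_disc"]
            meta_row["Beta replication"] = r["beta_rep"]
        rows.append(meta_row)
    cols = REPORT_COLUMNS + (
        ["Beta discovery", "Beta replication"]
        if any("Beta discovery" in r for r in rows) or stage.startswith("burden")
        else []
    )
    return pd.DataFrame(rows, columns=cols)
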