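"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 (GT field only; in synthetic VCFs the ALT
allele is the minor allele, so alt-allele count equals minor-allele
dosage) with a sidecar TSV carrying the annotation class, gene symbol and
IBD-locus flag per variant. Abundances, covariates and CNV events are
plain TSV; the ground-truth manifest of a simulated dataset is JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import CnvCallSet, FeatureTable, GenotypeMatrix, validate_sample_table

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes and an index-friendly header."""
    path = Path(path)
    chroms = pd.unique(g.variants["chrom"].astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mbqtl\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        dosage = g.dosage
        for j, (vid, row) in enumerate(g.variants.iterrows()):
            gts = "\t".join(
                _GT_CODES.get(dosage[i, j], "./.") for i in range(g.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(vcf_path, annotation_path=None) -> GenotypeMatrix:
    """Load genotypes from VCF; dosage counts ALT alleles (synthetic = minor).

    ``annotation_path`` points to the sidecar TSV with columns
    ``variant_id``, ``gene``, ``annotation``, ``ibd_locus``; without it those
    metadata default to unknown/False.
    """
    records = []
    dosages = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        sample_ids = np.array(list(vf.header.samples), dtype=object)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"variant {rec.id} is not biallelic")
            row = np.full(len(sample_ids), np.nan)
            for i, s in enumerate(sample_ids):
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    continue
                row[i] = float(sum(alleles))
            records.append(
                (rec.id, str(rec.chrom), int(rec.pos), rec.ref, rec.alts[0])
            )
            dosages.append(row)
    variants = pd.DataFrame(
        records, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    ).set_index("variant_id")
    variants["gene"] = ""
    variants["annotation"] = "other"
    variants["ibd_locus"] = False
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col="variant_id")
        for col in ("gene", "annotation", "ibd_locus"):
            if col in ann.columns:
                variants.loc[ann.index, col] = ann[col]
        variants["ibd_locus"] = variants["ibd_locus"].astype(bool)
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosage=np.array(dosages, dtype=float).T if dosages else
        np.empty((len(sample_ids), 0)),
    )
    g.recompute_stats()
    return g


def write_feature_table(features: FeatureTable, path) -> None:
    """Features x samples TSV of raw relative abundances."""
    features.raw.to_csv(path, sep="\t", index_label="feature_id")


def read_feature_table(path, meta_path=None) -> FeatureTable:
    raw = pd.read_csv(path, sep="\t", index_col="feature_id")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="feature_id")
    else:
        # taxa follow the profiler's t__ prefix convention; rest are pathways
        kind = ["taxon" if f.startswith("t__") else "pathway" for f in raw.index]
        meta = pd.DataFrame({"kind": kind, "rank": ""}, index=raw.index)
    return FeatureTable(raw=raw, meta=meta)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_table(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id",
                          dtype={"disease_location": object})
    for col in ("smoking", "ppi", "laxative", "antibiotic"):
        samples[col] = samples[col].astype(bool)
    return validate_sample_table(samples)


def write_cnv_calls(cnv: CnvCallSet, path) -> None:
    out = cnv.events.copy()
    out.attrs = {}
    out.to_csv(path, sep="\t", index=False)


def read_cnv_calls(path, n_samples: int) -> CnvCallSet:
    events = pd.read_csv(path, sep="\t")
    return CnvCallSet(events=events, n_samples=n_samples)


def write_dataset(dataset, out_dir) -> dict:
    """Persist a simulated dataset; returns the file manifest.

    Emits genotypes.vcf (+ variant annotation sidecar), reference_panel.vcf,
    abundances.tsv, feature_meta.tsv, covariates.tsv, cnv_calls.tsv and a
    ground_truth.json manifest listing the config and every planted effect.
    Round-tripping through :func:`read_dataset` reproduces the in-memory
    dosage and abundance matrices exactly.
    """
    from .simulate import manifest_dict  # local import avoids a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / "genotypes.vcf",
        "variant_annotations": out_dir / "variant_annotations.tsv",
        "reference_panel": out_dir / "reference_panel.vcf",
        "abundances": out_dir / "abundances.tsv",
        "feature_meta": out_dir / "feature_meta.tsv",
        "covariates": out_dir / "covariates.tsv",
        "cnv_calls": out_dir / "cnv_calls.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_vcf(dataset.genotypes, paths["genotypes"])
    dataset.genotypes.variants[["gene", "annotation", "ibd_locus"]].to_csv(
        paths["variant_annotations"], sep="\t", index_label="variant_id"
    )
    write_vcf(dataset.reference, paths["reference_panel"])
    write_feature_table(dataset.features, paths["abundances"])
    dataset.features.meta.to_csv(paths["feature_meta"], sep="\t",
                                 index_label="feature_id")
    write_sample_table(dataset.samples, paths["covariates"])
    write_cnv_calls(dataset.cnv, paths["cnv_calls"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(manifest_dict(dataset.config), fh, indent=2, default=str)
    return {k: str(v) for k, v in paths.items()}


def read_dataset(out_dir):
    """Load a dataset written by :func:`write_dataset`."""
    from .simulate import PlantedEffect, SimulatedDataset, SimulationConfig

    out_dir = Path(out_dir)
    with open(out_dir / "ground_truth.json") as fh:
        manifest = json.load(fh)
    effects = tuple(
        PlantedEffect(**e) for e in manifest.pop("planted_effects", [])
    )
    field_names = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for k, v in manifest.items():
        if k not in field_names:
            continue
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    config = SimulationConfig(planted_effects=effects, **kwargs)
    samples = read_sample_table(out_dir / "covariates.tsv")
    genotypes = read_vcf(out_dir / "genotypes.vcf",
                         out_dir / "variant_annotations.tsv")
    reference = read_vcf(out_dir / "reference_panel.vcf",
                         out_dir / "variant_annotations.tsv")
    features = read_feature_table(out_dir / "abundances.tsv",
                                  out_dir / "feature_meta.tsv")
    cnv = read_cnv_calls(out_dir / "cnv_calls.tsv", n_samples=len(samples))
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        reference=reference,
        cnv=cnv,
        features=features,
        samples=samples,
    )
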