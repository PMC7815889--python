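"""Shared in-memory containers for the mbQTL pipeline.

The pipeline moves three kinds of data between stages:

* host genotypes as a samples x variants minor-allele dosage matrix with
  per-variant metadata (:class:`GenotypeMatrix`),
* rare copy-number events as a per-sample event table (:class:`CnvCallSet`),
* microbial relative abundances (taxa and MetaCyc pathways) together with
  their transformed and covariate-adjusted versions (:class:`FeatureTable`).

Sample-level covariates travel as a plain :class:`pandas.DataFrame` indexed
by sample id (see :data:`SAMPLE_COLUMNS`); association results travel as
DataFrames with one row per (unit, feature, cohort) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Annotation classes counted as protein-truncating variants.
PTV_CLASSES = frozenset({"stop-gain", "frameshift", "splice-disrupting"})

#: All recognised variant annotation classes.
ANNOTATION_CLASSES = frozenset(
    {"missense", "synonymous", "intron", "intergenic", "other"} | PTV_CLASSES
)

#: Cohort labels used throughout: general-population controls and IBD patients.
COHORT_POPULATION = "population"
COHORT_IBD = "IBD"

#: Disease subtypes within the IBD cohort; controls carry ``none``.
SUBTYPES = ("CD", "UC", "IBDU", "none")

#: Expected columns of the sample/covariate table (index = sample id).
SAMPLE_COLUMNS = (
    "cohort",
    "subtype",
    "age",
    "sex",
    "bmi",
    "smoking",
    "ppi",
    "laxative",
    "antibiotic",
    "read_depth",
    "disease_location",
    "inbreeding_f",
)

#: Covariates shared by both cohorts (disease location is IBD-only).
SHARED_COVARIATES = (
    "age",
    "sex",
    "bmi",
    "smoking",
    "ppi",
    "laxative",
    "antibiotic",
    "read_depth",
)

#: Variant metadata columns carried by :class:`GenotypeMatrix`.
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "annotation", "ibd_locus")


def _as_str_array(ids) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError("ids must be one-dimensional")
    return arr


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage matrix with variant metadata.

    Dosage counts copies of the minor allele: 0 for major-allele homozygotes,
    1 for heterozygotes, 2 for minor-allele homozygotes; missing genotypes
    are ``NaN``. ``variants`` is indexed by variant id and carries at least
    :data:`VARIANT_COLUMNS`; ``maf``, ``call_rate`` and (after QC) ``hwe_p``
    are populated by :meth:`recompute_stats` / the QC stage.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing (NaN)")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def sample_indexer(self, ids) -> np.ndarray:
        pos = pd.Index(self.sample_ids).get_indexer(_as_str_array(ids))
        if (pos < 0).any():
            raise KeyError("unknown sample id(s)")
        return pos

    # -- per-variant statistics -----------------------------------------
    def recompute_stats(self) -> None:
        """Refresh ``maf`` and ``call_rate`` from the dosage matrix.

        MAF is computed on non-missing genotypes pooled across all samples
        and folded to the minor allele, so it always lies in [0, 0.5].
        """
        called = np.isfinite(self.dosage)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(self.dosage, axis=0) / np.maximum(2 * n_called, 1)
        freq = np.where(n_called > 0, freq, np.nan)
        self.variants["maf"] = np.minimum(freq, 1.0 - freq)
        self.variants["call_rate"] = n_called / max(self.n_samples, 1)

    def genotype_counts(self, variant_id, sample_mask=None) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) counts for one variant."""
        j = self.variants.index.get_loc(variant_id)
        col = self.dosage[:, j] if sample_mask is None else self.dosage[sample_mask, j]
        col = col[np.isfinite(col)]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    # -- subsetting ------------------------------------------------------
    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = self.variants.index.get_indexer(pd.Index(variant_ids))
        if (idx < 0).any():
            raise KeyError("unknown variant id(s)")
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            variants=self.variants.iloc[idx].copy(),
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        pos = self.sample_indexer(sample_ids)
        out = GenotypeMatrix(
            sample_ids=self.sample_ids[pos].copy(),
            variants=self.variants.copy(),
            dosage=self.dosage[pos, :].copy(),
        )
        out.recompute_stats()
        return out

    def dosage_series(self, variant_id) -> pd.Series:
        j = self.variants.index.get_loc(variant_id)
        return pd.Series(self.dosage[:, j], index=self.sample_ids, name=variant_id)


@dataclass
class CnvCallSet:
    """Per-sample rare CNV events (gene-level deletions and duplications).

    ``events`` has columns ``sample_id``, ``gene``, ``type`` (``deletion`` or
    ``duplication``); ``n_samples`` is the cohort-wide denominator for site
    frequencies (carrier fraction per gene and type).
    """

    events: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "type"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        bad = set(self.events["type"]) - {"deletion", "duplication"}
        if bad:
            raise ValueError(f"unknown CNV type(s): {sorted(bad)}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")

    def site_frequency(self) -> pd.Series:
        """Carrier fraction per (gene, type): distinct carriers / n_samples."""
        carriers = self.events.groupby(["gene", "type"])["sample_id"].nunique()
        return carriers / self.n_samples

    def filter_by_frequency(self, max_site_freq: float = 0.01) -> "CnvCallSet":
        """Drop (gene, type) sites at or above the carrier-fraction bound."""
        if max_site_freq >= 1:
            raise ValueError("site frequency bound must be < 1")
        freq = self.site_frequency()
        keep = freq[freq < max_site_freq].index
        key = pd.MultiIndex.from_frame(self.events[["gene", "type"]])
        kept = self.events[key.isin(keep)].reset_index(drop=True)
        return CnvCallSet(events=kept, n_samples=self.n_samples)

    @property
    def genes(self) -> np.ndarray:
        return np.sort(self.events["gene"].unique())


@dataclass
class FeatureTable:
    """Microbial features (taxa + pathways) across samples.

    ``raw`` holds relative abundances in [0, 1] (rows = features, columns =
    samples); ``meta`` is indexed by feature id with columns ``kind``
    (``taxon``/``pathway``) and ``rank``. The preparation stage fills
    ``transformed`` (inverse-rank normal scores, zero mean) and ``residual``
    (covariate-adjusted scores). The non-zero mask drives the "analysis
    confined to non-zero values" restriction downstream.
    """

    raw: pd.DataFrame
    meta: pd.DataFrame
    transformed: pd.DataFrame | None = None
    residual: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.raw.index.equals(self.meta.index):
            raise ValueError("raw and meta must share the feature index")
        vals = self.raw.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        bad = set(self.meta["kind"]) - {"taxon", "pathway"}
        if bad:
            raise ValueError(f"unknown feature kind(s): {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.raw.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.raw.columns

    @property
    def nonzero(self) -> pd.DataFrame:
        return self.raw.gt(0) & self.raw.notna()

    def prevalence(self, sample_ids=None) -> pd.Series:
        """Fraction of (optionally a subset of) samples with non-zero abundance."""
        nz = self.nonzero if sample_ids is None else self.nonzero.loc[:, sample_ids]
        return nz.mean(axis=1)

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(
            raw=self.raw.loc[ids].copy(),
            meta=self.meta.loc[ids].copy(),
            transformed=None if self.transformed is None else self.transformed.loc[ids].copy(),
            residual=None if self.residual is None else self.residual.loc[ids].copy(),
            provenance=dict(self.provenance),
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        ids = pd.Index(sample_ids)
        return FeatureTable(
            raw=self.raw.loc[:, ids].copy(),
            meta=self.meta.copy(),
            transformed=None if self.transformed is None else self.transformed.loc[:, ids].copy(),
            residual=None if self.residual is None else self.residual.loc[:, ids].copy(),
            provenance=dict(self.provenance),
        )


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the covariate table contract and return it unchanged.

    Subtype must be ``none`` exactly for population controls, and the shared
    covariates must be complete for every sample.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns and c != "inbreeding_f"]
    if missing:
        raise ValueError(f"sample table lacks columns: {missing}")
    is_pop = samples["cohort"] == COHORT_POPULATION
    bad_cohort = set(samples["cohort"]) - {COHORT_POPULATION, COHORT_IBD}
    if bad_cohort:
        raise ValueError(f"unknown cohort label(s): {sorted(bad_cohort)}")
    if ((samples["subtype"] == "none") != is_pop).any():
        raise ValueError("subtype must be 'none' iff cohort is population")
    shared = samples[list(SHARED_COVARIATES)]
    if shared.isna().any().any():
        raise ValueError("shared covariates must be complete for all samples")
    return samples
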