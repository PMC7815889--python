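"""Variant- and sample-level genotype quality control.

Implements the exome QC battery applied before association testing:

* variant filters — call rate >= 0.99 and a Hardy-Weinberg exact test at
  alpha 1e-4 (computed on the control cohort, configurable),
* sample filters — ancestry outliers via PCA against a reference panel
  (outside mean +/- 3 SD on both of the first two PCs), sex mismatches from
  the X-chromosome inbreeding coefficient (female f < 0.4, male f > 0.7),
  and relatedness pruning at pi-hat > 0.185,
* partition of the surviving variants into common (MAF >= 5%) and rare
  protein-truncating (MAF < 5%) sets, plus the < 1% site-frequency CNV
  filter handled by :meth:`CnvCallSet.filter_by_frequency`.

Pi-hat values are an input (a pairwise table from upstream tooling); a
genomic-relationship estimator is provided for synthetic data only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import COHORT_POPULATION, GenotypeMatrix, PTV_CLASSES


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic variant.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows a known exact distribution over counts of the same parity;
    the two-sided p-value sums the probabilities of all heterozygote counts
    no more probable than the observed one. Monomorphic variants return
    p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_minor = 2 * n_aa + n_Aa
    n_major = 2 * n_AA + n_Aa
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0

    def log_prob(h: int) -> float:
        # P(het = h | n, allele counts) under HWE, via log-gamma
        return (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma((n_minor - h) // 2 + 1)
            - math.lgamma((n_major - h) // 2 + 1)
            + math.lgamma(n_minor + 1)
            + math.lgamma(n_major + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    logp = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Ledger of removed variants/samples and retained class counts."""

    removed_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )
    retained_counts: dict = field(default_factory=dict)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return self.removed_variants, self.removed_samples


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------

def filter_variants(
    g: GenotypeMatrix,
    call_rate_min: float = 0.99,
    hwe_alpha: float = 1e-4,
    samples: pd.DataFrame | None = None,
    hwe_on: str = "controls",
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants with call rate < ``call_rate_min`` or HWE p < ``hwe_alpha``.

    HWE is evaluated on the control cohort when a sample table is supplied
    and ``hwe_on == "controls"`` (disease can distort genotype proportions
    at trait-associated loci); pass ``hwe_on="all"`` to use every sample.
    Variants failing the call-rate rule are logged under that reason even
    if they also fail HWE.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    g = GenotypeMatrix(g.sample_ids, g.variants.copy(), g.dosage)
    g.recompute_stats()

    if samples is not None and hwe_on == "controls":
        mask = (samples.loc[pd.Index(g.sample_ids), "cohort"]
                == COHORT_POPULATION).to_numpy()
    else:
        mask = np.ones(g.n_samples, dtype=bool)

    hwe_p = np.empty(g.n_variants)
    sub = g.dosage[mask, :]
    for j in range(g.n_variants):
        col = sub[:, j]
        col = col[np.isfinite(col)]
        hwe_p[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    g.variants["hwe_p"] = hwe_p

    call_fail = g.variants["call_rate"].to_numpy() < call_rate_min
    hwe_fail = hwe_p < hwe_alpha
    reasons = []
    for vid, cf, hf in zip(g.variants.index, call_fail, hwe_fail):
        if cf:
            reasons.append((vid, "call_rate"))
        elif hf:
            reasons.append((vid, "hwe"))
    removed = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    keep = ~(call_fail | hwe_fail)
    filtered = g.subset_variants(g.variants.index[keep])
    report = QcReport(
        removed_variants=removed,
        retained_counts={"variants": int(keep.sum())},
    )
    return filtered, report


# ---------------------------------------------------------------------------
# sample filters
# ---------------------------------------------------------------------------

def pca_outlier_flags(
    g: GenotypeMatrix,
    reference: GenotypeMatrix,
    k_sd: float = 3.0,
) -> pd.Series:
    """Flag ancestry outliers by PCA against a reference panel.

    Study and reference dosages are merged over shared variants,
    mean-imputed, standardized to unit variance per variant, and projected
    onto the first two principal components. A study sample is flagged only
    if it lies outside mean +/- ``k_sd`` SD on *both* PCs, with the mean and
    SD taken over the study samples.
    """
    shared = g.variants.index.intersection(reference.variants.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared variants for PCA")
    study = g.subset_variants(shared).dosage
    panel = reference.subset_variants(shared).dosage
    merged = np.vstack([study, panel])
    col_mean = np.nanmean(merged, axis=0)
    inds = np.where(np.isnan(merged))
    merged[inds] = np.take(col_mean, inds[1])
    sd = merged.std(axis=0)
    sd[sd == 0] = 1.0
    merged = (merged - merged.mean(axis=0)) / sd
    pcs = PCA(n_components=2, svd_solver="randomized",
              random_state=0).fit_transform(merged)
    study_pcs = pcs[: g.n_samples]
    mean = study_pcs.mean(axis=0)
    sd = study_pcs.std(axis=0)
    out = np.abs(study_pcs - mean) > k_sd * sd
    return pd.Series(out[:, 0] & out[:, 1], index=g.sample_ids, name="pca_outlier")


def sex_check(f_coefficient: float, reported_sex: str) -> str:
    """Compare the X inbreeding coefficient with the reported sex.

    Females pass only with f strictly below 0.4, males only with f strictly
    above 0.7; boundary values and the intermediate band are mismatches.
    """
    if not -1.0 <= f_coefficient <= 1.0:
        raise ValueError("inbreeding coefficient must lie in [-1, 1]")
    if reported_sex == "female":
        return "pass" if f_coefficient < 0.4 else "mismatch"
    if reported_sex == "male":
        return "pass" if f_coefficient > 0.7 else "mismatch"
    raise ValueError(f"unknown sex label {reported_sex!r}")


def sex_check_samples(samples: pd.DataFrame) -> pd.Series:
    """Vectorized sex check over a sample table (needs ``inbreeding_f``)."""
    flags = [
        sex_check(f, s) == "mismatch"
        for f, s in zip(samples["inbreeding_f"], samples["sex"])
    ]
    return pd.Series(flags, index=samples.index, name="sex_mismatch")


def relatedness_prune(
    pairwise_pihat: pd.DataFrame,
    call_rates: pd.Series,
    threshold: float = 0.185,
) -> set[str]:
    """Greedy removal set leaving no pair with pi-hat > ``threshold``.

    Repeatedly removes the sample appearing in the most over-threshold
    pairs; ties break to the lower genotyping call rate, then to the
    lexicographically later sample id. The pi-hat table has columns
    ``id1``, ``id2``, ``pihat``.
    """
    if not {"id1", "id2", "pihat"}.issubset(pairwise_pihat.columns):
        raise ValueError("pi-hat table needs columns id1, id2, pihat")
    if ((pairwise_pihat["pihat"] < 0) | (pairwise_pihat["pihat"] > 1)).any():
        raise ValueError("pi-hat values must lie in [0, 1]")
    pairs = [
        (a, b)
        for a, b, p in pairwise_pihat[["id1", "id2", "pihat"]].itertuples(index=False)
        if p > threshold
    ]
    removed: set[str] = set()
    while True:
        live = [(a, b) for a, b in pairs if a not in removed and b not in removed]
        if not live:
            return removed
        counts: dict[str, int] = {}
        for a, b in live:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        # most pairs first; then lower call rate; then later id
        victim = max(
            counts,
            key=lambda s: (counts[s], -float(call_rates.get(s, 1.0)), s),
        )
        removed.add(victim)


def estimate_pihat(g: GenotypeMatrix, min_maf: float = 0.05) -> pd.DataFrame:
    """Genomic-relationship (method-of-moments) pi-hat for synthetic data.

    Averages allele-frequency-standardized dosage products across variants,
    giving ~0 for unrelated pairs, ~0.5 for first-degree relatives and ~1
    for duplicates. Intended only to produce the pairwise table consumed by
    :func:`relatedness_prune` when simulating; real studies supply pi-hat
    from dedicated IBD tooling.
    """
    keep = g.variants["maf"].to_numpy() >= min_maf
    dosage = g.dosage[:, keep]
    freq = np.nanmean(dosage, axis=0) / 2.0
    centred = dosage - 2 * freq[None, :]
    centred = np.where(np.isfinite(centred), centred, 0.0)
    denom = 2 * freq * (1 - freq)
    z = centred / np.sqrt(denom)[None, :]
    grm = z @ z.T / z.shape[1]
    ids = g.sample_ids
    rows = [
        (ids[i], ids[j], float(np.clip(grm[i, j], 0.0, 1.0)))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    return pd.DataFrame(rows, columns=["id1", "id2", "pihat"])


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def partition_by_maf(
    g: GenotypeMatrix, maf_cut: float = 0.05
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split post-QC variants into common and rare-PTV sets.

    Common: MAF >= ``maf_cut`` (the boundary value counts as common).
    Rare PTV: MAF < ``maf_cut`` and a protein-truncating annotation
    (stop-gain, frameshift, splice-disrupting); rare non-PTVs enter
    neither set, matching the burden stage's input definition.
    """
    maf = g.variants["maf"].to_numpy()
    is_ptv = g.variants["annotation"].isin(PTV_CLASSES).to_numpy()
    common = g.subset_variants(g.variants.index[maf >= maf_cut])
    rare_ptv = g.subset_variants(g.variants.index[(maf < maf_cut) & is_ptv])
    return common, rare_ptv


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_sample_qc(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    reference: GenotypeMatrix,
    pihat: pd.DataFrame | None = None,
    k_sd: float = 3.0,
    pihat_threshold: float = 0.185,
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Apply PCA-outlier, sex-mismatch and relatedness filters in order."""
    pca_flags = pca_outlier_flags(g, reference, k_sd=k_sd)
    sex_flags = sex_check_samples(samples.loc[pd.Index(g.sample_ids)])
    removed = [(s, "pca_outlier") for s in pca_flags.index[pca_flags]]
    removed += [
        (s, "sex_mismatch")
        for s in sex_flags.index[sex_flags]
        if not pca_flags.get(s, False)
    ]
    dropped = {s for s, _ in removed}
    if pihat is not None:
        call_rates = pd.Series(
            np.isfinite(g.dosage).mean(axis=1), index=g.sample_ids
        )
        live = pihat[~pihat["id1"].isin(dropped) & ~pihat["id2"].isin(dropped)]
        related = relatedness_prune(live, call_rates, threshold=pihat_threshold)
        removed += [(s, "relatedness") for s in sorted(related)]
        dropped |= related
    keep = [s for s in g.sample_ids if s not in dropped]
    g_clean = g.subset_samples(keep)
    report = QcReport(
        removed_samples=pd.DataFrame(removed, columns=["sample_id", "reason"]),
        retained_counts={"samples": len(keep)},
    )
    return g_clean, samples.loc[pd.Index(keep)], report
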