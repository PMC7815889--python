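"""Disease x genotype interaction analysis with permutation calibration.

mbQTLs seen in only one cohort may be disease-dependent. For each such
candidate the two cohorts are pooled and the transformed abundance is
modelled (non-zero samples only) as

    feature ~ genotype + disease + genotype x disease + shared covariates

by ordinary least squares. The interaction coefficient carries an
asymptotic two-sided p and an empirical p calibrated by permuting the
disease label across all pooled samples (999 permutations by default,
add-one estimator), which guards the asymptotic p against inflation from
the zero-inflated, selected nature of the candidates. A recessive genotype
coding and CD/UC subgroup re-analyses cover the corresponding secondary
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import COHORT_IBD, FeatureTable, GenotypeMatrix
from .features import build_design
from .meta import bonferroni_threshold

from scipy import stats as _stats


@dataclass
class InteractionResult:
    """Joint-cohort interaction fit for one (unit, feature) pair."""

    unit: str
    feature: str
    beta_genotype: float
    beta_disease: float
    beta_interaction: float
    p_interaction: float
    p_empirical: float | None
    n_permutations: int
    n_used: int
    candidate_origin: str = ""
    untestable: bool = False


def genotype_recode(dosage, model: str = "additive") -> np.ndarray:
    """Additive (identity) or recessive (hom-minor vs rest) genotype coding.

    Recessive coding contrasts minor-allele homozygotes (dosage 2 -> 1)
    against every other called genotype; missing stays missing.
    """
    d = np.asarray(dosage, dtype=float)
    if model == "additive":
        return d.copy()
    if model == "recessive":
        out = np.where(d == 2, 1.0, 0.0)
        return np.where(np.isfinite(d), out, np.nan)
    raise ValueError(f"unknown genotype model {model!r}")


def select_interaction_candidates(
    primary: pd.DataFrame,
    swapped: pd.DataFrame,
    discovery_p_max: float,
    replication_p_min: float = 0.05,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Single-cohort-significant pairs from the two selection runs.

    A candidate reaches the stage's discovery cutoff in exactly one cohort
    while failing replication (p > ``replication_p_min``) in the other;
    both two-stage tables (primary and cohort-swapped) are scanned so each
    cohort gets a turn as discovery. Returns the candidate table, labelled
    with the cohort the signal is specific to, and the Bonferroni
    interaction threshold alpha / n_candidates.
    """
    frames = []
    for tab in (primary, swapped):
        if tab.empty:
            continue
        hit = tab[
            (tab["p_disc"] < discovery_p_max)
            & (tab["p_rep"] > replication_p_min)
        ].copy()
        hit["candidate_origin"] = hit["discovery_cohort"].map(
            lambda c: f"{c}_specific"
        )
        frames.append(hit)
    if not frames:
        empty = pd.DataFrame(columns=["unit", "feature", "candidate_origin"])
        return empty, np.nan
    cand = pd.concat(frames, ignore_index=True)
    cand = cand.drop_duplicates(subset=["unit", "feature"]).reset_index(drop=True)
    threshold = bonferroni_threshold(alpha, len(cand)) if len(cand) else np.nan
    return cand, threshold


def _standardize_cols(X: np.ndarray) -> np.ndarray:
    """Z-score covariate columns; rescaling them leaves the genotype,
    disease and interaction coefficients untouched but keeps X'X well
    conditioned (read depth is ~1e7 on its raw scale)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def _interaction_design(g, d, covariates) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(g)), g, d, g * d, X])


def interaction_test(
    abundance,
    dosage,
    disease,
    covariates,
    nonzero_mask=None,
    unit: str = "",
    feature: str = "",
    candidate_origin: str = "",
) -> InteractionResult:
    """OLS interaction fit on the pooled cohorts, non-zero samples only.

    Collinearity of the interaction column (e.g. the minor allele present
    in one disease group only) makes the pair untestable; so do constant
    genotype or disease vectors after masking.
    """
    y = np.asarray(abundance, dtype=float)
    g = np.asarray(dosage, dtype=float)
    d = np.asarray(disease, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mask = np.isfinite(y) & np.isfinite(g) & np.isfinite(d)
    mask &= np.isfinite(X).all(axis=1)
    if nonzero_mask is not None:
        mask &= np.asarray(nonzero_mask, dtype=bool)
    y, g, d, X = y[mask], g[mask], d[mask], _standardize_cols(X[mask])
    n = len(y)

    def _untestable() -> InteractionResult:
        return InteractionResult(unit, feature, np.nan, np.nan, np.nan,
                                 np.nan, None, 0, n, candidate_origin,
                                 untestable=True)

    if n < 10 or len(np.unique(g)) < 2 or len(np.unique(d)) < 2:
        return _untestable()
    exog = _interaction_design(g, d, X)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        return _untestable()
    beta, t_p = _ols_term(exog, y, term=3)
    bg, _ = _ols_term(exog, y, term=1)
    bd, _ = _ols_term(exog, y, term=2)
    return InteractionResult(
        unit, feature,
        beta_genotype=bg, beta_disease=bd, beta_interaction=beta,
        p_interaction=t_p, p_empirical=None, n_permutations=0,
        n_used=n, candidate_origin=candidate_origin,
    )


def _ols_term(exog: np.ndarray, y: np.ndarray, term: int) -> tuple[float, float]:
    """Coefficient and two-sided t-test p for one design column."""
    n, k = exog.shape
    xtx_inv = np.linalg.inv(exog.T @ exog)
    beta = xtx_inv @ (exog.T @ y)
    resid = y - exog @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(sigma2 * xtx_inv[term, term])
    t = beta[term] / se if se > 0 else np.nan
    p = float(2 * _stats.t.sf(abs(t), df=n - k)) if np.isfinite(t) else np.nan
    return float(beta[term]), p


def permutation_calibration(
    abundance,
    dosage,
    disease,
    covariates,
    nonzero_mask=None,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    unit: str = "",
    feature: str = "",
    candidate_origin: str = "",
) -> InteractionResult:
    """Empirical interaction p by permuting the disease label.

    Disease status is shuffled across all pooled samples while genotype,
    abundance and covariates stay fixed (so covariate-genotype linkage is
    preserved); the permutation statistic is |beta_interaction| and the
    empirical p uses the add-one estimator
    (1 + #{|beta_perm| >= |beta_obs|}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = interaction_test(abundance, dosage, disease, covariates,
                           nonzero_mask, unit, feature, candidate_origin)
    if obs.untestable:
        return obs

    y = np.asarray(abundance, dtype=float)
    g = np.asarray(dosage, dtype=float)
    d = np.asarray(disease, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mask = np.isfinite(y) & np.isfinite(g) & np.isfinite(d)
    mask &= np.isfinite(X).all(axis=1)
    if nonzero_mask is not None:
        mask &= np.asarray(nonzero_mask, dtype=bool)
    y, g, d, X = y[mask], g[mask], d[mask], _standardize_cols(X[mask])

    exceed = 0
    for _ in range(n_permutations):
        d_perm = rng.permutation(d)
        exog = _interaction_design(g, d_perm, X)
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            exceed += 1  # conservatively count degenerate permutations
            continue
        b, _ = _ols_term(exog, y, term=3)
        if abs(b) >= abs(obs.beta_interaction) - 1e-300:
            exceed += 1
    p_emp = (1 + exceed) / (n_permutations + 1)
    return InteractionResult(
        obs.unit, obs.feature, obs.beta_genotype, obs.beta_disease,
        obs.beta_interaction, obs.p_interaction, p_emp, n_permutations,
        obs.n_used, candidate_origin,
    )


def subgroup_analysis(
    genotypes: GenotypeMatrix,
    features: FeatureTable,
    samples: pd.DataFrame,
    subtype: str,
    scan_fn,
    min_subtype_n: int = 20,
):
    """Re-run an association scan with the IBD cohort restricted to CD or UC.

    ``scan_fn(genotypes, features, samples)`` is any per-cohort association
    driver (e.g. a closure over :func:`mbqtl.assoc.mbqtl_scan`); patients
    outside the requested subtype (including IBDU) are dropped while the
    population cohort is kept intact.
    """
    if subtype not in ("CD", "UC"):
        raise ValueError("subgroup analyses cover CD and UC only")
    keep = (samples["cohort"] != COHORT_IBD) | (samples["subtype"] == subtype)
    sub = samples[keep]
    n_sub = int((sub["subtype"] == subtype).sum())
    if n_sub == 0:
        raise ValueError(f"no samples with subtype {subtype}")
    if n_sub < min_subtype_n:
        raise ValueError(
            f"only {n_sub} {subtype} samples (minimum {min_subtype_n})"
        )
    ids = sub.index
    g = genotypes.subset_samples(ids)
    f = features.subset_samples(ids)
    return scan_fn(g, f, sub)


def interaction_design_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Shared-covariate design for the pooled interaction model.

    Disease location is undefined for controls and therefore dropped; all
    other covariates are shared between cohorts.
    """
    return build_design(samples, include_location=False)
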