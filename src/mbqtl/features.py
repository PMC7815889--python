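"""Microbiome feature preparation: prevalence filtering, inverse-rank
normalization and covariate residualization.

The association stages consume covariate-adjusted normal scores of the
relative abundances. Preparation proceeds per cohort, in a fixed order:

1. prevalence filter — taxa present in >= 10% and pathways in >= 25% of a
   cohort's samples, with the analysis set restricted to features passing
   in *both* cohorts;
2. inverse-rank (Blom) transform over all retained samples of the cohort,
   zeros included (they tie at the bottom rank);
3. ordinary-least-squares residualization on the nine covariates (age,
   sex, BMI, smoking, PPI/laxative/antibiotic use, read depth, and disease
   location within the IBD cohort only).

The zero/non-zero mask of the *raw* abundances is preserved so downstream
association tests can confine themselves to non-zero samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COHORT_IBD, FeatureTable, SHARED_COVARIATES


def prevalence_filter(
    features: FeatureTable,
    samples: pd.DataFrame,
    taxon_min: float = 0.10,
    pathway_min: float = 0.25,
) -> FeatureTable:
    """Keep features meeting the kind-specific prevalence in every cohort.

    A taxon present in fewer than ``taxon_min`` (default 10%) of a cohort's
    samples, or a pathway in fewer than ``pathway_min`` (default 25%), is
    dropped; the returned set is the intersection across cohorts so every
    retained feature is analyzable in both. An empty result warns rather
    than raises.
    """
    kinds = features.meta["kind"]
    threshold = kinds.map({"taxon": taxon_min, "pathway": pathway_min})
    keep = pd.Series(True, index=features.feature_ids)
    for _, cohort_samples in samples.groupby("cohort", observed=True):
        prev = features.prevalence(cohort_samples.index)
        keep &= prev >= threshold
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return features.subset_features(features.feature_ids[keep])


def inverse_rank_transform(values, offset: float = 0.375) -> np.ndarray:
    """Blom inverse-rank normal scores, mean-centered.

    Maps value i to ``ppf((rank_i - offset) / (n + 1 - 2*offset))`` with
    average ranks for ties (the default offset 3/8 gives the classical
    Blom scores). Scores are centered to exact zero mean afterwards: with
    ties the raw Blom scores of average ranks are not symmetric, and a
    zero-mean transformed scale is part of the table contract. Missing
    values pass through as NaN; fewer than two distinct values is a
    degenerate ranking and raises.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if len(np.unique(x[ok])) < 2:
        raise ValueError("need at least 2 distinct non-missing values to rank")
    ranks = stats.rankdata(x[ok], method="average")
    scores = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    out[ok] = scores - scores.mean()
    return out


def build_design(
    samples: pd.DataFrame,
    include_location: bool = False,
    covariates: tuple[str, ...] = SHARED_COVARIATES,
) -> pd.DataFrame:
    """Numeric covariate design matrix (no intercept column).

    Sex is coded female=1; binary medication flags as 0/1; disease
    location, when requested (IBD-cohort models), is one-hot encoded with
    the first category dropped.
    """
    cols = {}
    for name in covariates:
        col = samples[name]
        if name == "sex":
            cols["sex_female"] = (col == "female").astype(float)
        else:
            cols[name] = col.astype(float)
    design = pd.DataFrame(cols, index=samples.index)
    if include_location:
        loc = pd.get_dummies(samples["disease_location"], prefix="loc",
                             drop_first=True, dtype=float)
        design = pd.concat([design, loc], axis=1)
    return design


def residualize(values, design: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus the design columns.

    Rank-deficient designs are tolerated (least-squares projection is
    unique even when coefficients are not) with a warning about aliased
    columns. Samples with a missing response are returned as NaN and
    excluded from the fit.
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(len(y)), X])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    # unit-norm columns: projection is scale-invariant and the rank test
    # must not be dominated by large-scale covariates (read depth)
    norms = np.linalg.norm(X[ok], axis=0)
    norms[norms == 0] = 1.0
    X = X / norms
    rank = np.linalg.matrix_rank(X[ok])
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank deficient ({rank} < {X.shape[1]}); "
            "aliased columns contribute nothing to the projection",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out = np.full(y.shape, np.nan)
    out[ok] = y[ok] - X[ok] @ beta
    return out


def prepare_features(
    features: FeatureTable,
    samples: pd.DataFrame,
    taxon_min: float = 0.10,
    pathway_min: float = 0.25,
    blom_offset: float = 0.375,
    log_read_depth: bool = False,
) -> FeatureTable:
    """Run the full preparation pipeline per cohort.

    Returns a new table with ``transformed`` (within-cohort Blom scores)
    and ``residual`` (scores adjusted for the nine covariates; disease
    location enters the IBD cohort's model only). Read depth is used
    untransformed unless ``log_read_depth`` is set.
    """
    table = prevalence_filter(features, samples, taxon_min, pathway_min)
    transformed = pd.DataFrame(
        np.nan, index=table.feature_ids, columns=table.sample_ids
    )
    residual = transformed.copy()
    covs = samples.copy()
    if log_read_depth:
        covs["read_depth"] = np.log10(covs["read_depth"])
    for cohort, cohort_samples in covs.groupby("cohort", observed=True):
        ids = cohort_samples.index
        design = build_design(cohort_samples,
                              include_location=(cohort == COHORT_IBD))
        raw = table.raw.loc[:, ids].to_numpy()
        for i in range(raw.shape[0]):
            t = inverse_rank_transform(raw[i], offset=blom_offset)
            transformed.loc[table.feature_ids[i], ids] = t
            residual.loc[table.feature_ids[i], ids] = residualize(t, design)
    out = FeatureTable(
        raw=table.raw, meta=table.meta,
        transformed=transformed, residual=residual,
        provenance={
            **table.provenance,
            "transform": f"blom(offset={blom_offset}), per cohort, zeros included",
            "residualized_on": list(SHARED_COVARIATES) + ["disease_location (IBD only)"],
        },
    )
    return out
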