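"""Per-cohort association engines.

Three test families feed the pipeline:

* :func:`spearman_assoc` — the mbQTL workhorse: Spearman rank correlation
  between minor-allele dosage and the covariate-adjusted abundance,
  confined to samples whose *raw* abundance is non-zero;
* :func:`case_control_feature_test` — OLS of transformed abundance on
  disease status plus shared covariates (which taxa/pathways differ
  between patients and controls);
* :func:`case_control_variant_test` — additive logistic regression of
  disease on dosage adjusted for age, sex and smoking (the case-control
  genetic signature).

Pairs that are untestable (too few non-zero samples, constant dosage or
abundance, perfect separation) are flagged rather than silently dropped so
multiple-testing denominators can exclude them explicitly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import FeatureTable, GenotypeMatrix


@dataclass
class AssocResult:
    """One association test: unit (variant or gene) x feature x cohort."""

    unit: str
    feature: str
    cohort: str
    stat_kind: str  # spearman_rho | linear_beta | logistic_or
    estimate: float
    p: float
    n_used: int
    direction: int
    untestable: bool = False
    extra: dict | None = None


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho by full enumeration.

    Enumerates all n! orderings of one ranking (feasible for n <= 9); the
    p-value is the fraction of permutations whose |rho| reaches the
    observed |rho|, ties in magnitude counted as extreme.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rho_obs = abs(_rank_corr(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = abs(_rank_corr(rx, ry[list(perm)]))
        count += rho >= rho_obs - 1e-12
        total += 1
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom) if denom > 0 else np.nan


def spearman_assoc(
    dosage,
    abundance,
    nonzero_mask=None,
    unit: str = "",
    feature: str = "",
    cohort: str = "",
    min_n: int = 10,
    method: str = "t",
) -> AssocResult:
    """Spearman correlation between dosage and (residualized) abundance.

    The test is confined to samples that are non-zero in the raw abundance
    (``nonzero_mask``) and have a called genotype. ``method="t"`` uses the
    t-distribution approximation for the two-sided p; ``method="exact"``
    enumerates all rank permutations (n <= 9 only — available below the
    default ``min_n``). Pairs with fewer than ``min_n`` usable samples or a
    constant vector are flagged untestable.
    """
    d = np.asarray(dosage, dtype=float)
    a = np.asarray(abundance, dtype=float)
    mask = np.isfinite(d) & np.isfinite(a)
    if nonzero_mask is not None:
        mask &= np.asarray(nonzero_mask, dtype=bool)
    d, a = d[mask], a[mask]
    n = len(d)

    def _untestable() -> AssocResult:
        return AssocResult(unit, feature, cohort, "spearman_rho",
                           np.nan, np.nan, n, 0, untestable=True)

    if n < min_n or len(np.unique(d)) < 2 or len(np.unique(a)) < 2:
        return _untestable()
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p is limited to n <= 9")
        rho = _rank_corr(stats.rankdata(d), stats.rankdata(a))
        p = _spearman_exact_p(d, a)
    else:
        rho, p = stats.spearmanr(d, a)
    if not np.isfinite(rho):
        return _untestable()
    return AssocResult(
        unit, feature, cohort, "spearman_rho",
        float(rho), float(p), n, int(np.sign(rho)),
    )


def mbqtl_scan(
    genotypes: GenotypeMatrix,
    features: FeatureTable,
    samples: pd.DataFrame,
    cohort: str,
    variant_ids=None,
    min_n: int = 10,
) -> pd.DataFrame:
    """All variant x feature Spearman tests within one cohort.

    Uses the residualized abundance values and the raw-abundance non-zero
    mask; returns one row per pair with the usual AssocResult columns plus
    an ``untestable`` flag.
    """
    if features.residual is None:
        raise ValueError("features must be prepared (residual values missing)")
    ids = samples.index[samples["cohort"] == cohort]
    ids = ids.intersection(pd.Index(genotypes.sample_ids))
    g = genotypes.subset_samples(ids)
    resid = features.residual.loc[:, ids].to_numpy()
    nonzero = features.nonzero.loc[:, ids].to_numpy()
    variant_ids = genotypes.variant_ids if variant_ids is None else pd.Index(variant_ids)
    rows = []
    for vid in variant_ids:
        dos = g.dosage[:, g.variants.index.get_loc(vid)]
        for i, fid in enumerate(features.feature_ids):
            r = spearman_assoc(
                dos, resid[i], nonzero[i],
                unit=vid, feature=fid, cohort=cohort, min_n=min_n,
            )
            rows.append((r.unit, r.feature, r.cohort, r.estimate, r.p,
                         r.n_used, r.direction, r.untestable))
    return pd.DataFrame(
        rows,
        columns=["unit", "feature", "cohort", "estimate", "p",
                 "n_used", "direction", "untestable"],
    )


def case_control_feature_test(
    abundance,
    disease,
    design: pd.DataFrame | np.ndarray,
    feature: str = "",
    n_tests: int = 1,
) -> AssocResult:
    """OLS of transformed abundance on disease status plus covariates.

    ``estimate`` is the disease coefficient on the transformed scale; the
    Bonferroni-adjusted p (``min(1, p * n_tests)``) rides along in
    ``extra``. A constant disease indicator is degenerate and raises.
    """
    y = np.asarray(abundance, dtype=float)
    d = np.asarray(disease, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(y) & np.isfinite(d) & np.isfinite(X).all(axis=1)
    y, d, X = y[ok], d[ok], X[ok]
    if len(np.unique(d)) < 2:
        raise ValueError("disease indicator is constant")
    exog = np.column_stack([np.ones(len(y)), d, X])
    fit = sm.OLS(y, exog).fit()
    beta, p = float(fit.params[1]), float(fit.pvalues[1])
    return AssocResult(
        "disease", feature, "pooled", "linear_beta", beta, p, len(y),
        int(np.sign(beta)) if beta else 0,
        extra={"adjusted_p": min(1.0, p * n_tests)},
    )


def case_control_variant_test(
    dosage,
    disease,
    design: pd.DataFrame | np.ndarray,
    unit: str = "",
) -> AssocResult:
    """Additive logistic regression of disease on minor-allele dosage.

    ``estimate`` is the odds ratio per minor allele with a Wald two-sided
    p. Complete (or quasi-complete) separation is flagged untestable with
    the p left missing instead of reporting a meaningless Wald statistic.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(disease, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(d) & np.isfinite(y) & np.isfinite(X).all(axis=1)
    d, y, X = d[ok], y[ok], X[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if len(np.unique(d)) < 2:
        return AssocResult(unit, "", "pooled", "logistic_or",
                           np.nan, np.nan, len(d), 0, untestable=True)
    exog = np.column_stack([np.ones(len(d)), d, X])
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, exog).fit(disp=False, maxiter=200)
        except Exception:
            separated = True
    if not separated:
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        # runaway estimates betray separation the optimizer survived
        separated = not np.isfinite(se) or abs(beta) > 15
    if separated:
        return AssocResult(unit, "", "pooled", "logistic_or",
                           np.nan, np.nan, len(d), 0, untestable=True)
    return AssocResult(
        unit, "", "pooled", "logistic_or",
        float(np.exp(beta)), float(fit.pvalues[1]), len(d),
        int(np.sign(beta)) if beta else 0,
        extra={"log_or": beta, "se": se},
    )
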