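"""Two-cohort discovery/replication selection and weighted-Z meta-analysis.

The mbQTL design tests every (variant, feature) pair in a discovery cohort,
carries signals below a discovery p cutoff into the second cohort, keeps
only pairs replicating with the same allelic direction at p < 0.05, and
combines the two cohorts with a signed Stouffer weighted-Z statistic using
square-root sample-size weights:

    z_i = sign_i * Phi^-1(1 - p_i / 2),   w_i = sqrt(n_i)
    z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)),   p_meta = 2 * (1 - Phi(|z_meta|))

Significance cutoffs are Bonferroni: alpha / n_tests, with n_tests the
number of units in the stage (73 164 exome-wide variants gives the familiar
6.83e-7 cutoff at alpha 0.05). The "FDR" reported alongside is the
Bonferroni-adjusted meta p, min(1, p_meta * n_tests). Every stage is also
run with the cohorts swapped; pairs significant in exactly one cohort feed
the disease-interaction stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PTV_CLASSES, GenotypeMatrix


@dataclass(frozen=True)
class StageThresholds:
    """Discovery/replication/meta cutoffs for one analysis stage."""

    p_discovery_max: float
    p_replication_max: float
    n_tests: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be at least 1")
        for v in (self.p_discovery_max, self.p_replication_max, self.alpha):
            if not 0 < v <= 1:
                raise ValueError("thresholds must lie in (0, 1]")

    @property
    def p_meta_max(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)


#: Stage presets from the emulated study design (discovery p, replication p).
EXOME_WIDE = lambda n_tests: StageThresholds(5e-5, 0.05, n_tests)  # noqa: E731
TARGETED = lambda n_tests: StageThresholds(0.001, 0.05, n_tests)  # noqa: E731
BURDEN_PTV = lambda n_tests: StageThresholds(0.005, 0.05, n_tests)  # noqa: E731
BURDEN_CNV = lambda n_tests: StageThresholds(0.05, 0.05, n_tests)  # noqa: E731


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def signed_z_from_p(p_two_sided: float, direction: int) -> float:
    """Signed z-score from a two-sided p and an effect direction.

    Uses z = sign * Phi^-1(1 - p/2); a two-sided p of 1 maps to z = 0.
    Zero p-values are rejected — the caller must clamp at its numerical
    floor before combining.
    """
    if not 0 < p_two_sided <= 1:
        raise ValueError("p must lie in (0, 1]; clamp zero p upstream")
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    return float(direction * stats.norm.isf(p_two_sided / 2.0))


@dataclass(frozen=True)
class MetaStat:
    z: float
    p: float
    direction: int


def weighted_z_meta(results) -> MetaStat:
    """Stouffer weighted-Z combination of per-cohort (p, direction, n).

    Weights are sqrt(n); with equal n this reduces to the classical
    unweighted Stouffer statistic. Directions must be +/-1 for every
    cohort and every n positive.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least two cohorts to meta-analyse")
    zs, ws = [], []
    for p, direction, n in results:
        if n <= 0:
            raise ValueError("cohort n must be positive")
        zs.append(signed_z_from_p(p, direction))
        ws.append(np.sqrt(n))
    zs, ws = np.asarray(zs), np.asarray(ws)
    z = float(ws @ zs / np.sqrt((ws**2).sum()))
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaStat(z=z, p=max(p, 5e-324), direction=int(np.sign(z)) or 1)


def two_stage_select(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    thresholds: StageThresholds,
    discovery_label: str = "discovery",
    replication_label: str = "replication",
    weight_mode: str = "n_used",
    cohort_sizes: dict | None = None,
) -> pd.DataFrame:
    """Discovery -> replication -> meta pipeline over (unit, feature) pairs.

    ``discovery``/``replication`` are association tables (columns ``unit``,
    ``feature``, ``p``, ``direction``, ``n_used``, ``untestable``) from the
    same test family in the two cohorts. Gates, applied with strict
    inequalities: discovery p < ``p_discovery_max``; replication p <
    ``p_replication_max`` with the same direction; meta p < alpha/n_tests.
    Pairs untestable in either cohort, or present in only one, are skipped.

    Weights use the per-test ``n_used`` by default; ``weight_mode="cohort"``
    substitutes full cohort sizes from ``cohort_sizes`` keyed by the labels.
    Returns the merged table with per-gate flags and meta statistics for
    every pair that reached the replication stage; the selected set is
    ``table[table.selected]``.
    """
    key = ["unit", "feature"]
    d = discovery[~discovery["untestable"].astype(bool)]
    r = replication[~replication["untestable"].astype(bool)]
    merged = d.merge(r, on=key, suffixes=("_disc", "_rep"), how="inner")
    merged = merged[merged["p_disc"] < thresholds.p_discovery_max].copy()
    if merged.empty:
        return _empty_meta_table(discovery_label, replication_label)

    same_dir = merged["direction_disc"] == merged["direction_rep"]
    rep_ok = merged["p_rep"] < thresholds.p_replication_max
    merged["passed_replication"] = (same_dir & rep_ok).to_numpy()

    if weight_mode == "cohort":
        if not cohort_sizes:
            raise ValueError("cohort weight mode needs cohort_sizes")
        n_disc = np.full(len(merged), cohort_sizes[discovery_label])
        n_rep = np.full(len(merged), cohort_sizes[replication_label])
    else:
        n_disc = merged["n_used_disc"].to_numpy()
        n_rep = merged["n_used_rep"].to_numpy()

    stats_ = [
        weighted_z_meta(
            [(pd_, int(dd), nd), (pr_, int(dr), nr)]
        )
        for pd_, dd, nd, pr_, dr, nr in zip(
            merged["p_disc"], merged["direction_disc"], n_disc,
            merged["p_rep"], merged["direction_rep"], n_rep,
        )
    ]
    merged["z_meta"] = [s.z for s in stats_]
    merged["p_meta"] = [s.p for s in stats_]
    merged["direction_meta"] = [s.direction for s in stats_]
    merged["adjusted_p"] = np.minimum(1.0, merged["p_meta"] * thresholds.n_tests)
    merged["passed_meta"] = (merged["p_meta"] < thresholds.p_meta_max).to_numpy()
    merged["selected"] = merged["passed_replication"] & merged["passed_meta"]
    merged["discovery_cohort"] = discovery_label
    merged["replication_cohort"] = replication_label
    merged["n_tests"] = thresholds.n_tests
    return merged.sort_values(["unit", "feature"]).reset_index(drop=True)


def _empty_meta_table(discovery_label, replication_label) -> pd.DataFrame:
    cols = [
        "unit", "feature", "estimate_disc", "p_disc", "n_used_disc",
        "direction_disc", "estimate_rep", "p_rep", "n_used_rep",
        "direction_rep", "passed_replication", "z_meta", "p_meta",
        "direction_meta", "adjusted_p", "passed_meta", "selected",
        "discovery_cohort", "replication_cohort", "n_tests",
    ]
    out = pd.DataFrame(columns=cols)
    out["discovery_cohort"] = out["discovery_cohort"].astype(object)
    return out


def run_both_directions(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    thresholds: StageThresholds,
    label_a: str,
    label_b: str,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Primary and cohort-swapped two-stage runs.

    ``primary`` uses cohort A for discovery; ``swapped`` repeats the
    selection with discovery and replication cohorts exchanged.
    """
    return {
        "primary": two_stage_select(results_a, results_b, thresholds,
                                    label_a, label_b, **kwargs),
        "swapped": two_stage_select(results_b, results_a, thresholds,
                                    label_b, label_a, **kwargs),
    }


def targeted_variant_set(g: GenotypeMatrix, maf_cut: float = 0.05) -> pd.Index:
    """Variants for the targeted stage: common PTVs plus common IBD-locus hits.

    The union of (a) protein-truncating variants with MAF >= ``maf_cut``
    and (b) variants with MAF >= ``maf_cut`` inside known IBD-associated
    loci; the stage's Bonferroni denominator is the union size.
    """
    maf = g.variants["maf"].to_numpy()
    common = maf >= maf_cut
    is_ptv = g.variants["annotation"].isin(PTV_CLASSES).to_numpy()
    in_locus = g.variants["ibd_locus"].to_numpy(dtype=bool)
    keep = common & (is_ptv | in_locus)
    if not keep.any():
        raise ValueError("targeted variant set is empty")
    return g.variants.index[keep]
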