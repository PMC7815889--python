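"""Gene-based rare-variant and CNV burden testing.

Rare protein-truncating variants (MAF < 5%) are collapsed into one score
per gene and sample — the unweighted sum of minor-allele dosages over the
gene's qualifying PTVs — and that score replaces the single-variant dosage
in the same Spearman association / weighted-Z meta machinery used for
common variants. Rare CNVs (site frequency < 1%) are collapsed the same
way, counting deletion and duplication events per gene separately; the two
event types are never pooled into one statistic.

Stage thresholds follow the study design: PTV burden uses discovery
p < 0.005, replication p < 0.05 and a Bonferroni meta cutoff over the
number of scored genes; CNV burden uses p < 0.05 in each cohort with the
meta cutoff over the number of CNV genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import spearman_assoc
from .containers import CnvCallSet, FeatureTable, GenotypeMatrix
from .features import residualize
from .meta import StageThresholds, run_both_directions


@dataclass
class GeneBurdenScore:
    """Per-sample burden score for one gene and one variant class."""

    gene: str
    kind: str  # ptv | cnv_deletion | cnv_duplication
    scores: pd.Series  # indexed by sample id
    contributing: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("ptv", "cnv_deletion", "cnv_duplication"):
            raise ValueError(f"unknown burden kind {self.kind!r}")
        if (self.scores < 0).any():
            raise ValueError("burden scores must be non-negative")


def gene_ptv_score(
    rare_ptv: GenotypeMatrix,
    gene_map: pd.Series | None = None,
) -> list[GeneBurdenScore]:
    """Sum minor-allele dosages of qualifying PTVs per gene and sample.

    ``rare_ptv`` is the rare-PTV partition from QC (every variant already
    MAF < 5% and protein truncating). ``gene_map`` (variant id -> gene)
    overrides the matrix's own gene column when supplied. Missing genotypes
    contribute 0 to the sum; per-gene missingness is recorded on the score
    object via the contributing-variant list and the matrix call rates.
    Genes end up with scores bounded by 2 x (number of qualifying variants).
    """
    genes = (gene_map if gene_map is not None
             else rare_ptv.variants["gene"]).reindex(rare_ptv.variants.index)
    if genes.isna().any():
        raise ValueError("every qualifying variant needs a gene assignment")
    out = []
    for gene, ids in genes.groupby(genes).groups.items():
        idx = rare_ptv.variants.index.get_indexer(ids)
        block = rare_ptv.dosage[:, idx]
        scores = pd.Series(
            np.nansum(block, axis=1), index=rare_ptv.sample_ids, name=gene
        )
        out.append(GeneBurdenScore(
            gene=str(gene), kind="ptv", scores=scores,
            contributing=tuple(ids),
        ))
    return out


def gene_cnv_score(
    calls: CnvCallSet,
    sample_ids,
    max_site_freq: float = 0.01,
) -> list[GeneBurdenScore]:
    """Count CNV events per gene and sample, deletions and duplications apart.

    Events are first passed through the site-frequency filter
    (< ``max_site_freq``); each surviving (gene, type) site yields one
    score vector counting that sample's events of that type in the gene.
    """
    filtered = calls.filter_by_frequency(max_site_freq)
    sample_ids = pd.Index(sample_ids)
    out = []
    for (gene, typ), block in filtered.events.groupby(["gene", "type"]):
        counts = block.groupby("sample_id").size()
        scores = counts.reindex(sample_ids, fill_value=0).astype(float)
        out.append(GeneBurdenScore(
            gene=str(gene), kind=f"cnv_{typ}", scores=scores,
            contributing=tuple(f"{gene}:{typ}" for _ in range(1)),
        ))
    return out


def burden_assoc_scan(
    scores: list[GeneBurdenScore],
    features: FeatureTable,
    samples: pd.DataFrame,
    cohort: str,
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-cohort association of every gene score with every feature.

    The unit id is ``gene`` for PTV scores and ``gene:deletion`` /
    ``gene:duplication`` for CNV scores. The Spearman engine is reused with
    the score vector in place of dosage; a linear-model effect size of the
    residualized abundance on the score (per unit of score, among non-zero
    samples) is reported alongside as ``beta``. Constant scores within the
    cohort are untestable and flagged.
    """
    if features.residual is None:
        raise ValueError("features must be prepared (residual values missing)")
    ids = samples.index[samples["cohort"] == cohort]
    resid = features.residual.loc[:, ids]
    nonzero = features.nonzero.loc[:, ids]
    rows = []
    for sc in scores:
        unit = sc.gene if sc.kind == "ptv" else f"{sc.gene}:{sc.kind[4:]}"
        x = sc.scores.reindex(ids).to_numpy(dtype=float)
        for fid in features.feature_ids:
            r = spearman_assoc(
                x, resid.loc[fid].to_numpy(), nonzero.loc[fid].to_numpy(),
                unit=unit, feature=fid, cohort=cohort, min_n=min_n,
            )
            beta = np.nan
            if not r.untestable:
                mask = (nonzero.loc[fid].to_numpy()
                        & np.isfinite(resid.loc[fid].to_numpy())
                        & np.isfinite(x))
                y = resid.loc[fid].to_numpy()[mask]
                xx = x[mask]
                beta = float(np.polyfit(xx, y, 1)[0])
            rows.append((r.unit, r.feature, r.cohort, r.estimate, beta,
                         r.p, r.n_used, r.direction, r.untestable,
                         sc.kind))
    return pd.DataFrame(
        rows,
        columns=["unit", "feature", "cohort", "estimate", "beta", "p",
                 "n_used", "direction", "untestable", "burden_kind"],
    )


def burden_two_stage(
    scores: list[GeneBurdenScore],
    features: FeatureTable,
    samples: pd.DataFrame,
    cohort_a: str,
    cohort_b: str,
    thresholds: StageThresholds | None = None,
    kind: str = "ptv",
    min_n: int = 10,
) -> dict[str, pd.DataFrame]:
    """Full discovery/replication/meta run on gene burden scores.

    ``thresholds`` defaults to the stage presets: (0.005, 0.05) for PTV
    scores, (0.05, 0.05) for CNV scores, each with n_tests = number of
    scored units of that kind. Returns the primary and cohort-swapped meta
    tables (genes testable in only one cohort contribute no meta result).
    """
    use = [s for s in scores if (s.kind == "ptv") == (kind == "ptv")]
    if not use:
        raise ValueError(f"no {kind} burden scores supplied")
    n_units = len({s.gene if kind == "ptv" else f"{s.gene}:{s.kind}" for s in use})
    if thresholds is None:
        thresholds = (StageThresholds(0.005, 0.05, n_units) if kind == "ptv"
                      else StageThresholds(0.05, 0.05, n_units))
    res_a = burden_assoc_scan(use, features, samples, cohort_a, min_n=min_n)
    res_b = burden_assoc_scan(use, features, samples, cohort_b, min_n=min_n)
    return run_both_directions(res_a, res_b, thresholds, cohort_a, cohort_b)
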