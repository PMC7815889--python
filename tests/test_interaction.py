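"""Disease x genotype interaction: OLS recovery of planted interactions,
permutation calibration, genotype recoding, candidate selection and
subgroup reruns."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbqtl.assoc import spearman_assoc
from mbqtl.interaction import (
    genotype_recode,
    interaction_test,
    permutation_calibration,
    select_interaction_candidates,
    subgroup_analysis,
)
from mbqtl.simulate import SimulationConfig, simulate_dataset
from tests.conftest import make_genotypes


class TestRecode:
    def test_recessive_and_additive(self):
        d = np.array([0.0, 1.0, 2.0, np.nan])
        np.testing.assert_array_equal(genotype_recode(d, "recessive")[:3],
                                      [0, 0, 1])
        assert np.isnan(genotype_recode(d, "recessive")[3])
        np.testing.assert_array_equal(genotype_recode(d, "additive")[:3],
                                      d[:3])

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            genotype_recode(np.zeros(3), "dominant")

    def test_recessive_spearman_equals_binary_rank_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, 30).astype(float)
        y = rng.normal(size=30) + 0.8 * (d == 2)
        rec = genotype_recode(d, "recessive")
        r = spearman_assoc(rec, y)
        # brute-force rank statistic: Pearson correlation of average ranks
        # between the binary carrier indicator and the outcome ranks
        ry = stats.rankdata(y)
        rb = stats.rankdata(rec)
        oracle = np.corrcoef(rb, ry)[0, 1]
        assert r.estimate == pytest.approx(oracle, rel=1e-10)


def _pooled(n=600, seed=1, beta_g=0.0, beta_d=0.0, beta_gd=0.0, maf=0.3):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, n).astype(float)
    d = (np.arange(n) >= n * 2 // 3).astype(float)
    X = rng.normal(size=(n, 3))
    y = (beta_g * g + beta_d * d + beta_gd * g * d
         + X @ [0.2, -0.1, 0.1] + rng.normal(size=n))
    return y, g, d, X


class TestInteractionTest:
    def test_planted_interaction_recovered(self):
        signs = []
        for seed in range(10):
            y, g, d, X = _pooled(n=1355, seed=seed, beta_g=0.2, beta_d=0.5,
                                 beta_gd=0.5)
            r = interaction_test(y, g, d, X)
            # SE of the interaction slope at this design is ~0.08
            assert r.beta_interaction == pytest.approx(0.5, abs=3 * 0.09)
            signs.append(np.sign(r.beta_interaction))
        assert all(s == 1 for s in signs)

    def test_null_interaction_p_uniform_with_main_effects(self):
        ps = []
        for seed in range(400):
            y, g, d, X = _pooled(n=200, seed=seed, beta_g=0.3, beta_d=0.8)
            ps.append(interaction_test(y, g, d, X).p_interaction)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_genotype_untestable(self):
        y, g, d, X = _pooled()
        r = interaction_test(y, np.ones_like(g), d, X)
        assert r.untestable

    def test_minor_allele_in_one_group_only_untestable(self):
        y, g, d, X = _pooled()
        g2 = np.where(d == 1, g, 0.0)
        g2[(d == 1)] = 1.0  # carrier status == disease -> g collinear with d
        r = interaction_test(y, g2, d, X)
        assert r.untestable

    def test_type_one_error_calibrated(self):
        hits = 0
        trials = 1000
        for seed in range(trials):
            y, g, d, X = _pooled(n=150, seed=seed)
            r = interaction_test(y, g, d, X)
            hits += (not r.untestable) and r.p_interaction < 0.05
        lo, hi = stats.binom.interval(0.95, trials, 0.05)
        assert lo <= hits <= hi


class TestPermutation:
    def test_addone_formula_floor(self):
        # overwhelming planted interaction: no permutation reaches it
        y, g, d, X = _pooled(n=400, seed=3, beta_gd=3.0)
        r = permutation_calibration(y, g, d, X, n_permutations=99, seed=5)
        assert r.p_empirical == pytest.approx(1 / 100)

    def test_same_seed_reproducible(self):
        y, g, d, X = _pooled(n=200, seed=4, beta_gd=0.3)
        a = permutation_calibration(y, g, d, X, n_permutations=59, seed=9)
        b = permutation_calibration(y, g, d, X, n_permutations=59, seed=9)
        assert a.p_empirical == b.p_empirical

    def test_empirical_p_on_permutation_grid(self):
        y, g, d, X = _pooled(n=150, seed=6)
        r = permutation_calibration(y, g, d, X, n_permutations=49, seed=1)
        assert (r.p_empirical * 50) == pytest.approx(round(r.p_empirical * 50))

    def test_zero_permutations_rejected(self):
        y, g, d, X = _pooled()
        with pytest.raises(ValueError):
            permutation_calibration(y, g, d, X, n_permutations=0)

    def test_empirical_and_asymptotic_rank_correlated(self):
        rng = np.random.default_rng(11)
        emp, asy = [], []
        for seed in range(60):
            y, g, d, X = _pooled(n=150, seed=100 + seed,
                                 beta_gd=rng.uniform(-0.4, 0.4))
            r = permutation_calibration(y, g, d, X, n_permutations=99,
                                        seed=seed)
            emp.append(r.p_empirical)
            asy.append(r.p_interaction)
        rho = stats.spearmanr(emp, asy).statistic
        assert rho > 0.9


def _meta_table(rows, discovery, replication):
    df = pd.DataFrame(
        rows, columns=["unit", "feature", "p_disc", "p_rep"]
    )
    df["discovery_cohort"] = discovery
    df["replication_cohort"] = replication
    return df


class TestCandidateSelection:
    def test_pair_significant_in_both_cohorts_excluded(self):
        primary = _meta_table([("v1", "f1", 1e-8, 0.001)], "A", "B")
        swapped = _meta_table([("v1", "f1", 1e-7, 0.002)], "B", "A")
        cand, thr = select_interaction_candidates(primary, swapped, 6.83e-7)
        assert cand.empty

    def test_candidate_counts_set_printed_thresholds(self):
        rows = [(f"v{i}", "f", 1e-8, 0.5) for i in range(38)]
        primary = _meta_table(rows, "A", "B")
        swapped = _meta_table([], "B", "A")
        cand, thr = select_interaction_candidates(primary, swapped, 6.83e-7)
        assert len(cand) == 38
        assert f"{thr:.4f}" == "0.0013"
        rows = rows[:36]
        cand, thr = select_interaction_candidates(
            _meta_table(rows, "A", "B"), swapped, 6.83e-7
        )
        assert f"{thr:.4f}" == "0.0014"

    def test_origin_labels_follow_discovery_cohort(self):
        primary = _meta_table([("v1", "f1", 1e-8, 0.5)], "A", "B")
        swapped = _meta_table([("v2", "f2", 1e-8, 0.6)], "B", "A")
        cand, _ = select_interaction_candidates(primary, swapped, 6.83e-7)
        origins = dict(zip(cand["unit"], cand["candidate_origin"]))
        assert origins == {"v1": "A_specific", "v2": "B_specific"}


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(
        n_controls=100, n_cases=80, n_common_variants=8, n_rare_ptvs=5,
        n_cnv_genes=3, n_taxa=6, n_pathways=5, n_reference=20,
        cnv_site_freq_max=0.05, seed=13,
    )
    return simulate_dataset(cfg)


class TestSubgroup:

    def test_filter_keeps_exactly_the_subtype(self, dataset):
        seen = {}

        def scan(g, f, s):
            seen["samples"] = s
            return s

        out = subgroup_analysis(dataset.genotypes, dataset.features,
                                dataset.samples, "CD", scan)
        ibd = out[out["cohort"] == "IBD"]
        assert (ibd["subtype"] == "CD").all()
        pop = out[out["cohort"] == "population"]
        assert len(pop) == 100

    def test_ibdu_excluded_from_both_subgroups(self, dataset):
        for subtype in ("CD", "UC"):
            out = subgroup_analysis(dataset.genotypes, dataset.features,
                                    dataset.samples, subtype,
                                    lambda g, f, s: s)
            assert not (out["subtype"] == "IBDU").any()

    def test_unknown_subtype_rejected(self, dataset):
        with pytest.raises(ValueError, match="CD and UC"):
            subgroup_analysis(dataset.genotypes, dataset.features,
                              dataset.samples, "IBDU", lambda g, f, s: s)

    def test_planted_effect_same_sign_in_both_subgroups(self):
        from mbqtl.features import prepare_features
        from mbqtl.simulate import PlantedEffect

        eff = PlantedEffect("PWY-1000", "v00000", 1.0)
        cfg = SimulationConfig(
            n_controls=200, n_cases=200, n_common_variants=8, n_rare_ptvs=5,
            n_cnv_genes=3, n_taxa=4, n_pathways=4, n_reference=20,
            zero_inflation_range=(0.0, 0.0), cnv_site_freq_max=0.05,
            missing_rate=0.0, planted_effects=(eff,), seed=17,
        )
        ds = simulate_dataset(cfg)

        def scan(g, f, s):
            prepared = prepare_features(f, s)
            ids = s.index[s["cohort"] == "IBD"]
            gi = g.subset_samples(ids)
            return spearman_assoc(
                gi.dosage_series("v00000").to_numpy(),
                prepared.residual.loc["PWY-1000", ids].to_numpy(),
                prepared.nonzero.loc["PWY-1000", ids].to_numpy(),
            )

        rs = {
            sub: subgroup_analysis(ds.genotypes, ds.features, ds.samples,
                                   sub, scan)
            for sub in ("CD", "UC")
        }
        assert rs["CD"].direction == rs["UC"].direction == 1
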