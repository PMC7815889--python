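"""Genotype QC: exact Hardy-Weinberg test against a brute-force oracle,
variant filters, PCA ancestry outliers, sex checks, relatedness pruning and
the common/rare-PTV partition."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mbqtl.qc import (
    estimate_pihat,
    filter_variants,
    hwe_exact_test,
    partition_by_maf,
    pca_outlier_flags,
    relatedness_prune,
    sex_check,
)
from tests.conftest import make_genotypes


# --------------------------------------------------------------------------
# independent enumeration oracle for the HWE exact test
# --------------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact two-sided HWE p via exact rational arithmetic.

    Conditional on allele counts, counts the number of genotype
    configurations for each possible heterozygote count using factorials
    (2^h phase factor included) and sums the probabilities of all counts no
    more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    if min(n_a, 2 * n - n_a) == 0:
        return 1.0
    weights = {}
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_minor = (n_a - h) // 2
        hom_major = n - h - hom_minor
        weights[h] = Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(hom_minor) * math.factorial(hom_major),
        )
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHweExact:
    def test_perfect_proportions_are_modal(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 17) == 1.0

    def test_het_deficit_matches_enumeration(self):
        assert hwe_exact_test(5, 0, 5) == pytest.approx(hwe_oracle(5, 0, 5),
                                                        rel=1e-10)

    def test_matches_oracle_for_all_small_tables(self):
        for total in range(1, 13):
            for n_AA in range(total + 1):
                for n_Aa in range(total - n_AA + 1):
                    n_aa = total - n_AA - n_Aa
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        hwe_oracle(n_AA, n_Aa, n_aa), rel=1e-9
                    ), (n_AA, n_Aa, n_aa)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_p_is_valid_probability(self, a, b, c):
        if a + b + c == 0:
            with pytest.raises(ValueError):
                hwe_exact_test(a, b, c)
        else:
            assert 0 < hwe_exact_test(a, b, c) <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestFilterVariants:
    def _matrix(self):
        rng = np.random.default_rng(0)
        n = 200
        good = rng.binomial(2, 0.3, (n, 1)).astype(float)
        low_call = rng.binomial(2, 0.3, (n, 1)).astype(float)
        low_call[:3] = np.nan  # call rate 0.985 < 0.99
        bad_hwe = np.concatenate(  # strong het deficit
            [np.zeros(n // 2), np.full(n - n // 2, 2.0)]
        )[:, None]
        return make_genotypes(np.hstack([good, low_call, bad_hwe]),
                              variant_ids=["good", "low_call", "bad_hwe"])

    def test_call_rate_and_hwe_failures_logged(self):
        filtered, report = filter_variants(self._matrix())
        reasons = dict(
            report.removed_variants.set_index("variant_id")["reason"]
        )
        assert reasons == {"low_call": "call_rate", "bad_hwe": "hwe"}
        assert list(filtered.variant_ids) == ["good"]

    def test_idempotent(self):
        once, _ = filter_variants(self._matrix())
        twice, report = filter_variants(once)
        assert list(twice.variant_ids) == list(once.variant_ids)
        assert report.removed_variants.empty

    def test_hwe_on_controls_only(self):
        # controls in HWE; cases all hom-minor (as if disease-associated):
        # pooled counts fail HWE, control-only counts pass
        rng = np.random.default_rng(1)
        controls = rng.binomial(2, 0.4, (300, 1)).astype(float)
        cases = np.full((150, 1), 2.0)
        g = make_genotypes(np.vstack([controls, cases]), variant_ids=["v"])
        samples = pd.DataFrame(
            {"cohort": ["population"] * 300 + ["IBD"] * 150},
            index=g.sample_ids,
        )
        kept_ctrl, _ = filter_variants(g, samples=samples, hwe_on="controls")
        kept_all, _ = filter_variants(g, samples=samples, hwe_on="all")
        assert list(kept_ctrl.variant_ids) == ["v"]
        assert list(kept_all.variant_ids) == []


class TestPcaOutliers:
    @staticmethod
    def _cohorts(seed=1, n=120, m=400):
        rng = np.random.default_rng(seed)
        mafs = rng.uniform(0.1, 0.5, m)
        study = rng.binomial(2, mafs[None, :], (n, m)).astype(float)
        panel = rng.binomial(2, mafs[None, :], (80, m)).astype(float)
        return study, panel

    def test_homogeneous_cohort_unflagged(self):
        study, panel = self._cohorts()
        g = make_genotypes(study)
        ref = make_genotypes(panel, sample_ids=[f"R{i}" for i in range(80)])
        assert pca_outlier_flags(g, ref).sum() == 0

    def test_extreme_on_pc1_only_not_flagged(self):
        # a lone divergent sample defines PC1 by itself: huge PC1
        # coordinate, unremarkable PC2 -> the both-PC rule leaves it in
        study, panel = self._cohorts()
        study[0] = 2 - study[0]
        g = make_genotypes(study)
        ref = make_genotypes(panel, sample_ids=[f"R{i}" for i in range(80)])
        flags = pca_outlier_flags(g, ref)
        assert not flags.iloc[0]

    def test_flags_match_independent_pca_oracle(self):
        # two small divergent ancestry groups rotate the PCs so that some
        # samples are displaced on both axes; flags must equal the 3-SD
        # both-PC rule computed independently with sklearn
        from sklearn.decomposition import PCA

        study, panel = self._cohorts(seed=3)
        half = study.shape[1] // 2
        study[1:5, :half] = 2 - study[1:5, :half]
        study[5:9, half:] = 2 - study[5:9, half:]
        study[0] = 2 - study[0]
        g = make_genotypes(study)
        ref = make_genotypes(panel, sample_ids=[f"R{i}" for i in range(80)])
        flags = pca_outlier_flags(g, ref)

        merged = np.vstack([study, panel])
        merged = (merged - merged.mean(0)) / merged.std(0)
        pcs = PCA(n_components=2, svd_solver="randomized",
                  random_state=0).fit_transform(merged)[: len(study)]
        z = np.abs(pcs - pcs.mean(0)) / pcs.std(0)
        expected = (z > 3).all(axis=1)
        np.testing.assert_array_equal(flags.to_numpy(), expected)
        assert expected.any()  # the construction really exercises the rule

    def test_too_few_shared_variants_errors(self):
        study, panel = self._cohorts()
        g = make_genotypes(study[:, :2])
        ref = make_genotypes(panel[:, :2],
                             sample_ids=[f"R{i}" for i in range(80)])
        with pytest.raises(ValueError, match="shared variants"):
            pca_outlier_flags(g, ref)


class TestSexCheck:
    @pytest.mark.parametrize(
        "f,sex,expected",
        [
            (0.5, "female", "mismatch"),
            (0.8, "male", "pass"),
            (0.4, "female", "mismatch"),  # boundary excluded
            (0.7, "male", "mismatch"),  # boundary excluded
            (0.39, "female", "pass"),
            (0.1, "male", "mismatch"),
        ],
    )
    def test_threshold_rules(self, f, sex, expected):
        assert sex_check(f, sex) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="sex label"):
            sex_check(0.5, "unknown")

    def test_out_of_range_f_rejected(self):
        with pytest.raises(ValueError):
            sex_check(1.5, "male")


class TestRelatednessPrune:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["id1", "id2", "pihat"])

    def test_over_threshold_pair_loses_one_member(self):
        removed = relatedness_prune(
            self._table([("A", "B", 0.2)]),
            pd.Series({"A": 0.99, "B": 0.98}),
        )
        assert removed == {"B"}  # lower call rate loses

    def test_under_threshold_pair_kept(self):
        removed = relatedness_prune(
            self._table([("A", "B", 0.1)]), pd.Series({"A": 1.0, "B": 1.0})
        )
        assert removed == set()

    def test_chain_removes_shared_member_only(self):
        removed = relatedness_prune(
            self._table([("A", "B", 0.3), ("B", "C", 0.3)]),
            pd.Series({"A": 1.0, "B": 1.0, "C": 1.0}),
        )
        assert removed == {"B"}

    def test_call_rate_tiebreak_then_later_id(self):
        # equal counts, equal call rates -> lexicographically later id goes
        removed = relatedness_prune(
            self._table([("A", "B", 0.25)]), pd.Series({"A": 1.0, "B": 1.0})
        )
        assert removed == {"B"}

    @given(st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7),
                  st.floats(0, 1, allow_nan=False)),
        max_size=15,
    ))
    def test_result_is_pair_free(self, raw):
        rows = [(f"S{a}", f"S{b}", p) for a, b, p in raw if a != b]
        table = self._table(rows)
        calls = pd.Series({f"S{i}": 1.0 for i in range(8)})
        removed = relatedness_prune(table, calls)
        for a, b, p in rows:
            if p > 0.185:
                assert a in removed or b in removed

    def test_pihat_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            relatedness_prune(self._table([("A", "B", 1.2)]), pd.Series())


class TestPartition:
    def test_allele_count_arithmetic(self):
        # 10 samples, 3 het + 1 hom-minor -> MAF 5/20 = 0.25 -> common
        dosage = np.zeros((10, 1))
        dosage[:3, 0] = 1
        dosage[3, 0] = 2
        g = make_genotypes(dosage, annotation="synonymous")
        assert g.variants["maf"].iloc[0] == pytest.approx(0.25)
        common, rare = partition_by_maf(g)
        assert common.n_variants == 1 and rare.n_variants == 0

    def test_rare_ptv_and_rare_synonymous(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.04, (500, 2)).astype(float)
        g = make_genotypes(dosage, annotation=["stop-gain", "synonymous"])
        g.variants["maf"] = [0.04, 0.04]
        common, rare = partition_by_maf(g)
        assert list(rare.variant_ids) == ["v000"]
        assert common.n_variants == 0

    def test_boundary_maf_goes_to_common(self):
        dosage = np.zeros((10, 1))
        dosage[0, 0] = 1  # MAF = 0.05 exactly
        g = make_genotypes(dosage, annotation="stop-gain")
        assert g.variants["maf"].iloc[0] == pytest.approx(0.05)
        common, rare = partition_by_maf(g)
        assert common.n_variants == 1 and rare.n_variants == 0


def test_estimate_pihat_separates_duplicates_from_unrelated():
    rng = np.random.default_rng(2)
    m = 800
    mafs = rng.uniform(0.1, 0.5, m)
    base = rng.binomial(2, mafs[None, :], (30, m)).astype(float)
    base[1] = base[0]  # duplicate pair
    g = make_genotypes(base)
    tab = estimate_pihat(g).set_index(["id1", "id2"])["pihat"]
    assert tab.loc[("S000", "S001")] > 0.9
    others = tab.drop(index=("S000", "S001"))
    assert others.max() < 0.185
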