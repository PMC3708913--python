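"""Hardy-Weinberg, chi-square association, odds ratios, logistic IRLS,
power, and baseline comparisons."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import genecase as gc
from genecase.single_locus import odds_ratio_2x2

from conftest import make_cohort


class TestHWE:
    def test_exact_proportions_give_zero(self):
        assert gc.hwe_test((25, 50, 25)).chi2 == pytest.approx(0.0)

    def test_total_heterozygote_deficit(self):
        # n=100, allele freq 0.5 -> expected (25, 50, 25); observed (50, 0, 50)
        res = gc.hwe_test((50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)
        assert res.p < 1e-20

    def test_study_controls_in_equilibrium(self):
        assert gc.hwe_test((485, 289, 29)).p > 0.05

    def test_monomorphic_flagged(self):
        res = gc.hwe_test((42, 0, 0))
        assert res.monomorphic and res.chi2 == 0.0 and res.p == 1.0


class TestChiSquare:
    def test_strong_genotype_difference(self):
        chi2, df, p = gc.genotype_chi2(gc.GENOTYPE_COUNTS[0])
        assert df == 2 and p < 0.0005

    def test_identical_rows_null(self):
        t = gc.GenotypeCountTable(gc.LUNG_PANEL[0], (40, 20, 10), (40, 20, 10))
        chi2, _, p = gc.genotype_chi2(t)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_allele_chi2_reproduces_published_p(self):
        # second RAGE promoter SNP: allele table (407 vs 375 minor) -> p 0.319
        _, df, p = gc.allele_chi2(gc.GENOTYPE_COUNTS[1])
        assert df == 1
        assert p == pytest.approx(0.319, abs=0.005)

    def test_zero_margin_rejected(self):
        t = gc.GenotypeCountTable(gc.LUNG_PANEL[0], (0, 0, 0), (1, 2, 3))
        with pytest.raises(ValueError):
            gc.genotype_chi2(t)


# printed crude OR / 95% CI per locus and model (two printed decimals)
TABLE2_CRUDE = [
    ("rs1800625", "additive", 1.34, 1.14, 1.57),
    ("rs1800625", "dominant", 1.27, 1.04, 1.55),
    ("rs1800625", "recessive", 2.46, 1.57, 3.83),
    ("rs1800624", "additive", 1.08, 0.92, 1.27),
    ("rs1800624", "dominant", 1.05, 0.86, 1.28),
    ("rs1800624", "recessive", 1.34, 0.89, 2.00),
    ("rs2070600", "additive", 1.24, 1.07, 1.44),
    ("rs2070600", "dominant", 1.21, 0.99, 1.48),
    ("rs2070600", "recessive", 1.63, 1.19, 2.22),
    ("rs1760944", "additive", 1.10, 0.95, 1.27),
    ("rs1760944", "dominant", 1.12, 0.92, 1.36),
    ("rs1760944", "recessive", 1.16, 0.87, 1.55),
    ("rs1130409", "additive", 1.28, 1.08, 1.51),
    ("rs1130409", "dominant", 1.26, 1.03, 1.54),
    ("rs1130409", "recessive", 1.94, 1.18, 3.17),
]


class TestCrudeOR:
    @pytest.mark.parametrize("locus,model,or_,lo,hi", TABLE2_CRUDE,
                             ids=[f"{l}-{m}" for l, m, *_ in TABLE2_CRUDE])
    def test_reproduces_published_values(self, locus, model, or_, lo, hi):
        table = next(t for t in gc.GENOTYPE_COUNTS if t.locus.name == locus)
        res = gc.crude_or(table, model)
        assert round(res.or_crude, 2) == pytest.approx(or_)
        assert round(res.ci_crude[0], 2) == pytest.approx(lo)
        assert round(res.ci_crude[1], 2) == pytest.approx(hi)

    def test_symmetric_table_is_null(self):
        t = gc.GenotypeCountTable(gc.LUNG_PANEL[0], (30, 30, 30), (30, 30, 30))
        for model in gc.single_locus.GENETIC_MODELS:
            assert gc.crude_or(t, model).or_crude == pytest.approx(1.0)

    def test_zero_cell_needs_continuity(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 5, 3, 7)
        or_, ci, _ = odds_ratio_2x2(0, 5, 3, 7, continuity=True)
        assert 0 < or_ < 1 and ci[0] < or_ < ci[1]

    @given(st.tuples(*[st.integers(1, 400)] * 4))
    @settings(deadline=None, max_examples=50)
    def test_row_swap_inverts_or_and_ci(self, cells):
        a, b, c, d = cells
        o1, ci1, _ = odds_ratio_2x2(a, b, c, d)
        o2, ci2, _ = odds_ratio_2x2(c, d, a, b)
        assert o1 * o2 == pytest.approx(1.0)
        assert ci1[0] * ci2[1] == pytest.approx(1.0)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(60), np.zeros(40)]
        fit = gc.logistic_fit(np.ones((100, 1)), y)
        assert fit.coef[0] == pytest.approx(np.log(1.5), abs=1e-8)
        assert fit.converged

    def test_binary_predictor_matches_2x2_or(self):
        # 2x2 table (a,b;c,d) = (30,70,20,80)
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(20), np.zeros(80)]
        fit = gc.logistic_fit(np.column_stack([np.ones(200), x]), y)
        or_, _, _ = odds_ratio_2x2(30, 70, 20, 80)
        assert np.exp(fit.coef[1]) == pytest.approx(or_, abs=1e-6)

    def test_dose_regression_near_allele_or(self, expanded_cohort):
        dose = expanded_cohort.table["rs1800625"].to_numpy(float)
        X = np.column_stack([np.ones(len(dose)), dose])
        fit = gc.logistic_fit(X, expanded_cohort.status.astype(float))
        assert np.exp(fit.coef[1]) == pytest.approx(1.34, abs=0.01)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 3))])
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + X[:, 1] - 0.5 * X[:, 2])))).astype(float)
        ours = gc.logistic_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.cov, ref.cov_params(), rtol=1e-4)

    def test_separation_flagged(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()
        fit = gc.logistic_fit(np.column_stack([np.ones(40), x]), y)
        assert not fit.converged

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            gc.logistic_fit(np.ones((10, 1)), np.ones(10))


class TestAdjustedOR:
    def test_null_covariates_leave_or_unchanged(self):
        cohort = gc.simulate_cohort(gc.SimConfig(n_cases=600, n_controls=600, seed=9))
        crude = gc.locus_association(cohort, "rs1130409", "dominant")
        adj = gc.adjusted_or(cohort, "rs1130409", "dominant", ["age", "family_history"])
        # family history prevalence is nearly equal in both groups; the
        # adjusted estimate should sit within Monte-Carlo distance of crude
        assert adj.or_adjusted == pytest.approx(crude.or_crude, rel=0.08)

    def test_finite_ci_with_study_covariates(self, expanded_cohort):
        cohort = gc.simulate_cohort(gc.SimConfig(seed=13))
        res = gc.adjusted_or(cohort, "rs1130409", "recessive",
                             ["age", "sex", "smoking", "drinking"])
        lo, hi = res.ci_adjusted
        assert 0 < lo < res.or_adjusted < hi < np.inf
        assert res.converged

    def test_constant_covariate_rejected(self):
        cohort = gc.simulate_cohort(gc.SimConfig(n_cases=50, n_controls=50, seed=2))
        cohort.table["sex"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            gc.adjusted_or(cohort, "rs1130409", "additive", ["sex"])


class TestPower:
    def test_null_limit_is_half_alpha(self):
        assert gc.two_proportion_power(0.3, 0.3, 500, 500) == pytest.approx(0.025, abs=1e-6)

    def test_monotone_in_effect_and_n(self):
        base = gc.two_proportion_power(0.25, 0.20, 800, 800)
        assert gc.two_proportion_power(0.27, 0.20, 800, 800) > base
        assert gc.two_proportion_power(0.25, 0.20, 1600, 1600) > base

    def test_degenerate_proportions_rejected(self):
        with pytest.raises(ValueError):
            gc.two_proportion_power(0.0, 0.5, 100, 100)


class TestBaseline:
    def test_smoking_difference_strongly_significant(self):
        status = [1] * 819 + [0] * 803
        smoking = [1.0] * 297 + [0.0] * 522 + [1.0] * 64 + [0.0] * 739
        cohort = make_cohort({"rs1800625": [0] * 1622}, status)
        cohort.table["smoking"] = smoking
        _, p = gc.compare_baseline(cohort, "smoking")
        assert p < 0.0005

    def test_identical_binary_groups_null(self):
        cohort = make_cohort({"rs1800625": [0] * 40}, [1] * 20 + [0] * 20)
        cohort.table["sex"] = ([1.0] * 10 + [0.0] * 10) * 2
        stat, p = gc.compare_baseline(cohort, "sex")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_age_uses_t_test(self):
        rng = np.random.default_rng(5)
        cohort = make_cohort({"rs1800625": [0] * 200}, [1] * 100 + [0] * 100)
        cohort.table["age"] = rng.normal(57, 10, 200)
        stat, p = gc.compare_baseline(cohort, "age")
        from scipy.stats import ttest_ind
        ages = cohort.table["age"].to_numpy()
        ref = ttest_ind(ages[:100], ages[100:], equal_var=True)
        assert stat == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_equal_mean_age_p_uniformish(self):
        # calibration probe: 200 null replicates should give ~uniform p
        rng = np.random.default_rng(11)
        ps = []
        cohort = make_cohort({"rs1800625": [0] * 120}, [1] * 60 + [0] * 60)
        for _ in range(200):
            cohort.table["age"] = rng.normal(50, 8, 120)
            ps.append(gc.compare_baseline(cohort, "age")[1])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_variable_rejected(self):
        cohort = make_cohort({"rs1800625": [0] * 10}, [1] * 5 + [0] * 5)
        cohort.table["copd"] = 0.0
        with pytest.raises(ValueError):
            gc.compare_baseline(cohort, "copd")
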