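"""Composites, Welch t, allometry and partial correlations vs. longhand
closed-form oracles and independent implementations."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from valvedim import stats as vstats


class TestComposites:
    def test_equal_inputs_identity(self):
        assert vstats.composite_softpart_size(2.0, 2.0, 2.0, 2.0) == 2.0
        assert vstats.composite_hemibc(3.0, 3.0, 3.0) == 3.0

    def test_doubling_all_lengths_adds_log2(self):
        a = vstats.composite_softpart_size(*np.log([100, 100, 100, 100]))
        b = vstats.composite_softpart_size(*np.log([200, 200, 200, 200]))
        assert b - a == pytest.approx(math.log(2))

    def test_random_vector_equals_hand_mean(self):
        rng = np.random.default_rng(31)
        logs = rng.normal(5, 0.2, size=(4, 50))
        np.testing.assert_allclose(
            vstats.composite_softpart_size(*logs), logs.mean(axis=0),
            rtol=1e-12)

    def test_sum_vs_mean_convention_leaves_correlations_unchanged(self):
        # mean-of-logs and sum-of-logs differ by a factor of 3, so any
        # correlation with a third variable is bit-comparable
        rng = np.random.default_rng(32)
        logs = rng.normal(6, 0.1, size=(3, 60))
        other = rng.normal(size=60)
        mean_c = vstats.composite_hemibc(*logs)
        sum_c = 3.0 * mean_c
        r1 = np.corrcoef(mean_c, other)[0, 1]
        r2 = np.corrcoef(sum_c, other)[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_missing_input_error(self):
        with pytest.raises(ValueError, match="finite"):
            vstats.composite_softpart_size(1.0, np.nan, 2.0, 3.0)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = vstats.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_longhand_formula(self):
        f = np.array([13.2, 12.9, 13.8, 14.2, 13.1])
        m = np.array([13.9, 14.5, 15.2, 14.8, 14.1, 14.9])
        t, df, p = vstats.welch_t(f, m)
        vf, vm = f.var(ddof=1) / len(f), m.var(ddof=1) / len(m)
        t_hand = (f.mean() - m.mean()) / math.sqrt(vf + vm)
        df_hand = (vf + vm) ** 2 / (vf ** 2 / 4 + vm ** 2 / 5)
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(33)
        f, m = rng.normal(0, 1, 15), rng.normal(0.5, 2, 25)
        t, df, p = vstats.welch_t(f, m)
        ref = sps.ttest_ind(f, m, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_larger_males_give_negative_t(self):
        t, _, _ = vstats.welch_t([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
        assert t < 0


class TestDimorphism:
    def test_equal_means_zero_diff(self):
        est = vstats.dimorphism([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert est.diff == pytest.approx(0.0)

    def test_recovers_known_log_offset(self):
        rng = np.random.default_rng(34)
        f = rng.normal(0.53, 0.012, 50)
        m = rng.normal(0.60, 0.012, 50)
        est = vstats.dimorphism(f, m)
        se = 0.012 * math.sqrt(2 / 50)
        assert abs(est.diff - 0.07) < 2 * se
        assert est.p < 1e-6

    def test_global_scaling_leaves_log_shape_diff_unchanged(self):
        rng = np.random.default_rng(35)
        lengths_f, heights_f = rng.normal(1000, 20, 30), rng.normal(600, 15, 30)
        lengths_m, heights_m = rng.normal(1080, 20, 30), rng.normal(580, 15, 30)
        d1 = vstats.dimorphism(np.log(lengths_f / heights_f),
                               np.log(lengths_m / heights_m))
        k = 1e-3  # um -> mm
        d2 = vstats.dimorphism(np.log(k * lengths_f / (k * heights_f)),
                               np.log(k * lengths_m / (k * heights_m)))
        assert d1.diff == pytest.approx(d2.diff, rel=1e-12)
        assert d1.t == pytest.approx(d2.t, rel=1e-12)


class TestFemaleCenteredDeviations:
    def test_centroid_identities(self):
        rng = np.random.default_rng(36)
        size = rng.normal(12.8, 0.05, 40)
        shape = rng.normal(0.55, 0.01, 40)
        fem = np.arange(40) < 20
        dsize, dshape = vstats.female_centered_deviations(size, shape, fem)
        assert dsize[fem].mean() == pytest.approx(0.0, abs=1e-12)
        assert dshape[fem].mean() == pytest.approx(0.0, abs=1e-12)
        est = vstats.dimorphism(size[fem], size[~fem])
        assert dsize[~fem].mean() == pytest.approx(est.diff, rel=1e-10)

    def test_no_females_error(self):
        with pytest.raises(ValueError, match="no females"):
            vstats.female_centered_deviations([1.0, 2.0], [0.1, 0.2],
                                              [False, False])


class TestCV:
    def test_hand_computed(self):
        assert vstats.coefficient_of_variation([9.0, 10.0, 11.0]) == \
            pytest.approx(10.0)

    def test_constant_vector_zero(self):
        assert vstats.coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_scale_invariant(self):
        v = [9.0, 10.0, 11.0]
        assert vstats.coefficient_of_variation(v) == pytest.approx(
            vstats.coefficient_of_variation([x * 7.3 for x in v]))

    def test_zero_mean_error(self):
        with pytest.raises(ValueError, match="zero mean"):
            vstats.coefficient_of_variation([-1.0, 1.0])


class TestStaticAllometry:
    def test_exact_isometry(self):
        areas = np.linspace(3e5, 7e5, 20)
        traits = 0.01 * np.sqrt(areas)  # trait proportional to sqrt(area)
        fit = vstats.static_allometry(traits, areas, "TORO", "1A")
        assert fit.slope == pytest.approx(1.0, rel=1e-10)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)
        assert fit.isometry_p > 0.05

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(37)
        areas = np.exp(rng.normal(13, 0.1, 45))
        traits = np.exp(0.8 + 0.63 * np.log(np.sqrt(areas))
                        + rng.normal(0, 0.02, 45))
        fit = vstats.static_allometry(traits, areas, "TORO", "1A")
        x = np.column_stack([np.ones(45), np.log(np.sqrt(areas))])
        beta = np.linalg.solve(x.T @ x, x.T @ np.log(traits))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], rel=1e-8)

    def test_ci_coverage_for_published_scale_slope(self):
        # slope 0.63, sigma 0.02, n = 45: the 95% CI should cover the
        # true slope in roughly 95% of replicates
        rng = np.random.default_rng(38)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            areas = np.exp(rng.normal(13, 0.1, 45))
            traits = np.exp(0.8 + 0.63 * np.log(np.sqrt(areas))
                            + rng.normal(0, 0.02, 45))
            fit = vstats.static_allometry(traits, areas, "T", "1A")
            hits += fit.slope_ci[0] <= 0.63 <= fit.slope_ci[1]
        assert 0.92 <= hits / n_rep <= 0.98

    def test_area_on_area_dimensionality(self):
        areas = np.linspace(3e5, 7e5, 20)
        te_areas = 0.05 * areas
        fit = vstats.static_allometry(te_areas, areas, "T", "HemiTE_A",
                                      same_dimensionality=True)
        assert fit.size_proxy == "valve_area"
        assert fit.slope == pytest.approx(1.0, rel=1e-10)

    def test_small_n_error(self):
        with pytest.raises(ValueError, match="n >="):
            vstats.static_allometry([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestEvolutionaryAllometry:
    def test_collinear_means_r2_one(self):
        areas = np.array([4e5, 5e5, 6.5e5])
        traits = 2.0 * np.sqrt(areas) ** 0.8
        fit = vstats.evolutionary_allometry(traits, areas, trait="HemiBCd_L")
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.8, rel=1e-8)
        assert fit.kind == "evolutionary"

    def test_three_point_fit_equals_closed_form(self):
        areas = np.array([4e5, 5e5, 6.5e5])
        traits = np.array([400.0, 470.0, 600.0])
        fit = vstats.evolutionary_allometry(traits, areas)
        x = np.column_stack([np.ones(3), np.log(np.sqrt(areas))])
        beta = np.linalg.solve(x.T @ x, x.T @ np.log(traits))
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)

    def test_identical_means_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            vstats.evolutionary_allometry([5.0, 5.0, 5.0], [1e5, 1e5, 1e5])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, df, p = vstats.pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert df == 8

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(39)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, df, p = vstats.pearson_correlation(x, y)
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / math.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(r_hand, rel=1e-12)

    def test_independent_large_n_near_zero(self):
        rng = np.random.default_rng(40)
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        r, _, _ = vstats.pearson_correlation(x, y)
        assert abs(r) < 0.05


def _triples(seed=41, n=40, effect=0.5):
    rng = np.random.default_rng(seed)
    size = rng.normal(0, 1, n)
    male = 0.8 * size + rng.normal(0, 0.5, n)
    valve = 0.9 * size + effect * (male - 0.8 * size) + rng.normal(0, 0.3, n)
    return male, valve, size


class TestPartialCorrelation:
    def test_orthogonal_covariate_reduces_to_plain_r(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=200), rng.normal(size=200)
        z = np.tile([1.0, -1.0], 100)  # exactly orthogonal to nothing...
        z = z - np.polyval(np.polyfit(x, z, 0), 0)
        # use a covariate built orthogonal to both x and y
        q = rng.normal(size=200)
        xm = np.column_stack([np.ones(200), x, y])
        q = q - xm @ np.linalg.lstsq(xm, q, rcond=None)[0]
        res = vstats.partial_correlation(x, y, q)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert res.r_p == pytest.approx(r_plain, rel=1e-10)

    def test_six_point_longhand_oracle(self):
        male = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        valve = np.array([2.1, 2.0, 3.7, 3.1, 5.5, 5.0])
        size = np.array([0.9, 2.2, 2.8, 4.3, 4.8, 6.1])
        res = vstats.partial_correlation(male, valve, size)
        x = np.column_stack([np.ones(6), size])
        rm = male - x @ np.linalg.solve(x.T @ x, x.T @ male)
        rv = valve - x @ np.linalg.solve(x.T @ x, x.T @ valve)
        r_hand = (np.sum(rm * rv)
                  / math.sqrt(np.sum(rm ** 2) * np.sum(rv ** 2)))
        t_hand = r_hand * math.sqrt(3 / (1 - r_hand ** 2))
        p_hand = 2 * sps.t.sf(abs(t_hand), 3)
        assert res.r_p == pytest.approx(r_hand, rel=1e-12)
        assert res.df == 3
        assert res.p == pytest.approx(p_hand, rel=1e-12)

    def test_p_equals_multiple_regression_coefficient_p(self):
        for seed in (1, 2, 3, 4, 5):
            male, valve, size = _triples(seed)
            res = vstats.partial_correlation(male, valve, size)
            x = sm.add_constant(np.column_stack([size, male]))
            fit = sm.OLS(valve, x).fit()
            assert res.p == pytest.approx(fit.pvalues[2], abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        male, valve, size = _triples(6)
        res = vstats.partial_correlation(male, valve, size)
        ref = pingouin.partial_corr(
            pd.DataFrame({"m": male, "v": valve, "s": size}),
            x="m", y="v", covar="s")
        assert res.r_p == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_null_rejection_rate_nominal(self):
        # zero partial association: rejection at alpha=0.05 must sit at
        # the nominal rate across 1000 seeded datasets
        rng = np.random.default_rng(43)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            size = rng.normal(0, 1, 40)
            male = 0.8 * size + rng.normal(0, 0.5, 40)
            valve = 0.9 * size + rng.normal(0, 0.3, 40)
            rej += vstats.partial_correlation(male, valve, size).p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_collinear_error(self):
        size = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            vstats.partial_correlation(2 * size + 1, size ** 2, size)

    def test_unit_change_invariance(self):
        male, valve, size = _triples(7)
        r1 = vstats.partial_correlation(male, valve, size)
        r2 = vstats.partial_correlation(male, valve + math.log(1e-6), size)
        # a global unit change enters log variables as an additive shift
        assert r1.r_p == pytest.approx(r2.r_p, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
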