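import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from epivector.errors import ConfigurationError, ValidationError
from epivector.stats import (anova, boxplot_summary, significance_stars,
                             timepoint_ratio, welch_t)


class TestBoxplotSummary:
    def test_seven_point_sample_tukey_hinges(self):
        """{1..7}: Tukey fourths sit at depth 2.5, i.e. hinges 2.5/5.5
        (matches R fivenum(1:7)); whiskers reach the extremes."""
        s = boxplot_summary([1, 2, 3, 4, 5, 6, 7])
        assert s.median == 4
        assert (s.lower_hinge, s.upper_hinge) == (2.5, 5.5)
        assert (s.lower_whisker, s.upper_whisker) == (1, 7)
        assert s.outliers == ()

    def test_all_equal_values_degenerate(self):
        s = boxplot_summary([3.3] * 5)
        assert (s.median == s.lower_hinge == s.upper_hinge
                == s.lower_whisker == s.upper_whisker == 3.3)

    def test_outlier_flagged_by_iqr_rule(self):
        # {1,2,3,4,100}: hinges 2/4 (R fivenum), fence 4 + 1.5*2 = 7
        s = boxplot_summary([1, 2, 3, 4, 100])
        assert (s.lower_hinge, s.upper_hinge) == (2, 4)
        assert s.upper_whisker == 4
        assert s.outliers == (100,)

    def test_linear_quartile_switch(self):
        s = boxplot_summary([1, 2, 3, 4, 5, 6, 7], quartile_method="linear")
        assert (s.lower_hinge, s.upper_hinge) == (2.5, 5.5)
        s5 = boxplot_summary([1, 2, 3, 4, 5], quartile_method="linear")
        assert (s5.lower_hinge, s5.upper_hinge) == (2.0, 4.0)
        with pytest.raises(ConfigurationError):
            boxplot_summary([1, 2], quartile_method="exclusive")

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            boxplot_summary([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_summary_ordering_chain(self, values):
        s = boxplot_summary(values)
        assert (s.lower_whisker <= s.lower_hinge <= s.median
                <= s.upper_hinge <= s.upper_whisker)
        iqr = s.upper_hinge - s.lower_hinge
        assert s.lower_whisker >= s.lower_hinge - 1.5 * iqr
        assert s.upper_whisker <= s.upper_hinge + 1.5 * iqr


class TestWelch:
    def test_symmetric_equal_means(self):
        res = welch_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_agreement_with_scipy_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(2, 12))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(2, 12))
            mine = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            assert mine.df == pytest.approx(ref.df, abs=1e-9)

    def test_translation_invariance(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 3.5, 4.0, 5.0]
        base = welch_t(a, b)
        shifted = welch_t([x + 17.0 for x in a], [x + 17.0 for x in b])
        assert shifted.statistic == pytest.approx(base.statistic)
        assert shifted.p_value == pytest.approx(base.p_value)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            welch_t([2.0, 2.0], [3.0, 3.0])

    def test_type_I_error_under_null(self):
        """Null rejection rate at alpha=0.05, n=4 per group, 2000 reps."""
        rng = np.random.default_rng(1234)
        rejections = 0
        for _ in range(2000):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0, 1, 4)
            if welch_t(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 2000 <= 0.065


class TestAnova:
    def test_one_way_agrees_with_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.uniform(-1, 1), 1.0,
                                 size=rng.integers(3, 8)) for _ in range(k)]
            y = np.concatenate(groups)
            levels = np.concatenate([[f"g{i}"] * len(g)
                                     for i, g in enumerate(groups)])
            (res,) = anova(y, {"grp": levels})
            ref = sps.f_oneway(*groups)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_two_way_agrees_with_statsmodels_type2(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(5)
        for trial in range(20):
            a_levels = rng.integers(2, 4)
            b_levels = rng.integers(2, 4)
            reps = rng.integers(2, 5)
            rows = []
            for ai in range(a_levels):
                for bi in range(b_levels):
                    # unbalanced every other trial
                    n = reps + (rng.integers(0, 2) if trial % 2 else 0)
                    for _ in range(n):
                        rows.append({"A": f"a{ai}", "B": f"b{bi}",
                                     "y": rng.normal(ai + 0.5 * bi, 1.0)})
            df = pd.DataFrame(rows)
            results = anova(df["y"].to_numpy(),
                            {"A": df["A"].to_numpy(), "B": df["B"].to_numpy()})
            fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
            ref = sm.stats.anova_lm(fit, typ=2)
            for res, term in zip(results, ["C(A)", "C(B)", "C(A):C(B)"]):
                assert res.statistic == pytest.approx(ref.loc[term, "F"],
                                                      abs=1e-8)
                assert res.p_value == pytest.approx(ref.loc[term, "PR(>F)"],
                                                    abs=1e-8)

    def test_additive_no_noise_interaction_is_null(self):
        """Balanced 2x2 with purely additive effects and zero noise: the
        interaction carries no sum of squares."""
        rows = []
        effects_a = {"a0": 0.0, "a1": 2.0}
        effects_b = {"b0": 0.0, "b1": 1.0}
        for a in effects_a:
            for b in effects_b:
                for _ in range(3):
                    rows.append({"A": a, "B": b,
                                 "y": effects_a[a] + effects_b[b]})
        df = pd.DataFrame(rows)
        results = anova(df["y"].to_numpy(),
                        {"A": df["A"].to_numpy(), "B": df["B"].to_numpy()})
        interaction = results[2]
        assert interaction.term == "A:B"
        assert interaction.statistic == 0.0 and interaction.p_value == 1.0
        # the real main effects are detected as perfectly explanatory
        assert results[0].p_value == 0.0 and results[1].p_value == 0.0

    def test_constant_response_convention(self):
        y = np.full(8, 5.0)
        levels = np.array(["a", "a", "b", "b"] * 2)
        (res,) = anova(y, {"g": levels})
        assert res.statistic == 0.0 and res.p_value == 1.0
        res2 = anova(y, {"g": levels, "h": np.array(["x", "y"] * 4)})
        assert all(r.p_value == 1.0 for r in res2)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValidationError):
            anova(np.arange(4.0), {"g": np.array(["a"] * 4)})


class TestStarsAndRatios:
    @pytest.mark.parametrize("p,stars", [
        (0.2, "ns"), (0.05, "ns"), (0.049999, "*"), (0.01, "*"),
        (0.0099, "**"), (0.001, "**"), (0.0009, "***"), (0.0, "***")])
    def test_star_thresholds_pure_function(self, p, stars):
        assert significance_stars(p) == stars

    def test_star_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            significance_stars(1.5)

    def test_ratio_identity_and_arithmetic(self):
        assert timepoint_ratio([2.0, 4.0], [2.0, 4.0]) == 1.0
        assert timepoint_ratio([10, 20, 30], [1, 2, 3]) == pytest.approx(10.0)

    def test_ratio_scale_invariance(self):
        base = timepoint_ratio([10, 20, 30], [1, 2, 3])
        assert timepoint_ratio([35, 70, 105], [3.5, 7, 10.5]) == \
            pytest.approx(base)

    def test_non_positive_early_mean_rejected(self):
        with pytest.raises(ValidationError):
            timepoint_ratio([1.0, 2.0], [-1.0, 0.5])
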