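import numpy as np
import pandas as pd
import pytest

from glutme.exceptions import (
    DegenerateInputError,
    ParameterError,
    SurvivalModelError,
)
from glutme.response import (
    compare_groups,
    cox_assoc,
    glut_ratio,
    km_logrank,
    percent_change,
    validate_response_cohort,
    waterfall_table,
)
from glutme.synthetic import ResponseSimParams, generate_response_cohort
from oracles import cox_partial_likelihood_mle, logrank_statistic, mannwhitney_exact_enumeration


def make_cohort(glut1, glut3, timepoint="pre", response="SD"):
    n = len(glut1)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "timepoint": timepoint,
            "glut1": glut1,
            "glut3": glut3,
            "response": response,
            "pfs_time": np.linspace(1, 10, n),
            "event": True,
        }
    )


class TestGlutRatio:
    def test_equal_expression_gives_unit_ratio(self):
        cohort = make_cohort([2.0, 5.0, 0.7], [2.0, 5.0, 0.7])
        assert np.allclose(glut_ratio(cohort)["glut_ratio"], 1.0)

    def test_proportional_cohort(self):
        g1 = np.array([1.0, 2.0, 4.0])
        cohort = make_cohort(g1, 3.0 * g1)
        assert np.allclose(glut_ratio(cohort, pseudocount=1e-12)["glut_ratio"], 3.0, atol=1e-9)

    def test_zdiff_arithmetic(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [10.0, 30.0, 20.0])
        from scipy.stats import zscore

        expected = zscore([10.0, 30.0, 20.0]) - zscore([1.0, 2.0, 3.0])
        out = glut_ratio(cohort, mode="zdiff")
        assert np.allclose(out["glut_ratio"], expected)

    def test_zdiff_has_zero_mean_and_bounded_variance(self, response_sim):
        out = glut_ratio(response_sim.data, mode="zdiff")
        for tp in ("pre", "on"):
            vals = out.loc[response_sim.data["timepoint"] == tp, "glut_ratio"]
            assert vals.mean() == pytest.approx(0.0, abs=1e-10)
            assert vals.var(ddof=0) <= 2.0 + 1e-9

    def test_nonpositive_glut1_rejected_in_ratio_mode(self):
        cohort = make_cohort([-1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ParameterError):
            glut_ratio(cohort)

    def test_unknown_mode(self):
        with pytest.raises(ParameterError):
            glut_ratio(make_cohort([1.0, 2.0], [1.0, 2.0]), mode="log2fc")


class TestPercentChange:
    @pytest.mark.parametrize("pre,on,expected", [(2.0, 3.0, 50.0), (5.0, 5.0, 0.0), (4.0, 1.0, -75.0)])
    def test_arithmetic(self, pre, on, expected):
        assert percent_change(pre, on) == pytest.approx(expected)

    def test_zero_baseline(self):
        with pytest.raises(DegenerateInputError):
            percent_change(0.0, 1.0)


class TestCompareGroups:
    def test_textbook_exact_case(self):
        values = [1, 2, 3, 4, 5, 6]
        groups = ["a"] * 3 + ["b"] * 3
        res = compare_groups(values, groups)
        assert res.method == "mann-whitney-exact"
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(0.1)

    def test_exact_matches_enumeration(self, rng):
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=5))
        res = compare_groups(a + b, ["a"] * 4 + ["b"] * 5)
        assert res.p == pytest.approx(mannwhitney_exact_enumeration(a, b), abs=1e-12)

    def test_identical_groups_yield_p_near_one(self):
        values = list(range(20)) * 2
        groups = ["a"] * 20 + ["b"] * 20
        res = compare_groups(values, groups)
        assert res.method == "mann-whitney-asymptotic"
        assert res.p > 0.9

    def test_three_groups_kruskal_wallis(self, rng):
        values = rng.normal(size=30)
        groups = ["PD"] * 10 + ["SD"] * 10 + ["PR_CR"] * 10
        res = compare_groups(values, groups)
        assert res.method == "kruskal-wallis"
        assert 0 <= res.p <= 1

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestKmLogrank:
    def test_identical_curves_give_null_p(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        events = np.ones(10, bool)
        ratios = np.array([0.0] * 5 + [1.0] * 5)  # arbitrary split at mean 0.5
        res = km_logrank(ratios, times, events)
        assert res.logrank_p > 0.9

    def test_matches_hypergeometric_oracle(self):
        t1, t2 = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        e = np.ones(3, bool)
        expected = logrank_statistic(t1, t2, e, e)
        res = km_logrank(np.array([0, 0, 0, 1, 1, 1.0]), np.concatenate([t1, t2]), np.ones(6, bool))
        assert res.logrank_statistic == pytest.approx(expected, abs=1e-10)

    def test_protective_ratio_orders_median_survival(self, response_sim):
        merged = response_sim.data.merge(glut_ratio(response_sim.data), on=["patient_id", "timepoint"])
        pre = merged[merged["timepoint"] == "pre"]
        res = km_logrank(pre["glut_ratio"], pre["pfs_time"], pre["event"])
        assert res.median_survival["high"] >= res.median_survival["low"]

    def test_all_censored_rejected(self):
        with pytest.raises(SurvivalModelError):
            km_logrank(np.arange(6.0), np.arange(1.0, 7.0), np.zeros(6, bool))


class TestCoxAssoc:
    def test_matches_brute_force_partial_likelihood(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0] * 2)
        times = np.arange(1.0, 13.0)
        events = np.ones(12, bool)
        res = cox_assoc(x, times, events)
        assert res.coef == pytest.approx(cox_partial_likelihood_mle(x, times, events), abs=1e-5)

    def test_recovers_generator_hazard(self):
        sim = generate_response_cohort(ResponseSimParams(n_patients=2000, seed=3))
        merged = sim.data.merge(glut_ratio(sim.data), on=["patient_id", "timepoint"])
        pre = merged[merged["timepoint"] == "pre"].set_index("patient_id")
        res = cox_assoc(sim.truth["z"].reindex(pre.index), pre["pfs_time"], pre["event"])
        assert res.hazard_ratio == pytest.approx(np.exp(-0.3), rel=0.05)
        assert res.ci_low < np.exp(-0.3) < res.ci_high

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            cox_assoc(np.arange(5.0), np.arange(1.0, 6.0), np.ones(5, bool))
        with pytest.raises(ParameterError):
            cox_assoc(np.arange(12.0), np.arange(1.0, 13.0), np.zeros(12, bool))


class TestWaterfall:
    def test_single_paired_patient_skips_correlations(self):
        cohort = pd.concat(
            [make_cohort([1.0], [2.0], timepoint="pre"), make_cohort([1.0], [3.0], timepoint="on")],
            ignore_index=True,
        )
        ratios = glut_ratio(cohort)
        with pytest.warns(UserWarning):
            table, corrs = waterfall_table(cohort, ratios)
        assert len(table) == 1
        assert corrs == {}

    def test_no_change_surfaces_degenerate_correlation_as_warning(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0])
        cohort = pd.concat(
            [make_cohort(g1, 2 * g1, timepoint="pre"), make_cohort(g1, 2 * g1, timepoint="on")],
            ignore_index=True,
        )
        ratios = glut_ratio(cohort, pseudocount=1e-12)
        with pytest.warns(UserWarning):
            table, corrs = waterfall_table(cohort, ratios)
        assert np.allclose(table["pct_change"], 0.0, atol=1e-6)

    def test_sorted_for_plotting(self, response_sim):
        ratios = glut_ratio(response_sim.data)
        table, _ = waterfall_table(response_sim.data, ratios)
        assert table["pct_change"].is_monotonic_decreasing

    def test_negative_baseline_change_coupling(self, response_sim):
        ratios = glut_ratio(response_sim.data)
        _, corrs = waterfall_table(response_sim.data, ratios)
        assert corrs["overall"].r <= -0.4
        assert abs(corrs["PD"].r) <= 0.2
        assert corrs["SD"].r < 0 and corrs["PR_CR"].r < 0

    def test_unpaired_cohort_rejected(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], timepoint="pre")
        with pytest.raises(ParameterError):
            waterfall_table(cohort, glut_ratio(cohort))


class TestValidation:
    def test_duplicate_patient_timepoint_rejected(self):
        cohort = make_cohort([1.0, 2.0], [1.0, 2.0])
        cohort.loc[1, "patient_id"] = "p0"
        with pytest.raises(ParameterError):
            validate_response_cohort(cohort)
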