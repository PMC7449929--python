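import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glutme.enrichment import IMMUNE_SCORE_COLUMN
from glutme.exceptions import DegenerateInputError, NoValleyError, ParameterError
from glutme.stratification import (
    IMMUNE_POOR,
    IMMUNE_RICH,
    assign_clusters,
    conditional_correlations,
    correlation_panel,
    find_split_threshold,
    kde_density,
    pearson,
    stratify_scores,
)
from oracles import pearson_closed_form


class TestKdeDensity:
    def test_symmetric_input_gives_symmetric_density(self):
        rng = np.random.default_rng(3)
        half = rng.normal(1.0, 0.3, 300)
        values = np.concatenate([half, -half])  # exactly symmetric about 0
        curve = kde_density(values)
        assert np.allclose(curve.grid, -curve.grid[::-1], atol=1e-9)
        assert np.allclose(curve.density, curve.density[::-1], atol=1e-6)

    def test_integrates_to_one(self, rng):
        curve = kde_density(rng.gamma(2.0, 1.0, 500))
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_recovers_standard_normal_density(self):
        rng = np.random.default_rng(42)
        curve = kde_density(rng.normal(0, 1, 10_000))
        assert np.max(np.abs(curve.density - stats.norm.pdf(curve.grid))) <= 0.02

    def test_grid_has_512_points_with_3bw_margin(self, rng):
        values = rng.normal(size=100)
        curve = kde_density(values)
        assert len(curve.grid) == 512
        assert curve.grid[0] == pytest.approx(values.min() - 3 * curve.bandwidth)
        assert curve.grid[-1] == pytest.approx(values.max() + 3 * curve.bandwidth)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateInputError):
            kde_density(np.ones(10))
        with pytest.raises(ParameterError):
            kde_density([1.0, 2.0, 3.0])
        with pytest.raises(ParameterError):
            kde_density([1.0, 2.0, np.nan, 4.0])
        with pytest.raises(ParameterError):
            kde_density(np.arange(10.0), bandwidth_rule="fixed")


class TestFindSplitThreshold:
    def _mixture(self, weights, n, seed):
        rng = np.random.default_rng(seed)
        n0 = int(round(weights[0] * n))
        return np.concatenate([rng.normal(0.2, 0.05, n0), rng.normal(0.8, 0.05, n - n0)])

    def test_equal_weight_mixture_valley_near_midpoint(self):
        values = self._mixture((0.5, 0.5), 1000, seed=7)
        threshold = find_split_threshold(kde_density(values))
        assert 0.40 <= threshold <= 0.60

    def test_skewed_mixture_valley_stays_between_modes(self):
        values = self._mixture((0.9, 0.1), 2000, seed=11)
        threshold = find_split_threshold(kde_density(values))
        assert 0.3 < threshold < 0.75

    def test_unimodal_raises_no_valley(self, rng):
        with pytest.raises(NoValleyError):
            find_split_threshold(kde_density(rng.normal(0, 1, 500)))


class TestAssignClusters:
    def test_basic_labels(self):
        clusters = assign_clusters(pd.Series({"s1": 0.1, "s2": 0.9}), threshold=0.5)
        assert clusters.labels.tolist() == [IMMUNE_POOR, IMMUNE_RICH]

    def test_boundary_score_is_poor(self):
        clusters = assign_clusters(pd.Series({"s1": 0.5, "s2": 0.9}), threshold=0.5)
        assert clusters.labels["s1"] == IMMUNE_POOR

    def test_pipeline_recovers_generator_clusters(self, bulk_cohort, bulk_scores):
        clusters = stratify_scores(bulk_scores[IMMUNE_SCORE_COLUMN])
        agreement = (clusters.labels == bulk_cohort.cluster_truth).mean()
        assert agreement >= 0.90


class TestPearson:
    def test_exact_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = pearson(x, y)
            assert res.r == pytest.approx(pearson_closed_form(x, y), abs=1e-12)
            assert abs(res.r) <= 1.0
            # two-sided p from the t distribution with n-2 df
            t = res.r * np.sqrt(18 / (1 - res.r**2))
            assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ParameterError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestCorrelationPanel:
    def test_self_feature_has_unit_correlation(self, bulk_scores, bulk_cohort):
        features = bulk_cohort.features()
        features["B_copy"] = bulk_scores["B_cells"]
        panel = correlation_panel(bulk_scores, features)
        assert panel["r"].loc["B_cells", "B_copy"] == pytest.approx(1.0)

    def test_permutation_invariance(self, bulk_scores, bulk_cohort):
        features = bulk_cohort.features()
        perm = np.random.default_rng(5).permutation(bulk_scores.index)
        base = correlation_panel(bulk_scores, features)
        shuffled = correlation_panel(bulk_scores.loc[perm], features.loc[perm])
        pd.testing.assert_frame_equal(base["r"], shuffled["r"])

    def test_majority_sign_pattern(self, bulk_scores, bulk_cohort):
        panel = correlation_panel(bulk_scores, bulk_cohort.features())
        immune_rows = panel["r"].loc[list(bulk_cohort.signatures.immune_summands)]
        assert (immune_rows["GLUT1"] < 0).mean() > 0.5
        assert (immune_rows["GLUT3"] > 0).mean() > 0.5

    def test_too_few_shared_samples(self, bulk_scores, bulk_cohort):
        with pytest.raises(ParameterError):
            correlation_panel(bulk_scores.iloc[:2], bulk_cohort.features().iloc[:2])


class TestConditionalCorrelations:
    def test_null_split_of_uncorrelated_cohort(self):
        rng = np.random.default_rng(19)
        n = 2000
        idx = pd.Index([f"s{i}" for i in range(n)])
        tlr = pd.Series(rng.normal(size=n), index=idx)
        features = pd.DataFrame({"x": rng.normal(size=n)}, index=idx)
        labels = pd.Series(rng.choice([IMMUNE_POOR, IMMUNE_RICH], size=n), index=idx)
        clusters = assign_clusters(pd.Series(0.0, index=idx), 0.5)
        clusters.labels = labels
        table = conditional_correlations(tlr, features, clusters)
        assert (table["r"].abs() <= 0.1).all()

    def test_sign_reproduction_on_default_cohort(self, bulk_cohort, bulk_scores):
        clusters = stratify_scores(bulk_scores[IMMUNE_SCORE_COLUMN])
        features = bulk_cohort.features().drop(columns="TLRmax")
        table = conditional_correlations(bulk_cohort.tlr_max, features, clusters).set_index(
            ["cluster", "feature"]
        )
        assert table.loc[(IMMUNE_POOR, "GLUT1"), "r"] > 0
        assert table.loc[(IMMUNE_RICH, "GLUT3"), "r"] > 0

    def test_small_cluster_skipped(self, bulk_cohort):
        idx = bulk_cohort.samples.index
        labels = pd.Series(IMMUNE_POOR, index=idx)
        labels.iloc[0] = IMMUNE_RICH  # singleton cluster
        clusters = assign_clusters(pd.Series(0.0, index=idx), 0.5)
        clusters.labels = labels
        table = conditional_correlations(bulk_cohort.tlr_max, bulk_cohort.features(), clusters)
        assert set(table["cluster"]) == {IMMUNE_POOR}
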