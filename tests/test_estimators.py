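import math

import numpy as np
import pytest
from scipy import stats

from nestpower.datagen import NestedDataset, generate_design_b
from nestpower.estimators import (
    METHODS,
    fixed_effects_dummies,
    lmm_covariate,
    lmm_intercept,
    lmm_intercept_slope,
    paired_ttest_means,
    ttest_cluster_means,
    ttest_individual,
)
from nestpower.exceptions import UsageError
from nestpower.params import DesignSpec, resolve_params


def dataset_from_cells(cell_values, design="B"):
    """Build a design-B dataset from per-cluster (control_obs, experimental_obs)."""
    cluster, condition, y = [], [], []
    for j, (c_obs, e_obs) in enumerate(cell_values):
        for v in c_obs:
            cluster.append(j), condition.append(0), y.append(v)
        for v in e_obs:
            cluster.append(j), condition.append(1), y.append(v)
    return NestedDataset(cluster, condition, y, design=design)


@pytest.fixture()
def balanced_data():
    spec = DesignSpec("B", 12, 6)
    params = resolve_params(d=0.4, icc=0.3, var_u1=0.08)
    return generate_design_b(spec, params, seed=100)


class TestTtestIndividual:
    def test_noiseless(self, fixtures):
        r = ttest_individual(fixtures["noiseless_b"].dataset)
        assert r.estimate == pytest.approx(2.0)
        assert r.se == 0.0 and r.p_value == 0.0  # degenerate, flagged via se == 0

    def test_matches_scipy(self):
        spec = DesignSpec("B", 10, 4)
        data = generate_design_b(spec, resolve_params(d=0.3, icc=0.0), seed=1)
        r = ttest_individual(data)
        ref = stats.ttest_ind(data.y[data.condition == 1], data.y[data.condition == 0])
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert r.df == len(data) - 2

    def test_welch_matches_scipy(self):
        spec = DesignSpec("B", 10, 4)
        data = generate_design_b(spec, resolve_params(d=0.3, icc=0.2), seed=2)
        r = ttest_individual(data, welch=True)
        ref = stats.ttest_ind(
            data.y[data.condition == 1], data.y[data.condition == 0], equal_var=False
        )
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_missing_condition(self):
        data = NestedDataset([0, 0, 1, 1], [0, 0, 0, 0], [1.0, 2.0, 3.0, 4.0], design="B")
        with pytest.raises(UsageError):
            ttest_individual(data)


class TestPairedTtestMeans:
    def test_hand_oracle(self):
        # cluster condition means (0,1), (1,3), (2,2) -> differences (1, 2, 0)
        data = dataset_from_cells(
            [([0.0, 0.0], [1.0, 1.0]), ([1.0, 1.0], [3.0, 3.0]), ([2.0, 2.0], [2.0, 2.0])]
        )
        r = paired_ttest_means(data)
        assert r.estimate == pytest.approx(1.0)
        assert r.se == pytest.approx(0.5773502691896258, abs=1e-12)
        assert r.statistic == pytest.approx(1.732050807568877, abs=1e-12)
        assert r.df == 2

    def test_matches_scipy_on_means(self, balanced_data):
        r = paired_ttest_means(balanced_data)
        ids = np.unique(balanced_data.cluster)
        diffs = []
        for j in ids:
            mask = balanced_data.cluster == j
            diffs.append(
                balanced_data.y[mask & (balanced_data.condition == 1)].mean()
                - balanced_data.y[mask & (balanced_data.condition == 0)].mean()
            )
        ref = stats.ttest_1samp(diffs, 0.0)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_differences_flagged(self):
        data = dataset_from_cells([([0.0, 0.0], [1.0, 1.0])] * 3)
        r = paired_ttest_means(data)
        assert r.estimate == pytest.approx(1.0)
        assert r.se == 0.0 and r.p_value == 0.0

    def test_missing_condition_names_cluster(self):
        data = NestedDataset(
            [0, 0, 1, 1, 2, 2], [0, 1, 0, 1, 0, 0], np.arange(6.0), design="B"
        )
        with pytest.raises(UsageError, match="cluster 2"):
            paired_ttest_means(data)


class TestTtestClusterMeans:
    def test_hand_oracle(self):
        # 2 + 2 clusters with means (0, 2) vs (1, 3)
        cluster = [0, 0, 1, 1, 2, 2, 3, 3]
        condition = [0, 0, 0, 0, 1, 1, 1, 1]
        y = [0.0, 0.0, 2.0, 2.0, 1.0, 1.0, 3.0, 3.0]
        r = ttest_cluster_means(NestedDataset(cluster, condition, y, design="A"))
        assert r.estimate == pytest.approx(1.0)
        assert r.statistic == pytest.approx(0.7071067811865476, abs=1e-12)
        assert r.df == 2

    def test_equal_means_p_one(self):
        cluster = [0, 0, 1, 1, 2, 2, 3, 3]
        condition = [0, 0, 0, 0, 1, 1, 1, 1]
        y = [1.0, 3.0, 2.0, 2.0, 0.0, 4.0, 3.0, 1.0]  # all cluster means 2
        r = ttest_cluster_means(NestedDataset(cluster, condition, y, design="A"))
        assert r.estimate == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_requires_design_a(self, balanced_data):
        with pytest.raises(UsageError):
            ttest_cluster_means(balanced_data)

    def test_too_few_clusters(self):
        data = NestedDataset([0, 0, 1, 1], [0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0], design="A")
        with pytest.raises(UsageError):
            ttest_cluster_means(data)


def mixedlm_reference(data, random_slope):
    import statsmodels.api as sm

    x = data.condition.astype(float)
    exog = np.column_stack([np.ones_like(x), x])
    exog_re = np.column_stack([np.ones_like(x), x]) if random_slope else None
    model = sm.MixedLM(data.y, exog, groups=data.cluster, exog_re=exog_re)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=True, method="lbfgs")


class TestLmmIntercept:
    def test_estimate_equals_mean_difference(self, balanced_data):
        r = lmm_intercept(balanced_data)
        naive = (
            balanced_data.y[balanced_data.condition == 1].mean()
            - balanced_data.y[balanced_data.condition == 0].mean()
        )
        assert r.estimate == pytest.approx(naive, abs=1e-8)
        assert math.isinf(r.df)

    def test_matches_statsmodels(self):
        # closed-form balanced REML against the numeric optimizer
        spec = DesignSpec("B", 30, 10)
        data = generate_design_b(spec, resolve_params(d=0.4, icc=0.3), seed=200)
        r = lmm_intercept(data)
        ref = mixedlm_reference(data, random_slope=False)
        assert ref.converged
        assert r.estimate == pytest.approx(ref.fe_params[1], abs=1e-8)
        assert r.se == pytest.approx(ref.bse_fe[1], rel=1e-4)
        assert r.varcomp["var_e"] == pytest.approx(ref.scale, rel=1e-3)
        assert r.varcomp["var_u0"] == pytest.approx(ref.cov_re[0, 0], rel=1e-3, abs=1e-4)

    def test_boundary_recovery(self):
        spec = DesignSpec("B", 40, 10)
        data = generate_design_b(spec, resolve_params(d=0.2, icc=0.0), seed=201)
        r = lmm_intercept(data)
        assert r.varcomp["var_u0"] < 0.05
        assert r.converged

    def test_unbalanced_falls_back(self, balanced_data):
        sub = NestedDataset(
            balanced_data.cluster[1:], balanced_data.condition[1:],
            balanced_data.y[1:], design="B",
        )
        r = lmm_intercept(sub)
        ref = mixedlm_reference(sub, random_slope=False)
        assert r.estimate == pytest.approx(ref.fe_params[1], abs=1e-8)


class TestLmmInterceptSlope:
    def test_matches_statsmodels_interior(self):
        spec = DesignSpec("B", 200, 20)
        params = resolve_params(d=0.5, icc=0.25, var_u1=0.10, cov_u0u1=0.05)
        data = generate_design_b(spec, params, seed=2)
        r = lmm_intercept_slope(data)
        ref = mixedlm_reference(data, random_slope=True)
        assert ref.converged
        assert r.estimate == pytest.approx(ref.fe_params[1], abs=1e-8)
        assert r.se == pytest.approx(ref.bse_fe[1], rel=1e-3)
        assert r.varcomp["var_e"] == pytest.approx(ref.scale, rel=1e-3)
        assert r.varcomp["var_u0"] == pytest.approx(ref.cov_re[0, 0], rel=1e-2)
        assert r.varcomp["var_u1"] == pytest.approx(ref.cov_re[1, 1], rel=1e-2)
        assert r.varcomp["cov_u0u1"] == pytest.approx(ref.cov_re[0, 1], rel=1e-2, abs=1e-3)

    def test_equals_paired_means_estimate(self, balanced_data):
        full = lmm_intercept_slope(balanced_data)
        paired = paired_ttest_means(balanced_data)
        assert full.estimate == pytest.approx(paired.estimate, abs=1e-6)

    def test_parameter_recovery(self):
        # simulation-based calibration: means over replicates close to truth
        spec = DesignSpec("B", 200, 20)
        params = resolve_params(d=0.5, icc=0.25, var_u1=0.10)
        ests, v0s, v1s = [], [], []
        ss = np.random.SeedSequence(77)
        for child in ss.spawn(200):
            data = generate_design_b(spec, params, np.random.default_rng(child))
            r = lmm_intercept_slope(data)
            ests.append(r.estimate)
            v0s.append(r.varcomp["var_u0"])
            v1s.append(r.varcomp["var_u1"])
        for observed, truth in (
            (ests, 0.5),
            (v0s, params.var_u0),
            (v1s, 0.10),
        ):
            observed = np.asarray(observed)
            mc_se = observed.std(ddof=1) / math.sqrt(observed.size)
            assert abs(observed.mean() - truth) < 3 * mc_se + 1e-3

    def test_requires_two_per_cell(self):
        data = NestedDataset([0, 0, 1, 1], [0, 1, 0, 1], [1.0, 2.0, 3.0, 4.0], design="B")
        with pytest.raises(UsageError):
            lmm_intercept_slope(data)

    def test_slope_boundary_uses_intercept_model_se(self):
        spec = DesignSpec("B", 10, 5)
        data = generate_design_b(spec, resolve_params(d=0.3, icc=0.2), seed=55)
        r = lmm_intercept_slope(data)
        if r.varcomp["var_u1"] == 0.0:
            ri = lmm_intercept(data)
            assert r.se == pytest.approx(ri.se)


class TestFixedEffectsDummies:
    def test_noiseless(self, fixtures):
        r = fixed_effects_dummies(fixtures["noiseless_b"].dataset)
        assert r.estimate == pytest.approx(2.0)

    def test_matches_statsmodels_ols(self, balanced_data):
        import statsmodels.api as sm

        r = fixed_effects_dummies(balanced_data)
        x = balanced_data.condition.astype(float)
        dummies = (balanced_data.cluster[:, None] == np.unique(balanced_data.cluster)[1:]).astype(float)
        exog = np.column_stack([np.ones_like(x), x, dummies])
        ref = sm.OLS(balanced_data.y, exog).fit()
        assert r.estimate == pytest.approx(ref.params[1], abs=1e-10)
        assert r.se == pytest.approx(ref.bse[1], abs=1e-10)
        assert r.df == ref.df_resid

    def test_equals_paired_means_estimate(self, balanced_data):
        assert fixed_effects_dummies(balanced_data).estimate == pytest.approx(
            paired_ttest_means(balanced_data).estimate, abs=1e-8
        )

    def test_rank_deficiency(self):
        data = NestedDataset([0, 0, 1, 1], [0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0], design="B")
        with pytest.raises(UsageError):
            fixed_effects_dummies(data)


class TestLmmCovariate:
    @staticmethod
    def _covariate_data(frac, seed, n_clusters=400, nc=10, var_u1=0.10):
        from nestpower.datagen import generate_with_cluster_covariate

        spec = DesignSpec("B", n_clusters, nc)
        params = resolve_params(d=0.5, icc=0.25, var_u1=var_u1)
        return generate_with_cluster_covariate(spec, params, frac, seed=seed)

    def test_null_covariate_recovers_var_u1(self):
        data = self._covariate_data(0.0, seed=300)
        r = lmm_covariate(data)
        assert r.varcomp["var_u1"] == pytest.approx(0.10, abs=0.03)

    def test_variance_partition(self):
        v1s = []
        ss = np.random.SeedSequence(301)
        for child in ss.spawn(30):
            data = self._covariate_data(0.5, seed=np.random.default_rng(child))
            v1s.append(lmm_covariate(data).varcomp["var_u1"])
        assert np.mean(v1s) == pytest.approx(0.05, abs=0.01)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        data = self._covariate_data(0.5, seed=304, n_clusters=80, nc=8)
        r = lmm_covariate(data)
        x = data.condition.astype(float)
        exog = np.column_stack([np.ones_like(x), x, data.w, data.w * x])
        exog_re = np.column_stack([np.ones_like(x), x])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(data.y, exog, groups=data.cluster, exog_re=exog_re).fit(
                reml=True, method="lbfgs"
            )
        assert ref.converged
        assert r.estimate == pytest.approx(ref.fe_params[1], abs=1e-6)
        assert r.se == pytest.approx(ref.bse_fe[1], rel=5e-3)

    def test_requires_w(self, balanced_data):
        with pytest.raises(UsageError):
            lmm_covariate(balanced_data)

    def test_w_must_be_cluster_constant(self):
        data = NestedDataset(
            [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2],
            [0, 0, 1, 1] * 3,
            list(np.arange(12.0)),
            design="B",
            w=[0.1, 0.2, 0.1, 0.1] + [1.0] * 4 + [2.0] * 4,
        )
        with pytest.raises(UsageError):
            lmm_covariate(data)


class TestCrossMethodProperties:
    def test_point_estimates_agree_on_balanced_data(self, balanced_data):
        estimates = [
            ttest_individual(balanced_data).estimate,
            paired_ttest_means(balanced_data).estimate,
            lmm_intercept(balanced_data).estimate,
            lmm_intercept_slope(balanced_data).estimate,
            fixed_effects_dummies(balanced_data).estimate,
        ]
        assert np.ptp(estimates) < 1e-6

    @pytest.mark.parametrize(
        "method",
        ["ttest_individual", "paired_ttest_means", "lmm_intercept",
         "lmm_intercept_slope", "fixed_effects_dummies"],
    )
    def test_cluster_relabel_invariance(self, method, balanced_data):
        base = METHODS[method](balanced_data)
        relabeled = NestedDataset(
            997 - balanced_data.cluster * 7, balanced_data.condition,
            balanced_data.y, design="B",
        )
        alt = METHODS[method](relabeled)
        assert alt.p_value == pytest.approx(base.p_value, abs=1e-10)
        assert alt.estimate == pytest.approx(base.estimate, abs=1e-10)

    @pytest.mark.parametrize(
        "method",
        ["ttest_individual", "paired_ttest_means", "lmm_intercept",
         "lmm_intercept_slope", "fixed_effects_dummies"],
    )
    def test_location_scale_equivariance(self, method, balanced_data):
        base = METHODS[method](balanced_data)
        shifted = NestedDataset(
            balanced_data.cluster, balanced_data.condition,
            balanced_data.y + 5.0, design="B",
        )
        scaled = NestedDataset(
            balanced_data.cluster, balanced_data.condition,
            balanced_data.y * 3.0, design="B",
        )
        assert METHODS[method](shifted).estimate == pytest.approx(base.estimate, abs=1e-8)
        r_scaled = METHODS[method](scaled)
        assert r_scaled.estimate == pytest.approx(3.0 * base.estimate, abs=1e-8)
        assert r_scaled.se == pytest.approx(3.0 * base.se, rel=1e-8)

    def test_p_values_in_unit_interval(self, balanced_data):
        for name in ("ttest_individual", "paired_ttest_means", "lmm_intercept",
                     "lmm_intercept_slope", "fixed_effects_dummies"):
            assert 0.0 <= METHODS[name](balanced_data).p_value <= 1.0
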