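"""Estimator correctness: hand-solved oracles, robust SEs, IV properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import teleiv as tv
from teleiv.design import make_design
from teleiv.iv import (
    DegenerateOutcomeError,
    RobustOLS,
    SingularDesignError,
    TwoStageLS,
    WeakInstrumentError,
    Z_CRIT,
    fit_2sls,
    fit_ols,
)

# 6-point hand dataset used by several oracles.
_X6 = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
_Y6 = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.9])


class TestOLS:
    def test_six_point_normal_equations(self):
        # Oracle: solve the 2-unknown normal equations directly from the
        # summed moments.
        n, sx, sy = 6, _X6.sum(), _Y6.sum()
        sxx, sxy = (_X6**2).sum(), (_X6 * _Y6).sum()
        oracle = np.linalg.solve([[n, sx], [sx, sxx]], [sy, sxy])
        res = fit_ols(_Y6, np.column_stack([np.ones(6), _X6]), ["const", "x"])
        np.testing.assert_allclose(res.params, oracle, atol=1e-10)

    def test_exact_fit_zero_residuals_and_ses(self):
        y = 2.0 + 3.0 * _X6
        res = fit_ols(y, np.column_stack([np.ones(6), _X6]))
        np.testing.assert_allclose(res.resid, 0, atol=1e-12)
        np.testing.assert_allclose(res.bse, 0, atol=1e-12)

    def test_hc1_close_to_classical_when_homoskedastic(self):
        # In the homoskedastic limit the HC1 sandwich SE and the classical
        # SE agree on average.
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(2000):
            x = rng.standard_normal(100)
            y = 1 + 2 * x + rng.standard_normal(100)
            X = np.column_stack([np.ones(100), x])
            robust = fit_ols(y, X).bse[1]
            classical = fit_ols(y, X, robust=False).bse[1]
            ratios.append(robust / classical)
        assert abs(np.mean(ratios) - 1) < 0.05

    def test_hc1_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(80), rng.standard_normal((80, 2))])
        y = X @ [1.0, 0.5, -2.0] + rng.standard_normal(80) * (
            1 + 0.5 * np.abs(X[:, 1])
        )
        res = fit_ols(y, X)
        ref = sm.OLS(y, X).fit(cov_type="HC1")
        np.testing.assert_allclose(res.params, ref.params, rtol=1e-10)
        np.testing.assert_allclose(res.bse, ref.bse, rtol=1e-8)

    def test_singular_design_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(SingularDesignError) as exc:
            fit_ols(np.zeros(20), X, ["const", "a", "twice_a"])
        assert set(exc.value.columns) & {"a", "twice_a"}

    def test_confidence_interval_uses_stated_critical_value(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        res = fit_ols(y, np.column_stack([np.ones(50), x]))
        ci = res.conf_int()
        np.testing.assert_allclose(
            ci[:, 0], res.params - Z_CRIT * res.bse, rtol=1e-12
        )


class TestTwoStageLS:
    def _toy(self, n=500, seed=0, gamma=1.0):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(n)          # confounder
        z = rng.standard_normal(n)
        w = rng.standard_normal(n)
        t = 0.8 * z + 0.3 * w + gamma * u + rng.standard_normal(n)
        y = 2.0 * t + 0.5 * w + gamma * u + rng.standard_normal(n)
        W = np.column_stack([np.ones(n), w])
        return y, t, z, W

    def test_equals_ols_when_instrument_is_treatment(self):
        y, t, _, W = self._toy()
        iv_res = fit_2sls(y, t, t, W, exog_names=["const", "w"])
        ols = fit_ols(y, np.column_stack([t, W]), ["treatment", "const", "w"])
        np.testing.assert_allclose(iv_res.params, ols.params, rtol=1e-12)
        np.testing.assert_allclose(iv_res.bse, ols.bse, rtol=1e-10)

    def test_six_point_indirect_least_squares_oracle(self):
        # Just-identified 2SLS equals the ratio of the reduced-form to the
        # first-stage coefficient after partialling the covariate
        # (Frisch-Waugh oracle computed independently).
        z = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        w = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        t = np.array([0.2, 0.9, 0.1, 1.1, 0.8, 0.3])
        y = np.array([0.5, 2.1, 0.3, 2.6, 1.8, 0.9])
        W = np.column_stack([np.ones(6), w])

        def partial(v):
            coef, *_ = np.linalg.lstsq(W, v, rcond=None)
            return v - W @ coef

        zt, tt, yt = partial(z), partial(t), partial(y)
        oracle = (zt @ yt) / (zt @ tt)
        res = fit_2sls(y, t, z, W)
        assert res.params[0] == pytest.approx(oracle, abs=1e-10)

    def test_matches_statsmodels_iv2sls(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        y, t, z, W = self._toy(seed=5)
        res = fit_2sls(y, t, z, W, exog_names=["const", "w"])
        ref = IV2SLS(y, np.column_stack([t, W]), np.column_stack([z, W])).fit()
        np.testing.assert_allclose(res.params, ref.params, rtol=1e-8)

    def test_recovers_truth_under_confounding_where_ols_fails(self):
        y, t, z, W = self._toy(n=5000, seed=7, gamma=1.0)
        iv_res = fit_2sls(y, t, z, W)
        ols = fit_ols(y, np.column_stack([t, W]), ["t", "const", "w"])
        assert abs(iv_res.params[0] - 2.0) < 3 * iv_res.bse[0]
        assert abs(ols.params[0] - 2.0) > 3 * ols.bse[0]

    def test_constant_instrument_after_partialling_rejected(self):
        y, t, _, W = self._toy()
        z = 0.5 * W[:, 1] + 2.0  # in the span of [const, w]
        with pytest.raises(WeakInstrumentError):
            fit_2sls(y, t, z, W)

    def test_first_stage_f_decreases_with_first_stage_noise(self):
        # Robust first-stage F should fall monotonically as noise is added
        # to the treatment equation (trend over replicate means).
        rng = np.random.default_rng(1)
        grid = [0.5, 1.0, 2.0, 4.0, 8.0]
        means = []
        for sd in grid:
            fs = []
            for _ in range(30):
                z = rng.standard_normal(400)
                t = z + sd * rng.standard_normal(400)
                y = t + rng.standard_normal(400)
                res = fit_2sls(y, t, z, np.ones((400, 1)))
                fs.append(res.first_stage_F)
            means.append(np.mean(fs))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestModelBattery:
    def test_scale_linearity(self, default_cohort):
        a = default_cohort["analytic"]
        r100 = tv.run_primary(a, scale=100.0)
        r1 = tv.run_primary(a, scale=1.0)
        for g in r100:
            assert r100[g].estimate == pytest.approx(100 * r1[g].estimate)
            assert r100[g].robust_se == pytest.approx(100 * r1[g].robust_se)

    def test_primary_returns_all_strata(self, default_cohort):
        results = tv.run_primary(default_cohort["analytic"])
        assert set(results) == set(tv.DIAGNOSIS_GROUPS) | {"overall"}
        for fr in results.values():
            assert fr.estimator == "tsls"
            assert fr.first_stage_F > 10  # strong by construction
            assert fr.ci_low == pytest.approx(
                fr.estimate - Z_CRIT * fr.robust_se
            )

    def test_tiny_stratum_skipped(self, default_cohort):
        a = default_cohort["analytic"]
        small = a.loc[a["diagnosis_group"] != "preoperative_evaluation"].copy()
        keep = a.loc[a["diagnosis_group"] == "preoperative_evaluation"].head(5)
        results = tv.run_primary(pd.concat([small, keep], ignore_index=True))
        assert "preoperative_evaluation" not in results
        assert "overall" in results

    def test_reference_level_invariance(self, default_cohort):
        # The treatment effect is invariant to which insurance category is
        # the omitted reference.
        a = default_cohort["analytic"]
        sub = a.loc[a["diagnosis_group"] == "dyslipidemia"]
        levels = sorted(sub["insurance"].unique())
        fits = []
        for ref in ("Private", "Medicare"):
            cats = {"insurance": [ref] + [l for l in levels if l != ref]}
            di = make_design(sub, categories=cats)
            res = TwoStageLS(
                sub["outcome_count"].to_numpy(float),
                sub["treatment"].to_numpy(float),
                sub["instrument"].to_numpy(float),
                di.X, endog_names=["treatment"], exog_names=di.names,
            ).fit()
            fits.append(res.params[0])
        assert fits[0] == pytest.approx(fits[1], abs=1e-10)

    def test_binary_outcome_without_variance_rejected(self, default_cohort):
        a = default_cohort["analytic"].copy()
        a["any_followup"] = 1
        with pytest.raises(DegenerateOutcomeError):
            tv.run_sensitivities(a, which=("binary",))

    def test_binary_sensitivity_reported_in_percentage_points(
        self, default_cohort
    ):
        res = tv.run_sensitivities(
            default_cohort["analytic"], which=("binary",)
        )["binary"]
        assert res["overall"].spec.outcome == "any_followup"
        assert -100 <= res["overall"].estimate <= 100

    def test_covariate_free_matches_adjusted_when_no_covariate_effects(self):
        cfg = tv.recovery_config(
            seed=99, npv_per_clinician_mean=125.0, covariate_effects={}
        )
        visits, _ = tv.generate_study_log(cfg)
        a, _ = tv.build_cohort(visits, validate=False)
        adj = tv.run_primary(a)["overall"]
        noadj = tv.run_sensitivities(a, which=("nocov",))["nocov"]["overall"]
        tol = 2 * max(adj.robust_se, noadj.robust_se)
        assert abs(adj.estimate - noadj.estimate) < tol


@pytest.fixture(scope="module")
def null_effect_study():
    """200 replicates of a zero-effect generator: pooled 2SLS estimate/CI
    and the period-interaction contrast (true effect equal — zero — in both
    periods)."""
    rows = []
    for rep in range(200):
        cfg = tv.recovery_config(
            seed=60_000 + rep,
            npv_per_clinician_mean=50.0,
            effects_by_diagnosis={g: 0.0 for g in tv.DIAGNOSIS_GROUPS},
        )
        visits, _ = tv.generate_study_log(cfg)
        a, _ = tv.build_cohort(visits, validate=False)
        di = make_design(a, covariates=True, diagnosis_fe=True)
        y = a["outcome_count"].to_numpy(float)
        t = a["treatment"].to_numpy(float)
        z = a["instrument"].to_numpy(float)
        pooled = TwoStageLS(
            y, t, z, di.X, endog_names=["treatment"], exog_names=di.names
        ).fit()
        late = (a["period"] == "p2022_23").to_numpy(float)
        inter = TwoStageLS(
            y, np.column_stack([t, t * late]), np.column_stack([z, z * late]),
            di.X, endog_names=["treatment", "treatment_x_late"],
            exog_names=di.names,
        ).fit()
        rows.append(
            {
                "pooled": pooled.params[0], "pooled_se": pooled.bse[0],
                "inter": inter.params[1], "inter_se": inter.bse[1],
            }
        )
    return pd.DataFrame(rows)


class TestNullCalibration:
    def test_pooled_ci_covers_zero_at_nominal_rate(self, null_effect_study):
        s = null_effect_study
        cover = (np.abs(s["pooled"]) <= Z_CRIT * s["pooled_se"]).mean()
        assert 0.90 <= cover <= 0.99

    def test_interaction_ci_covers_zero_when_effects_equal(
        self, null_effect_study
    ):
        s = null_effect_study
        cover = (np.abs(s["inter"]) <= Z_CRIT * s["inter_se"]).mean()
        assert 0.90 <= cover <= 0.99


class TestBiasOrdering:
    def test_ols_overshoots_while_2sls_does_not(self, recovery_study):
        # With positive confound_treat * confound_outcome, OLS overstates
        # every stratum effect while 2SLS does not (one-sided t test on the
        # replicate means, alpha=0.01).
        s = recovery_study
        for g, sub in s.groupby("stratum"):
            ols_err = sub["ols_estimate"] - sub["truth"]
            iv_err = sub["estimate"] - sub["truth"]
            t_ols = stats.ttest_1samp(ols_err, 0, alternative="greater")
            assert t_ols.pvalue < 0.01, g
            t_iv = stats.ttest_1samp(iv_err, 0, alternative="greater")
            assert t_iv.pvalue > 0.01, g
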