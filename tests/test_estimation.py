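"""Moments, 2SLS identities, Sargan, Holm and the BCa bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import latentiv as lv
from latentiv.estimation import (
    AnalysisConfig,
    ConstantColumnError,
    EstimationError,
    MomentSet,
    _bca_interval,
    _em_saturated,
    compute_moments,
    fit_from_moments,
    fit_miiv_sem,
    holm_adjust,
)
from latentiv.sem_model import parse_model
from conftest import make_eight_row_table


class TestComputeMoments:
    def test_complete_uses_denominator_n(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        m = compute_moments(df, "complete")
        X = df.to_numpy()
        expected = (X - X.mean(0)).T @ (X - X.mean(0)) / 50
        np.testing.assert_allclose(m.cov, expected, atol=1e-12)
        assert m.n_effective == 50 and m.source == "complete"

    def test_complete_rejects_missing_cells(self, cohort70):
        with pytest.raises(EstimationError, match="missing"):
            compute_moments(cohort70, "complete")

    def test_listwise_effective_n_is_67_of_70(self, cohort70):
        m = compute_moments(cohort70, "listwise")
        assert m.n_effective == 67
        assert m.source == "listwise"

    def test_em_equals_complete_when_nothing_missing(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        mc = compute_moments(df, "complete")
        me = compute_moments(df, "twostage_em")
        np.testing.assert_allclose(me.mean, mc.mean, atol=1e-10)
        np.testing.assert_allclose(me.cov, mc.cov, atol=1e-10)
        assert me.n_effective == 40

    def test_em_matches_hand_iteration_on_bivariate_toy(self):
        """Independent EM for a 4-row bivariate table with one missing cell:
        the conditional-expectation fill-in, iterated to convergence."""
        X = np.array([[1.0, 2.0], [2.0, 2.5], [3.0, 4.0], [4.0, np.nan]])
        mu = np.nanmean(X, axis=0)
        Xf = np.where(np.isnan(X), mu, X)
        S = (Xf - Xf.mean(0)).T @ (Xf - Xf.mean(0)) / 4
        for _ in range(2000):  # plain fixed-point iteration
            cond = mu[1] + S[0, 1] / S[0, 0] * (X[3, 0] - mu[0])
            filled = X.copy()
            filled[3, 1] = cond
            mu = filled.mean(axis=0)
            Sc = (filled - mu).T @ (filled - mu) / 4
            Sc[1, 1] += (S[1, 1] - S[0, 1] ** 2 / S[0, 0]) / 4
            S = Sc
        m = compute_moments(
            pd.DataFrame(X, columns=["a", "b"]), "twostage_em", tol=1e-14, max_iter=5000
        )
        np.testing.assert_allclose(m.mean, mu, atol=1e-6)
        np.testing.assert_allclose(m.cov, S, atol=1e-6)

    def test_non_numeric_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": ["x", "y", "z"]})
        with pytest.raises(EstimationError, match="non-numeric"):
            compute_moments(df, "complete")

    def test_listwise_with_everything_missing_fails(self):
        df = pd.DataFrame({"a": [np.nan, 1.0], "b": [2.0, np.nan]})
        with pytest.raises(EstimationError):
            compute_moments(df, "listwise")


class TestTwoSLS:
    def test_exact_line_recovered(self):
        df = pd.DataFrame({"x": np.arange(8.0)})
        df["y"] = 2.0 * df["x"]
        fit = fit_miiv_sem(df, "y ~ x", AnalysisConfig(bootstrap_B=0, missing="complete"))
        assert fit.params["beta_y_x"].estimate == pytest.approx(2.0, abs=1e-12)
        assert fit.params["alpha_y"].estimate == pytest.approx(0.0, abs=1e-12)
        assert fit.equations[0].residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_instruments_equal_regressors_is_ols(self, rng):
        """No latents -> every regressor is its own instrument -> OLS.
        Cross-checked against statsmodels."""
        import statsmodels.api as sm

        n = 60
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1.5 + 0.8 * x1 - 0.3 * x2 + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = fit_miiv_sem(df, "y ~ x1 + x2", AnalysisConfig(bootstrap_B=0, missing="complete"))
        assert fit.equations[0].instrument_names == ["x1", "x2"]
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        assert fit.params["alpha_y"].estimate == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.params["beta_y_x1"].estimate == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.params["beta_y_x2"].estimate == pytest.approx(ols.params[2], abs=1e-10)

    def test_stagewise_oracle_on_eight_row_table(self):
        """Moment-algebra 2SLS equals the literal two-stage computation:
        stage 1 regress x on (1, z1, z2); stage 2 regress y on (1, x_hat)."""
        df = make_eight_row_table()
        Z = np.column_stack([np.ones(8), df["z1"], df["z2"]])
        g, *_ = np.linalg.lstsq(Z, df["x"], rcond=None)
        xhat = Z @ g
        X2 = np.column_stack([np.ones(8), xhat])
        b, *_ = np.linalg.lstsq(X2, df["y"], rcond=None)

        mom = compute_moments(df, "complete")
        eq = lv.miiv_engine.TransformedEquation(
            "e", "y", [lv.miiv_engine.Regressor("x", True, "beta")], "alpha",
            {"zeta_y": 1}, "structural",
        )
        miivs = lv.miiv_engine.MIIVSet("e", frozenset(["z1", "z2"]), ["z1", "z2"])
        est = lv.fit_2sls_equation(eq, miivs, mom)
        assert est.slopes["beta"] == pytest.approx(b[1], abs=1e-8)
        assert est.intercept == pytest.approx(b[0], abs=1e-8)

    def test_moment_based_equals_observation_level(self, complete_cohort, brain_body_text):
        """Full fit from moments == fit where each equation is computed by the
        literal observation-level two-stage procedure on the rescaled data."""
        cfg = AnalysisConfig(bootstrap_B=0, missing="complete")
        fit = fit_miiv_sem(complete_cohort, brain_body_text, cfg)
        spec = parse_model(brain_body_text)
        plan = lv.sem_model.rescale_plan(spec)
        d = plan.apply(complete_cohort[list(spec.observed_vars)])
        for eqest in fit.equations:
            Z = np.column_stack(
                [np.ones(len(d))] + [d[z].to_numpy() for z in eqest.instrument_names]
            )
            X = np.column_stack(
                [np.ones(len(d))] + [d[x].to_numpy() for x in eqest.regressor_names]
            )
            y = d[eqest.outcome].to_numpy()
            xhat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
            b = np.linalg.lstsq(xhat, y, rcond=None)[0]
            got = [eqest.intercept] + [
                eqest.slopes[pid] for pid in eqest.slopes
            ]
            np.testing.assert_allclose(got, b, atol=1e-10)

    def test_collinear_instruments_rejected(self):
        df = pd.DataFrame({"x": np.arange(8.0)})
        df["y"] = 2.0 * df["x"] + 0.1 * np.sin(df["x"])
        df["x2"] = df["x"] * 2.0  # collinear regressor pair
        with pytest.raises(EstimationError):
            fit_miiv_sem(df, "y ~ x + x2", AnalysisConfig(bootstrap_B=0, missing="complete"))

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [5.0] * 4})
        with pytest.raises(ConstantColumnError):
            fit_miiv_sem(df, "y ~ x", AnalysisConfig(bootstrap_B=0, missing="complete"))


class TestScaleEquivariance:
    def _scaled_moments(self, mom, name, c):
        i = list(mom.names).index(name)
        mean = mom.mean.copy()
        cov = mom.cov.copy()
        mean[i] *= c
        cov[i, :] *= c
        cov[:, i] *= c
        return MomentSet(mom.names, mean, cov, mom.n_effective, mom.source)

    def test_non_scaling_indicator_scaling(self, brain_body_spec):
        """Multiplying cerebrum by c multiplies its loading and intercept by c
        and changes nothing else."""
        mom = lv.implied_moments(lv.default_params())
        base = fit_from_moments(brain_body_spec, mom)
        c = 3.7
        scaled = fit_from_moments(brain_body_spec, self._scaled_moments(mom, "cerebrum", c))
        for pid in base.params:
            expect = base.params[pid].estimate
            if pid in ("lambda_cerebrum", "alpha_cerebrum"):
                expect *= c
            assert scaled.params[pid].estimate == pytest.approx(expect, abs=1e-9), pid

    def test_scaling_indicator_rescales_latent_unit(self, brain_body_spec):
        """Multiplying TIV by c changes the brain latent's unit: paths into
        the latent (and its intercept) scale by c, paths and loadings out of
        it by 1/c; everything else is untouched."""
        mom = lv.implied_moments(lv.default_params())
        base = fit_from_moments(brain_body_spec, mom)
        c = 2.5
        scaled = fit_from_moments(brain_body_spec, self._scaled_moments(mom, "TIV", c))
        mapping = {
            "beta_brain_height": c,
            "alpha_brain": c,
            "lambda_cerebrum": 1 / c,
            "lambda_cerebellum": 1 / c,
            "beta_body_brain": 1 / c,
            "beta_fat_brain": 1 / c,
        }
        for pid in base.params:
            expect = base.params[pid].estimate * mapping.get(pid, 1.0)
            assert scaled.params[pid].estimate == pytest.approx(expect, abs=1e-9), pid


class TestSargan:
    def test_exactly_identified_equation_has_no_test(self, complete_cohort, brain_body_text):
        fit = fit_miiv_sem(complete_cohort, brain_body_text, AnalysisConfig(bootstrap_B=0, missing="complete"))
        brain = next(e for e in fit.equations if e.equation_id == "brain")
        assert brain.sargan_df == 0
        assert brain.sargan_p_raw is None and brain.sargan_p_holm is None

    def test_statistic_is_n_times_residual_r2(self, complete_cohort, brain_body_text):
        """Dual route: n * R^2 from an observation-level OLS of the 2SLS
        residual on the instruments equals the moment-algebra statistic."""
        cfg = AnalysisConfig(bootstrap_B=0, missing="complete")
        fit = fit_miiv_sem(complete_cohort, brain_body_text, cfg)
        spec = parse_model(brain_body_text)
        d = lv.sem_model.rescale_plan(spec).apply(complete_cohort[list(spec.observed_vars)])
        n = len(d)
        for eqest in fit.equations:
            if eqest.sargan_df == 0:
                continue
            X = np.column_stack([d[x].to_numpy() for x in eqest.regressor_names])
            u = (
                d[eqest.outcome].to_numpy()
                - eqest.intercept
                - X @ np.array(list(eqest.slopes.values()))
            )
            Z = np.column_stack(
                [np.ones(n)] + [d[z].to_numpy() for z in eqest.instrument_names]
            )
            uhat = Z @ np.linalg.lstsq(Z, u, rcond=None)[0]
            r2 = 1.0 - np.sum((u - uhat) ** 2) / np.sum((u - u.mean()) ** 2)
            assert eqest.sargan_stat == pytest.approx(n * r2, rel=1e-8)
            assert eqest.sargan_p_raw == pytest.approx(
                stats.chi2.sf(n * r2, eqest.sargan_df), rel=1e-8
            )


class TestHolm:
    def test_hand_computed_fixture(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged_and_all_ones(self):
        assert holm_adjust([0.2]) == [0.2]
        assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_none_passthrough_and_family_size(self):
        # the undefined entry must not inflate the multiplier (m = 2, not 3)
        assert holm_adjust([0.01, None, 0.04]) == pytest.approx([0.02, None, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_dominates_raw_monotone_idempotent(self, ps):
        adj = holm_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        order = np.argsort(ps)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-15 for i in range(len(ps) - 1)
        )
        # applying Holm to already-adjusted values keeps order-respecting caps
        assert max(adj) <= 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0001, 0.9999), min_size=1, max_size=10))
    def test_agrees_with_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(ps, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(ps), expected, atol=1e-12)


class TestBootstrap:
    def test_constant_statistic_collapses(self):
        df = pd.DataFrame({"x": np.arange(12.0)})
        df["y"] = 2.0 * df["x"]  # slope is 2 in every resample
        cfg = AnalysisConfig(bootstrap_B=100, seed=5, missing="complete")
        fit = fit_miiv_sem(df, "y ~ x", cfg)
        p = fit.params["beta_y_x"]
        assert p.se == pytest.approx(0.0, abs=1e-12)
        assert p.ci_low == pytest.approx(2.0) and p.ci_high == pytest.approx(2.0)

    def test_bca_interval_matches_textbook_implementation(self, rng):
        """BCa for the mean of a fixed 10-value sample against an independent
        implementation of the bias-correction/acceleration formulas."""
        x = np.array([2.3, 4.1, 1.7, 5.5, 3.3, 2.8, 6.1, 3.9, 4.6, 2.2])
        B = 2000
        boot = np.array([rng.choice(x, size=x.size).mean() for _ in range(B)])
        jack = np.array([np.delete(x, i).mean() for i in range(x.size)])
        theta = x.mean()
        lo, hi = _bca_interval(theta, boot, jack, 0.95)

        # --- independent textbook computation ---
        z0 = stats.norm.ppf((np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / B)
        jm = jack.mean()
        a = np.sum((jm - jack) ** 3) / (6.0 * np.sum((jm - jack) ** 2) ** 1.5)
        lo2, hi2 = [
            np.quantile(
                boot,
                stats.norm.cdf(z0 + (z0 + stats.norm.ppf(q)) / (1 - a * (z0 + stats.norm.ppf(q)))),
            )
            for q in (0.025, 0.975)
        ]
        assert lo == pytest.approx(lo2, abs=1e-3)
        assert hi == pytest.approx(hi2, abs=1e-3)

    def test_default_bootstrap_B_is_5000(self):
        assert AnalysisConfig().bootstrap_B == 5000
        assert AnalysisConfig().ci == "bca"
        assert AnalysisConfig().missing == "twostage"
        assert AnalysisConfig().sargan_adjust == "holm"
        assert AnalysisConfig().overid_degree == 2

    def test_bootstrap_reports_counts_and_seed_reproducibility(self, brain_body_text):
        p = lv.default_params().with_(n=120, missing_var=None)
        df = lv.generate(p, seed=11)
        cfg = AnalysisConfig(bootstrap_B=60, seed=9, missing="complete")
        f1 = fit_miiv_sem(df, brain_body_text, cfg)
        f2 = fit_miiv_sem(df, brain_body_text, cfg)
        assert f1.bootstrap["B_successful"] == 60
        assert f1.bootstrap["B_attempted"] >= 60
        for pid in f1.params:
            assert f1.params[pid].se == f2.params[pid].se
            assert f1.params[pid].ci_low == f2.params[pid].ci_low


class TestLatentCollapse:
    def test_zero_measurement_error_on_scaling_indicators(self):
        """With error-free scaling indicators the latents equal their scaling
        indicators, so the causal paths equal plain regression coefficients
        computed directly from the population moments."""
        p = lv.default_params().with_(sd_eps_tiv=0.0, sd_eps_organs=0.0)
        mom = lv.implied_moments(p)
        fit = fit_from_moments(lv.synthetic_data.MODEL_TEXT, mom)
        i = {n: k for k, n in enumerate(mom.names)}
        x = [i["TIV"], i["height"]]
        S = mom.cov
        b = np.linalg.solve(S[np.ix_(x, x)], S[np.ix_(x, [i["organs"]])]).ravel()
        assert fit.params["beta_body_brain"].estimate == pytest.approx(b[0], abs=1e-10)
        assert fit.params["beta_body_height"].estimate == pytest.approx(b[1], abs=1e-10)
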