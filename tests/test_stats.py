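"""Wilson intervals, VarIdent GLS, nested-intercept LME, Wald-F and LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from fishchroma import stats as st
from fishchroma.synthetic import default_scenarios, simulate_trajectories


class TestWilson:
    def test_low_row_zero_events(self):
        lo, hi = st.wilson_interval(0, 231)
        assert lo == 0.0
        assert round(hi, 2) == 0.02

    def test_closed_form_hand_value(self):
        lo, hi = st.wilson_interval(5, 10)
        assert lo == pytest.approx(0.2366, abs=1e-4)
        assert hi == pytest.approx(0.7634, abs=1e-4)

    def test_all_successes_upper_is_one(self):
        assert st.wilson_interval(17, 17)[1] == 1.0

    def test_zero_successes_upper_closed_form(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        _, hi = st.wilson_interval(0, 57)
        assert hi == pytest.approx(z * z / (57 + z * z), rel=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(0, 231), (4, 131), (46, 150), (10, 10)]:
            ours = st.wilson_interval(x, n)
            theirs = proportion_confint(x, n, method="wilson")
            assert np.allclose(ours, theirs, atol=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=hst.integers(1, 500), frac=hst.floats(0.0, 1.0))
    def test_contains_point_estimate_and_bounded(self, n, frac):
        x = int(round(frac * n))
        lo, hi = st.wilson_interval(x, n)
        assert 0.0 <= lo <= x / n <= hi <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.wilson_interval(1, 0)
        with pytest.raises(ValueError):
            st.wilson_interval(5, 4)


class TestDesignEncoding:
    def test_treatment_contrasts_alphabetical_reference(self):
        d = pd.DataFrame({"g": ["b", "a", "c"], "y": [1.0, 2.0, 3.0]})
        X, names, term_cols, y = st.build_design(
            st.DesignSpec(data=d, response="y", fixed=("g",)))
        assert names == ["Intercept", "g[T.b]", "g[T.c]"]  # 'a' is reference

    def test_interaction_columns(self):
        d = pd.DataFrame({"g": ["a", "a", "b", "b", "a", "b"],
                          "x": [2.0, 4.0, 3.0, 5.0, 1.0, 7.0],
                          "y": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        X, names, term_cols, _ = st.build_design(
            st.DesignSpec(data=d, response="y", fixed=("g", "x", "g:x")))
        assert "g[T.b]:x" in names
        j = names.index("g[T.b]:x")
        assert X[:, j] == pytest.approx([0.0, 0.0, 3.0, 5.0, 0.0, 7.0])

    def test_rank_deficiency_detected(self):
        d = pd.DataFrame({"x": [1.0, 2.0, 3.0], "z": [2.0, 4.0, 6.0],
                          "y": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="rank"):
            st.build_design(st.DesignSpec(data=d, response="y", fixed=("x", "z")))


class TestGLS:
    def test_single_group_equals_ols(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"x": rng.uniform(0, 1, 50)})
        d["y"] = 1 + 2 * d["x"] + rng.normal(0, 0.5, 50)
        fit = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("x",)))
        beta = np.polyfit(d["x"], d["y"], 1)
        assert fit.params["x"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.params["Intercept"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.var_ratios == {}

    def test_ols_loglik_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 60)
        y = 1 + 2 * x + rng.normal(0, 1, 60)
        d = pd.DataFrame({"x": x, "y": y})
        fit = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("x",)))
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.loglik_ml == pytest.approx(ref.llf, abs=1e-8)
        assert np.allclose(fit.bse, ref.bse, atol=1e-8)

    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(2)
        n = 200
        g = np.repeat(["A", "B"], n // 2)
        y = np.where(g == "A", 1.0, 3.0) * rng.normal(size=n)
        d = pd.DataFrame({"g": g, "y": y})
        fit = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("g",),
                                       variance_groups="g"))
        assert fit.var_ratios["A"] == 1.0
        assert abs(fit.var_ratios["B"] - 3.0) / 3.0 < 0.20

    def test_high_trial_slope_recovery(self):
        scs = default_scenarios()
        df = simulate_trajectories([scs["Control"], scs["High"]], 40, 15.0, seed=3)
        fit = st.fit_gls(st.DesignSpec(
            data=df, response="b",
            fixed=("trial", "exposure_min", "trial:exposure_min"),
            variance_groups="trial"))
        slopes = st.trial_slopes(fit).set_index("trial")
        est, se = slopes.loc["High", "slope"], slopes.loc["High", "se"]
        assert abs(est - (-0.82)) < 3 * se


class TestWaldF:
    def test_deterministic_refit(self):
        rng = np.random.default_rng(4)
        d = pd.DataFrame({"g": np.repeat(["A", "B"], 30),
                          "x": rng.uniform(0, 1, 60)})
        d["y"] = rng.normal(size=60)
        spec = st.DesignSpec(data=d, response="y", fixed=("g", "x"),
                             variance_groups="g")
        f1, f2 = st.fit_gls(spec), st.fit_gls(spec)
        r1, r2 = st.wald_f(f1, "x"), st.wald_f(f2, "x")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_large_effect_power(self):
        rng = np.random.default_rng(5)
        rejected = 0
        for i in range(50):
            x = rng.uniform(0, 1, 40)
            y = 5.0 * x + rng.normal(size=40)  # 5 SD effect
            d = pd.DataFrame({"x": x, "y": y})
            fit = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("x",)))
            if st.wald_f(fit, "x").p_value < 0.05:
                rejected += 1
        assert rejected >= 50 * 0.99

    def test_missing_term_rejected(self):
        d = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 2.5]})
        fit = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("x",)))
        with pytest.raises(ValueError):
            st.wald_f(fit, "z")


class TestLME:
    @staticmethod
    def _grouped_data(seed, n_groups=30, per=10, tau=1.0, sigma=1.0):
        rng = np.random.default_rng(seed)
        g = np.repeat([f"g{i:02d}" for i in range(n_groups)], per)
        u = np.repeat(rng.normal(0, tau, n_groups), per)
        x = rng.uniform(0, 1, n_groups * per)
        y = 1 + 0.5 * x + u + rng.normal(0, sigma, n_groups * per)
        return pd.DataFrame({"g": g, "x": x, "y": y})

    def test_tau_zero_collapses_to_gls(self):
        d = self._grouped_data(6, tau=0.0)
        lme = st.fit_lme(st.DesignSpec(data=d, response="y", fixed=("x",),
                                       random_groups=("g",)))
        gls = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("x",)))
        assert lme.loglik_reml >= gls.loglik_reml - 1e-4
        assert lme.random_sd["g"] < 0.2

    def test_random_intercept_sd_recovery(self):
        d = self._grouped_data(7, tau=1.0)
        fit = st.fit_lme(st.DesignSpec(data=d, response="y", fixed=("x",),
                                       random_groups=("g",)))
        assert 0.7 <= fit.random_sd["g"] <= 1.3

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        d = self._grouped_data(8, n_groups=12, per=8)
        fit = st.fit_lme(st.DesignSpec(data=d, response="y", fixed=("x",),
                                       random_groups=("g",)))
        ref = smf.mixedlm("y ~ x", d, groups=d["g"]).fit(reml=True)
        assert fit.params["x"] == pytest.approx(ref.params["x"], abs=1e-4)
        assert fit.random_sd["g"] == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), abs=1e-3)
        assert fit.sigma == pytest.approx(np.sqrt(ref.scale), abs=1e-3)

    def test_optimizer_matches_brute_force_grid(self):
        """On a 12-observation instance the simplex optimum matches a dense
        (sigma, tau) REML grid within 1e-3 log-likelihood."""
        rng = np.random.default_rng(9)
        g = np.repeat(["a", "b", "c", "d"], 3)
        u = np.repeat(rng.normal(0, 1, 4), 3)
        x = rng.uniform(0, 1, 12)
        y = 1 + x + u + rng.normal(0, 1, 12)
        d = pd.DataFrame({"g": g, "x": x, "y": y})
        fit = st.fit_lme(st.DesignSpec(data=d, response="y", fixed=("x",),
                                       random_groups=("g",)))
        X = np.column_stack([np.ones(12), x])
        Z = (np.asarray(g)[:, None] == np.array(["a", "b", "c", "d"])).astype(float)
        best = -np.inf
        for s in np.linspace(0.05, 3.0, 150):
            for t in np.linspace(0.0, 3.0, 150):
                V = s**2 * np.eye(12) + t**2 * Z @ Z.T
                Vi = np.linalg.inv(V)
                beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
                r = y - X @ beta
                ll = -0.5 * (np.linalg.slogdet(V)[1]
                             + np.linalg.slogdet(X.T @ Vi @ X)[1]
                             + r @ Vi @ r + 10 * np.log(2 * np.pi))
                best = max(best, ll)
        assert fit.loglik_reml >= best - 1e-3

    def test_nested_grouping_factors_match_lme4(self):
        """Nested random intercepts on a 6 trial x 4 period x 8 obs design;
        expected values frozen from lme4's lmer(y ~ 1 + (1|trial/period))
        on the identical dataset."""
        rng = np.random.default_rng(10)
        nt, npd, per = 6, 4, 8
        trials = np.repeat([f"t{i}" for i in range(nt)], npd * per)
        periods = np.tile(np.repeat([f"p{i}" for i in range(npd)], per), nt)
        u_t = np.repeat(rng.normal(0, 1.0, nt), npd * per)
        u_p = np.repeat(rng.normal(0, 1.0, nt * npd), per)
        y = 2.0 + u_t + u_p + rng.normal(0, 1.0, nt * npd * per)
        d = pd.DataFrame({"trial": trials, "period": periods, "y": y})
        fit = st.fit_lme(st.DesignSpec(data=d, response="y", fixed=(),
                                       random_groups=("trial", "period")))
        assert fit.random_sd["trial"] == pytest.approx(0.7720, abs=5e-3)
        assert fit.random_sd["period"] == pytest.approx(0.7753, abs=5e-3)
        assert fit.sigma == pytest.approx(0.9423, abs=5e-3)
        assert fit.loglik_reml == pytest.approx(-287.3359, abs=1e-3)

    def test_requires_random_groups(self):
        d = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            st.fit_lme(st.DesignSpec(data=d, response="y"))


class TestLRT:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(11)
        d = pd.DataFrame({"x": rng.uniform(0, 1, 30)})
        d["y"] = d["x"] + rng.normal(size=30)
        spec = st.DesignSpec(data=d, response="y", fixed=("x",))
        f1, f2 = st.fit_gls(spec), st.fit_gls(spec)
        res = st.lrt(f1, f2)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_non_nested_detected(self):
        rng = np.random.default_rng(12)
        d = pd.DataFrame({"x": rng.uniform(0, 1, 30), "z": rng.uniform(0, 1, 30)})
        d["y"] = rng.normal(size=30)
        fx = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("x",)))
        fz = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=("z",)))
        with pytest.raises(ValueError, match="nested"):
            st.lrt(fx, fz)

    def test_loglik_ordering_ols_gls_lme(self):
        """Each model class generalises the previous: the maximised ML
        log-likelihoods must be (weakly) ordered OLS <= GLS <= LME."""
        rng = np.random.default_rng(13)
        g = np.repeat(["A", "B", "C", "D", "E"], 16)
        u = np.repeat(rng.normal(0, 1, 5), 16)
        sd = np.where(np.isin(g, ["A", "B"]), 1.0, 2.0)
        d = pd.DataFrame({"g": g, "y": 1.0 + u + sd * rng.normal(size=80)})
        ols = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=()))
        gls = st.fit_gls(st.DesignSpec(data=d, response="y", fixed=(),
                                       variance_groups="g"))
        lme = st.fit_lme(st.DesignSpec(data=d, response="y", fixed=(),
                                       variance_groups="g", random_groups=("g",)))
        assert ols.loglik_ml <= gls.loglik_ml + 1e-6
        assert gls.loglik_ml <= lme.loglik_ml + 1e-6


class TestTermDropper:
    @staticmethod
    def _vitality_data(seed, effect):
        rng = np.random.default_rng(seed)
        n = 80
        vit = rng.random(n) < 0.5
        x = rng.uniform(0, 10, n)
        y = 10 - 0.3 * x + effect * vit + rng.normal(0, 1, n)
        return pd.DataFrame({"vitality_assessed": vit, "x": x, "y": y})

    def test_strong_effect_retained(self):
        d = self._vitality_data(14, effect=3.0)
        spec = st.DesignSpec(data=d, response="y", fixed=("x", "vitality_assessed"))
        chosen, fit, audit = st.term_dropper(spec, "vitality_assessed")
        assert not audit["dropped"]
        assert "vitality_assessed" in chosen.fixed

    def test_null_effect_dropped_at_alpha(self):
        dropped = 0
        for s in range(40):
            d = self._vitality_data(100 + s, effect=0.0)
            spec = st.DesignSpec(data=d, response="y",
                                 fixed=("x", "vitality_assessed"))
            chosen, fit, audit = st.term_dropper(spec, "vitality_assessed")
            dropped += audit["dropped"]
        assert dropped >= 40 * 0.85  # ~95% expected at alpha = 0.05

    def test_absent_term_returned_unchanged(self):
        d = self._vitality_data(15, effect=0.0)
        spec = st.DesignSpec(data=d, response="y", fixed=("x",))
        chosen, fit, audit = st.term_dropper(spec, "vitality_assessed")
        assert chosen is spec and not audit["present"]
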