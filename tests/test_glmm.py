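import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from pheasantcog import glmm


def _toy_data():
    X = pd.DataFrame(
        {
            "const": 1.0,
            "x": [0.2, -0.5, 1.0, 0.3, -1.2, 0.7],
        }
    )
    y = np.array([1, 0, 1, 0, 1, 1], float)
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    return glmm.GLMMData(X=X, y=y, groups=groups, term_map={"x": ["x"]}, slope_col="x")


def _simulated_data(seed=0, n_groups=8, n_per=60, sigma=0.6, beta=(0.4, 0.7), slope_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma)
        u1 = rng.normal(0, slope_sd) if slope_sd > 0 else 0.0
        x = rng.normal(0, 1, n_per)
        eta = beta[0] + (beta[1] + u1) * x + u
        y = (rng.random(n_per) < expit(eta)).astype(float)
        rows.append(pd.DataFrame({"g": f"g{g}", "x": x, "y": y}))
    df = pd.concat(rows, ignore_index=True)
    X = pd.DataFrame({"const": 1.0, "x": df["x"]})
    return glmm.GLMMData(
        X=X, y=df["y"].to_numpy(), groups=df["g"].to_numpy(),
        term_map={"x": ["x"]}, slope_col="x",
    ), df


class TestMarginalLikelihood:
    def test_zero_variance_boundary_equals_plain_logistic(self):
        """With the random-intercept variance pinned to 0 the marginal
        log-likelihood is the ordinary logistic-regression log-likelihood."""
        import statsmodels.api as sm

        data, df = _simulated_data(seed=1, n_groups=4, n_per=30, sigma=0.5)
        fit0 = glmm.fit_binomial_glmm(data, random_structure="none")
        res = sm.GLM(
            data.y, data.X.to_numpy(), family=sm.families.Binomial()
        ).fit()
        assert fit0.loglik == pytest.approx(float(res.llf), abs=1e-6)
        np.testing.assert_allclose(fit0.estimates.to_numpy(), res.params, atol=1e-5)

    def test_intercept_loglik_matches_dense_integration(self):
        """AGQ marginal likelihood vs trapezoid integration over +-10 SD
        with 1e5 nodes on a 2-group toy."""
        data = _toy_data()
        X = data.X.to_numpy()
        y = data.y
        starts = np.array([0, 3])
        counts = np.array([3, 3])
        beta = np.array([0.3, -0.4])
        sigma = 0.8
        ll = glmm.marginal_loglik_intercept(beta, sigma, X, y, starts, counts, 15)
        u = np.linspace(-10 * sigma, 10 * sigma, 100_001)
        total = 0.0
        for s, c in zip(starts, counts):
            eta = X[s : s + c] @ beta
            lp = (
                y[s : s + c, None] * (eta[:, None] + u)
                - np.logaddexp(0.0, eta[:, None] + u)
            ).sum(axis=0)
            total += np.log(np.trapezoid(np.exp(lp) * norm.pdf(u, 0, sigma), u))
        assert ll == pytest.approx(total, abs=1e-6)

    def test_slope_loglik_matches_dense_2d_integration(self):
        from scipy.stats import multivariate_normal

        data = _toy_data()
        X = data.X.to_numpy()
        y = data.y
        s = X[:, 1]
        starts = np.array([0, 3])
        counts = np.array([3, 3])
        beta = np.array([0.3, -0.4])
        theta = np.array([np.log(0.6), 0.2, np.log(0.4)])
        ll = glmm.marginal_loglik_slope(beta, theta, X, y, s, starts, counts, 9)
        L = glmm._chol_from_theta(theta)
        cov = L @ L.T
        g = np.linspace(-6, 6, 401)
        U0, U1 = np.meshgrid(g, g, indexing="ij")
        pdf = multivariate_normal(mean=[0, 0], cov=cov).pdf(np.dstack([U0, U1]))
        total = 0.0
        for st_, c in zip(starts, counts):
            eta0 = X[st_ : st_ + c] @ beta
            lp = np.zeros_like(U0)
            for i in range(c):
                e = eta0[i] + U0 + U1 * s[st_ + i]
                lp += y[st_ + i] * e - np.logaddexp(0.0, e)
            total += np.log(np.trapezoid(np.trapezoid(np.exp(lp) * pdf, g, axis=1), g))
        assert ll == pytest.approx(total, abs=1e-6)

    def test_quadrature_stability_15_to_25(self):
        data, _ = _simulated_data(seed=2, n_groups=8, n_per=99, sigma=0.6)
        f15 = glmm.fit_binomial_glmm(data, quad_points=15)
        f25 = glmm.fit_binomial_glmm(data, quad_points=25)
        assert abs(f15.loglik - f25.loglik) < 1e-4


class TestFitting:
    def test_agreement_with_lme4_glmer(self, tmp_path):
        """Fixed effects, random-intercept SD and log-likelihood match
        glmer(..., nAGQ=15) on a simulated dataset."""
        data, df = _simulated_data(seed=42, n_groups=6, n_per=40, sigma=0.8)
        csv = tmp_path / "toy.csv"
        df.to_csv(csv, index=False)
        fit = glmm.fit_binomial_glmm(data, quad_points=15)
        r_code = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15)
        cat(jsonlite::toJSON(list(beta=unname(fixef(m)),
            sigma=sqrt(unname(VarCorr(m)$g[1])), ll=logLik(m)[1]), digits=10))
        """
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        np.testing.assert_allclose(fit.estimates.to_numpy(), ref["beta"], atol=1e-3)
        assert fit.sigma_u == pytest.approx(ref["sigma"][0], abs=1e-3)
        assert fit.loglik == pytest.approx(ref["ll"][0], abs=1e-5)

    def test_parameter_recovery_on_simulated_groups(self):
        """Fits of data simulated from the model family recover the
        generating fixed effects (small replicate check; the full
        200-replicate check lives in the acceptance suite)."""
        ests = []
        for s in range(25):
            data, _ = _simulated_data(seed=100 + s, n_groups=8, n_per=99, sigma=0.3)
            fit = glmm.fit_binomial_glmm(data, quad_points=15)
            ests.append(fit.estimates.to_numpy())
        mean_est = np.mean(ests, axis=0)
        mc_se = np.std(ests, axis=0, ddof=1) / np.sqrt(len(ests))
        np.testing.assert_array_less(np.abs(mean_est - [0.4, 0.7]), 3 * mc_se + 0.02)

    def test_odds_ratios_are_exp_estimates(self):
        data, _ = _simulated_data(seed=3, n_groups=4, n_per=30)
        fit = glmm.fit_binomial_glmm(data, quad_points=15)
        tbl = fit.fixed_effects_table()
        np.testing.assert_allclose(tbl["or"], np.exp(tbl["estimate"]), rtol=1e-12)


class TestLRT:
    def test_identical_fits_give_chi2_zero_p_one(self):
        data, _ = _simulated_data(seed=4, n_groups=4, n_per=30)
        fit = glmm.fit_binomial_glmm(data, quad_points=15)
        clone = glmm.GLMMFit(**{**fit.__dict__, "n_params": fit.n_params - 1})
        res = glmm.likelihood_ratio_test(fit, clone)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0)

    def test_matches_deviance_difference_of_plain_logistic(self):
        """On fixed-effects-only fits the LRT equals the IRLS deviance
        difference between nested ordinary logistic models."""
        import statsmodels.api as sm

        data, _ = _simulated_data(seed=5, n_groups=4, n_per=40)
        full = glmm.fit_binomial_glmm(data, random_structure="none")
        reduced = glmm.fit_binomial_glmm(data.drop_term("x"), random_structure="none")
        lrt = glmm.likelihood_ratio_test(full, reduced)
        rf = sm.GLM(data.y, data.X.to_numpy(), family=sm.families.Binomial()).fit()
        rr = sm.GLM(
            data.y, data.X.drop(columns="x").to_numpy(), family=sm.families.Binomial()
        ).fit()
        assert lrt.chi2 == pytest.approx(float(rr.deviance - rf.deviance), abs=1e-5)

    def test_adding_a_term_never_decreases_loglik(self):
        rng = np.random.default_rng(6)
        data, _ = _simulated_data(seed=6, n_groups=6, n_per=40)
        noise = rng.normal(0, 1, len(data.y))
        X2 = data.X.assign(noise=noise)
        data2 = glmm.GLMMData(
            X=X2, y=data.y, groups=data.groups,
            term_map={**data.term_map, "noise": ["noise"]}, slope_col="x",
        )
        f1 = glmm.fit_binomial_glmm(data, quad_points=15)
        f2 = glmm.fit_binomial_glmm(data2, quad_points=15)
        assert f2.loglik >= f1.loglik - 1e-6


class TestRandomStructure:
    def test_zero_slope_variance_null_p_typically_large(self):
        ps = []
        for s in range(8):
            data, _ = _simulated_data(seed=200 + s, n_groups=8, n_per=50, sigma=0.6)
            ps.append(glmm.compare_random_structures(data, quad_points=9).p)
        # chi2(2) reference ignoring the boundary is conservative: large p typical
        assert np.median(ps) > 0.2

    def test_strong_slope_variance_detected(self):
        chis = []
        for s in range(8):
            data, _ = _simulated_data(
                seed=300 + s, n_groups=8, n_per=60, sigma=0.6, slope_sd=0.9
            )
            chis.append(glmm.compare_random_structures(data, quad_points=9).chi2)
        assert np.median(chis) > chi2_dist.ppf(0.95, 2)

    def test_identical_loglik_gives_chi2_zero(self):
        res = glmm.LRTResult(chi2=0.0, df=2, p=1.0)
        assert res.p == 1.0


class TestStudyDesign:
    def _trials(self, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"m{k}" for k in range(8)]
        rows = []
        for k, i in enumerate(ids):
            y = (rng.random(100) < 0.6).astype(int)
            rows.append(
                pd.DataFrame(
                    {"individual": i, "phase": "adult", "trial": range(1, 101), "correct": y}
                )
            )
        trials = pd.concat(rows, ignore_index=True)
        elo = {i: float(v) for i, v in zip(ids, rng.normal(0, 300, 8))}
        females = {i: (2 if k % 2 else 4) for k, i in enumerate(ids)}
        cohort = {i: ("I" if k < 4 else "II") for k, i in enumerate(ids)}
        return trials, elo, females, cohort

    def test_first_trial_becomes_covariate_and_rows_span_2_100(self):
        trials, elo, females, cohort = self._trials()
        data = glmm.build_study_design(trials, elo, females, cohort)
        assert len(data.y) == 8 * 99
        first = trials[trials["trial"] == 1].set_index("individual")["correct"]
        got = (
            pd.DataFrame({"individual": data.groups, "fc": data.X["first_choice"].to_numpy()})
            .groupby("individual")["fc"].first()
        )
        for ind in first.index:
            assert got[ind] == first[ind]

    def test_z_scored_regressors(self):
        trials, elo, females, cohort = self._trials(1)
        data = glmm.build_study_design(trials, elo, females, cohort)
        for col in ("trial_z", "elo_z"):
            v = data.X[col].to_numpy()
            assert v.mean() == pytest.approx(0.0, abs=1e-10)
            assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_minimum_adequate_model_respects_interaction_hierarchy(self):
        trials, elo, females, cohort = self._trials(2)
        data = glmm.build_study_design(trials, elo, females, cohort)
        fit, final_data, history = glmm.minimum_adequate_model(data, quad_points=9)
        kept = set(final_data.term_map)
        if "trial:elo" in kept:
            assert {"trial", "elo"} <= kept
        # intercept always retained
        assert "const" in fit.estimates.index
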