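import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from esmstaging.igglmm import (
    GlmmSpec,
    IGParams,
    center_predictor,
    fit_glmm,
    fit_ig_glm,
    ig_logpdf,
    ig_sample,
    laplace_loglik_fixed_beta,
    lrt,
    marginal_loglik_agq,
    score_ratio,
    shift_outcome,
)


def simulate_ig_glmm(
    n_persons, n_obs, beta, sigma_p, family_sd, phi, seed, twin=True
):
    """Draw data from the IG-log mixed model itself."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma_p)
    fam = np.repeat(np.arange((n_persons + 1) // 2), 2)[:n_persons] if twin else np.arange(n_persons)
    v = family_sd * rng.standard_normal(fam.max() + 1)
    frames = []
    for p in range(n_persons):
        u = L @ rng.standard_normal(2)
        x = rng.standard_normal(n_obs)
        g = rng.integers(1, 5)
        eta = beta[0] + (beta[1] + u[1]) * x + u[0] + v[fam[p]]
        mu = np.exp(eta)
        y = stats.invgauss.rvs(mu * phi, scale=1.0 / phi, random_state=rng)
        frames.append(pd.DataFrame({
            "person_id": p, "family_id": fam[p], "y": y, "x": x, "severity_group": g,
        }))
    return pd.concat(frames, ignore_index=True)


class TestIgDistribution:
    def test_logpdf_at_mode_point(self):
        # exponent vanishes at y = mu: only the normalizing factor remains
        assert ig_logpdf(1.0, 1.0, 1.0) == pytest.approx(-0.5 * np.log(2 * np.pi))

    @pytest.mark.parametrize("mu,lam", [(1, 1), (2, 0.5), (1.3, 3)])
    def test_density_integrates_to_one(self, mu, lam):
        val, _ = integrate.quad(
            lambda y: np.exp(ig_logpdf(y, mu, lam)), 1e-12, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_parameterization(self):
        y = np.linspace(0.05, 8, 50)
        mine = ig_logpdf(y, 1.7, 2.3)
        ref = stats.invgauss.logpdf(y, 1.7 / 2.3, scale=2.3)
        assert np.allclose(mine, ref, atol=1e-10)

    def test_nonpositive_support_rejected(self):
        with pytest.raises(ValueError):
            ig_logpdf(-0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            IGParams(mu=-1.0, lam=1.0)

    def test_sampler_moments(self):
        params = IGParams(mu=2.0, lam=1.0)
        x = ig_sample(params, 100_000, seed=0)
        assert np.all(x > 0)
        se_mean = np.sqrt(params.variance / x.size)
        assert abs(x.mean() - 2.0) < 3 * se_mean
        assert x.var() == pytest.approx(8.0, rel=0.05)

    def test_high_precision_approaches_normal(self):
        x = ig_sample(IGParams(mu=1.0, lam=1000.0), 100_000, seed=1)
        assert abs(stats.skew(x)) < 0.2  # theoretical 3*sqrt(mu/lam) ~ 0.095

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ig_sample(IGParams(1, 1), 0, seed=0)


class TestIgGlm:
    def test_intercept_only_mle_is_sample_mean(self):
        y = ig_sample(IGParams(1.5, 3.0), 500, seed=2)
        fit = fit_ig_glm(y, np.ones((500, 1)))
        assert np.exp(fit.params[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 5000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([0.4, 0.25])
        mu = np.exp(X @ beta)
        phi = 0.1
        y = stats.invgauss.rvs(mu * phi, scale=1 / phi, random_state=rng)
        fit = fit_ig_glm(y, X)
        se = np.sqrt(np.diag(fit.cov_params))
        assert np.all(np.abs(fit.params - beta) < 3 * se)

    def test_loglik_is_maximal_under_perturbation(self):
        rng = np.random.default_rng(4)
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        mu = np.exp(0.3 + 0.2 * X[:, 1])
        y = stats.invgauss.rvs(mu * 0.15, scale=1 / 0.15, random_state=rng)
        fit = fit_ig_glm(y, X)
        for _ in range(100):
            pert = fit.params + 0.05 * rng.standard_normal(2)
            ll_pert = np.sum(ig_logpdf(y, np.exp(X @ pert), 1 / fit.dispersion))
            assert ll_pert <= fit.log_likelihood + 1e-8

    def test_nonpositive_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_ig_glm(np.array([1.0, -2.0]), np.ones((2, 1)))

    def test_rank_deficiency_rejected(self):
        y = np.ones(10) * 2
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError):
            fit_ig_glm(y, X)


class TestRescaling:
    def test_center_predictor(self):
        c, gm = center_predictor([1.0, 2.0, 3.0])
        assert gm == 2.0
        assert np.allclose(c, [-1, 0, 1])
        assert abs(np.mean(c)) < 1e-12

    def test_center_idempotent(self):
        c, _ = center_predictor([-1.0, 0.0, 1.0])
        assert np.allclose(c, [-1, 0, 1])

    def test_shift_outcome_range(self):
        y = np.array([1.0, 4.3, 7.0])
        s = shift_outcome(y)
        assert s.min() == 1.5 and s.max() == 7.5
        assert np.allclose(shift_outcome(y, 0.0), y)

    @pytest.mark.parametrize(
        "coef, ratio_2dp, pct",
        [(0.049, 1.05, 5.0), (0.0, 1.0, 0.0), (-0.019, 0.98, -1.9), (0.078, 1.08, 8.1)],
    )
    def test_score_ratio(self, coef, ratio_2dp, pct):
        sr = score_ratio(coef)
        assert round(sr.ratio, 2) == ratio_2dp
        assert round(sr.percent_change, 1) == pct
        assert sr.ratio > 0


class TestGlmmCore:
    def test_zero_re_degenerates_to_glm(self):
        """Pinning the random-effect variances to ~0 must reproduce the
        independent statsmodels GLM likelihood."""
        rng = np.random.default_rng(5)
        n, k = 200, 20
        x = rng.standard_normal(n)
        mu = np.exp(0.2 + 0.15 * x)
        y = stats.invgauss.rvs(mu * 0.1, scale=10.0, random_state=rng)
        df = pd.DataFrame({
            "person_id": np.repeat(np.arange(k), n // k),
            "family_id": np.repeat(np.arange(k), n // k),
            "y": y, "x": x,
        })
        glm = fit_ig_glm(y, np.column_stack([np.ones(n), x]))
        spec = GlmmSpec(outcome="y", predictor="x", response_family="ig",
                        severity_role="none", random_effects="person_intercept")
        fit = fit_glmm(spec, df, fix_theta=np.array([np.log(1e-8), np.log(glm.dispersion)]))
        assert fit.log_likelihood == pytest.approx(glm.log_likelihood, abs=1e-4)

    def test_gaussian_oneway_matches_closed_form(self):
        """Balanced one-way Gaussian layout: ML variance components have
        a closed form (within-MS and scaled between-MS)."""
        rng = np.random.default_rng(6)
        k, m = 20, 10
        b = 0.8 * rng.standard_normal(k)
        y = 2.0 + np.repeat(b, m) + 1.2 * rng.standard_normal(k * m)
        df = pd.DataFrame({
            "person_id": np.repeat(np.arange(k), m),
            "family_id": np.repeat(np.arange(k), m),
            "y": y,
        })
        ybar_i = y.reshape(k, m).mean(axis=1)
        ssw = float(np.sum((y.reshape(k, m) - ybar_i[:, None]) ** 2))
        ssb_n = float(m * np.sum((ybar_i - y.mean()) ** 2))
        sige2 = ssw / (k * (m - 1))
        sigb2 = (ssb_n / k - sige2) / m
        spec = GlmmSpec(outcome="y", predictor=None, response_family="gaussian",
                        severity_role="none", random_effects="person_intercept")
        fit = fit_glmm(spec, df, gtol=1e-8, ftol=1e-15)
        assert fit.dispersion == pytest.approx(sige2, abs=1e-3)
        assert fit.person_cov[0, 0] == pytest.approx(sigb2, abs=1e-3)
        assert fit.coef("intercept") == pytest.approx(y.mean(), abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_laplace_close_to_agq_on_tiny_instances(self, seed):
        """Laplace marginal log-likelihood within 0.5 of 15-node adaptive
        Gauss-Hermite on random small single-intercept IG instances."""
        rng = np.random.default_rng(seed)
        k, m = 8, 6
        sigma_b = rng.uniform(0.2, 0.5)
        phi = rng.uniform(0.02, 0.15)
        beta = np.array([rng.uniform(0, 0.5), rng.uniform(-0.3, 0.3)])
        x = rng.standard_normal(k * m)
        bb = sigma_b * rng.standard_normal(k)
        mu = np.exp(beta[0] + beta[1] * x + np.repeat(bb, m))
        y = stats.invgauss.rvs(mu * phi, scale=1 / phi, random_state=rng)
        df = pd.DataFrame({"person_id": np.repeat(np.arange(k), m),
                           "family_id": np.repeat(np.arange(k), m),
                           "y": y, "x": x})
        spec = GlmmSpec(outcome="y", predictor="x", response_family="ig",
                        severity_role="none", random_effects="person_intercept")
        theta = np.array([np.log(sigma_b), np.log(phi)])
        ll_lap = laplace_loglik_fixed_beta(spec, df, beta, theta)
        X = np.column_stack([np.ones(k * m), x])
        ll_agq = marginal_loglik_agq(y, X, beta, df["person_id"].to_numpy(),
                                     sigma_b, phi)
        assert abs(ll_lap - ll_agq) <= 0.5

    def test_parameter_recovery_from_own_model(self):
        """Fitting data simulated from the IG mixed model itself recovers
        fixed effects within 3 SE and RE variances within 30%."""
        sigma_p = np.array([[0.05, 0.01], [0.01, 0.02]])
        beta = np.array([0.25, 0.15])
        data = simulate_ig_glmm(300, 30, beta, sigma_p, family_sd=0.15,
                                phi=0.08, seed=11)
        spec = GlmmSpec(outcome="y", predictor="x", response_family="ig",
                        severity_role="none", random_effects="person_slope_family")
        fit = fit_glmm(spec, data, ftol=1e-9)
        assert fit.converged
        est = fit.coefficients
        for term, truth in [("intercept", beta[0]), ("slope", beta[1])]:
            assert abs(est.loc[term, "estimate"] - truth) < 3 * est.loc[term, "se"]
        assert fit.person_cov[0, 0] == pytest.approx(sigma_p[0, 0], rel=0.30)
        assert fit.person_cov[1, 1] == pytest.approx(sigma_p[1, 1], rel=0.30)
        assert fit.dispersion == pytest.approx(0.08, rel=0.15)

    def test_optimizer_improves_on_start(self):
        data = simulate_ig_glmm(60, 10, np.array([0.2, 0.1]),
                                np.array([[0.04, 0.0], [0.0, 0.01]]),
                                family_sd=0.1, phi=0.1, seed=12)
        spec = GlmmSpec(outcome="y", predictor="x", response_family="ig",
                        severity_role="none", random_effects="person_slope_family")
        fit = fit_glmm(spec, data)
        assert fit.log_likelihood >= fit.diagnostics["ll_start"] - 1e-6

    def test_wald_ci_symmetry(self):
        data = simulate_ig_glmm(40, 8, np.array([0.2, 0.1]),
                                np.array([[0.04, 0.0], [0.0, 0.01]]),
                                family_sd=0.1, phi=0.1, seed=13)
        spec = GlmmSpec(outcome="y", predictor="x", response_family="ig",
                        severity_role="none", random_effects="person_intercept_family")
        fit = fit_glmm(spec, data)
        c = fit.coefficients
        assert np.allclose(c["ci_high"] - c["estimate"],
                           c["estimate"] - c["ci_low"], atol=1e-10)


@pytest.fixture(scope="module")
def nested_fits():
    data = simulate_ig_glmm(80, 10, np.array([0.2, 0.1]),
                            np.array([[0.04, 0.0], [0.0, 0.01]]),
                            family_sd=0.1, phi=0.1, seed=14)
    full = fit_glmm(GlmmSpec(outcome="y", predictor="x", response_family="ig",
                             severity_role="moderator"), data)
    reduced = fit_glmm(GlmmSpec(outcome="y", predictor="x", response_family="ig",
                                severity_role="covariate"), data)
    return full, reduced


class TestLrt:
    @pytest.fixture()
    def fits(self, nested_fits):
        return nested_fits

    def test_identical_fits_give_null_test(self, fits):
        full, _ = fits
        t = lrt(full, full.__class__(**{**full.__dict__,
                                        "n_params": full.n_params - 1}))
        assert t.chi_sq == 0.0 and t.p_value == 1.0

    def test_moderator_vs_covariate_df_is_three(self, fits):
        full, reduced = fits
        t = lrt(full, reduced)
        assert t.df == 3
        assert t.p_value == pytest.approx(stats.chi2.sf(t.chi_sq, 3))

    def test_mismatched_nesting_rejected(self, fits):
        full, reduced = fits
        with pytest.raises(ValueError):
            lrt(reduced, full)

    def test_gaussian_lrt_invariant_to_rescaling(self):
        """Centering the predictor and shifting the outcome are exact
        reparameterizations of the Gaussian-identity model, so the
        interaction LRT must not move."""
        data = simulate_ig_glmm(80, 10, np.array([0.4, 0.1]),
                                np.array([[0.04, 0.0], [0.0, 0.01]]),
                                family_sd=0.1, phi=0.05, seed=15)
        chis = []
        for shift, center in [(0.0, False), (0.5, True)]:
            full = fit_glmm(GlmmSpec(outcome="y", predictor="x",
                                     response_family="gaussian",
                                     severity_role="moderator",
                                     rescale_outcome_shift=shift,
                                     rescale_predictor_center=center),
                            data, ftol=1e-12, gtol=1e-5)
            red = fit_glmm(GlmmSpec(outcome="y", predictor="x",
                                    response_family="gaussian",
                                    severity_role="covariate",
                                    rescale_outcome_shift=shift,
                                    rescale_predictor_center=center),
                           data, ftol=1e-12, gtol=1e-5)
            chis.append(lrt(full, red).chi_sq)
        assert chis[0] == pytest.approx(chis[1], abs=0.02)

    def test_ig_shift_is_recorded(self):
        data = simulate_ig_glmm(30, 8, np.array([0.2, 0.1]),
                                np.array([[0.04, 0.0], [0.0, 0.01]]),
                                family_sd=0.1, phi=0.1, seed=16)
        fit = fit_glmm(GlmmSpec(outcome="y", predictor="x", response_family="ig",
                                severity_role="covariate",
                                rescale_outcome_shift=0.5), data)
        assert fit.rescaling["outcome_shift"] == 0.5
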