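import warnings

import numpy as np
import pytest
from scipy import stats

import magest
from magest.models import (
    LinearModelSpec,
    ModelData,
    PowerModelSpec,
    fit,
    linear_log_density,
    log_prior,
    power_log_density,
    prepare_model_data,
)

from conftest import make_dataset


class TestPointwiseDensities:
    def test_at_the_mean_only_normalisation_remains(self):
        sigma = 0.07
        val = power_log_density(y=0.1 * 0.5**0.4, x=0.5, b0j=0.1, b1j=0.4, sigma_e=sigma)
        assert val == pytest.approx(-np.log(sigma * np.sqrt(2 * np.pi)), rel=1e-12)
        val = linear_log_density(y=0.2 + 0.3 * 0.5, x=0.5, beta0j=0.2, beta1j=0.3, sigma_e=sigma)
        assert val == pytest.approx(-np.log(sigma * np.sqrt(2 * np.pi)), rel=1e-12)

    def test_unit_exponent_nests_the_linear_model(self):
        for x, y in [(0.1, 0.05), (0.7, 0.3)]:
            assert power_log_density(y, x, b0j=0.23, b1j=1.0, sigma_e=0.05) == pytest.approx(
                linear_log_density(y, x, beta0j=0.0, beta1j=0.23, sigma_e=0.05), rel=1e-12
            )

    def test_against_independent_normal_pdf(self):
        # fitted-scale worked numbers: mean 0.23 * 0.1^0.44 = 0.0835
        mean = 0.23 * 0.1**0.44
        expected = stats.norm.logpdf(0.1, loc=mean, scale=0.03)
        assert power_log_density(0.1, 0.1, 0.23, 0.44, 0.03) == pytest.approx(
            expected, rel=1e-12
        )
        expected = stats.norm.logpdf(0.08, loc=0.05 + 0.2 * 0.3, scale=0.04)
        assert linear_log_density(0.08, 0.3, 0.05, 0.2, 0.04) == pytest.approx(
            expected, rel=1e-12
        )

    def test_flat_slope_ignores_x(self):
        a = linear_log_density(0.1, 0.2, beta0j=0.1, beta1j=0.0, sigma_e=0.05)
        b = linear_log_density(0.1, 0.9, beta0j=0.1, beta1j=0.0, sigma_e=0.05)
        assert a == b

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            power_log_density(0.1, 0.5, 0.2, 0.4, sigma_e=-0.01)
        with pytest.raises(ValueError):
            power_log_density(0.1, 0.0, 0.2, 0.4, sigma_e=0.05)


class TestLogPrior:
    def test_negative_sigma_outside_support(self):
        params = dict(b0=0.2, b1=0.5, sigma_u0=0.1, sigma_u1=0.1, sigma_e=-0.1)
        assert log_prior(PowerModelSpec(), params) == -np.inf

    def test_negative_exponent_outside_truncated_prior(self):
        params = dict(b0=0.2, b1=-0.5, sigma_u0=0.1, sigma_u1=0.1, sigma_e=0.05)
        assert log_prior(PowerModelSpec(), params) == -np.inf

    def test_lkj_shape_one_is_uniform_over_rho(self):
        base = dict(beta0=0.1, beta1=0.2, sigma_u0=0.1, sigma_u1=0.1, sigma_e=0.05)
        lp1 = log_prior(LinearModelSpec(), {**base, "rho": -0.8})
        lp2 = log_prior(LinearModelSpec(), {**base, "rho": 0.3})
        assert lp1 == pytest.approx(lp2, abs=1e-12)
        assert log_prior(LinearModelSpec(), {**base, "rho": 1.2}) == -np.inf

    def test_half_normal_exponent_prior_density(self):
        # normal(1, 0.5) truncated at zero, renormalised
        spec = PowerModelSpec()
        params = dict(b0=0.0, b1=0.7, sigma_u0=1.0, sigma_u1=1.0, sigma_e=1.0)
        lp = log_prior(spec, params)
        expected = (
            stats.norm.logpdf(0.0, 0, 5)
            + stats.truncnorm.logpdf(0.7, -2.0, np.inf, loc=1.0, scale=0.5)
            + 3 * (np.log(2) + stats.t.logpdf(1.0 / 2.5, 3) - np.log(2.5))
        )
        assert lp == pytest.approx(expected, rel=1e-9)


class TestFit:
    def test_parameter_recovery_and_diagnostics(self, power_fit_small):
        s = power_fit_small["samples"]
        pop = power_fit_small["pop"]
        b1 = s.flat("b1")
        assert abs(b1.mean() - pop.mean_a) <= 2 * b1.std(ddof=1)
        # pointwise log-likelihood matrix is draws x observations, complete
        assert s.pointwise_loglik.shape == (s.n_draws, s.data.n_obs)
        assert np.isfinite(s.pointwise_loglik).all()
        assert set(s.rhat) == set(s.spec.population_params)

    def test_same_seed_same_draws(self, lum):
        ds, _, _ = make_dataset(lum, n_participants=4, n_reps=2, seed=51)
        clean, _ = magest.preprocess(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(PowerModelSpec(), clean, chains=4, warmup=150, total_draws=500, seed=5)
            b = fit(PowerModelSpec(), clean, chains=4, warmup=150, total_draws=500, seed=5)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.summary().equals(b.summary())

    def test_near_noiseless_recovery(self, lum):
        ds, pop, _ = make_dataset(
            lum, noise_sd=0.002, sd_a=0.02, mean_a=0.6, n_participants=6, seed=61
        )
        clean, _ = magest.preprocess(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit(PowerModelSpec(), clean, chains=4, warmup=600, total_draws=2000, seed=62)
        b1 = s.flat("b1")
        assert abs(b1.mean() - 0.6) <= 2 * max(b1.std(ddof=1), 1e-3)

    def test_unit_exponent_power_and_linear_fits_agree(self, lum):
        # nesting: data generated at a = 1 are both a power law and a line
        ds, pop, _ = make_dataset(
            lum, mean_a=1.0, sd_a=0.05, noise_sd=0.03, n_participants=6, seed=71
        )
        clean, _ = magest.preprocess(ds)
        data = prepare_model_data(clean)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = fit(PowerModelSpec(), data, chains=4, warmup=600, total_draws=2000, seed=72)
            sl = fit(LinearModelSpec(), data, chains=4, warmup=600, total_draws=2000, seed=73)

        def fitted_means(s):
            spec, flat = s.spec, s.flat_theta()
            p = spec.unpack(flat, data.n_participants)
            e0, e1 = spec.participant_effects(p)
            return spec.mean_function(e0[:, data.pid], e1[:, data.pid], data.x).mean(axis=0)

        sigma_pred = np.mean(sp.flat("sigma_e"))
        assert np.max(np.abs(fitted_means(sp) - fitted_means(sl))) < 2 * sigma_pred

    def test_prior_only_run_reproduces_stated_priors(self):
        # no data: the sampled "posterior" must reproduce the prior marginals
        empty = ModelData(
            y=np.empty(0), x=np.empty(0), pid=np.empty(0, dtype=np.int64), n_participants=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit(PowerModelSpec(), empty, chains=40, warmup=500, total_draws=10000, seed=9)
        ks_b1 = stats.kstest(
            s.flat("b1"),
            lambda v: stats.truncnorm.cdf(v, -2.0, np.inf, loc=1.0, scale=0.5),
        ).statistic
        ks_b0 = stats.kstest(s.flat("b0"), lambda v: stats.norm.cdf(v, 0, 5)).statistic
        ks_se = stats.kstest(
            s.flat("sigma_e"), lambda v: 2 * stats.t.cdf(v / 2.5, 3) - 1
        ).statistic
        assert max(ks_b0, ks_b1, ks_se) < 0.02

    def test_unconstrained_log_posterior_matches_manual_sum(self, power_fit_small):
        # joint density = sum of pointwise likelihoods + prior, checked on a
        # retained draw via the natural-scale building blocks
        s = power_fit_small["samples"]
        data = s.data
        theta = s.flat_theta()[100]
        p = s.spec.unpack(theta[None, :], data.n_participants)
        e0, e1 = s.spec.participant_effects(p)
        ll = sum(
            power_log_density(
                data.y[i], data.x[i], e0[0, data.pid[i]], e1[0, data.pid[i]],
                float(p["sigma_e"][0]),
            )
            for i in range(data.n_obs)
        )
        lp = s.spec.log_prior_unconstrained(theta[None, :], data.n_participants)[0]
        assert s.log_posterior(theta[None, :])[0] == pytest.approx(ll + lp, rel=1e-9)
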