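"""GEV density, sampling and Bayesian fitting.

scipy.stats.genextreme (shape convention c = -xi) serves as the
independent oracle for the hand-implemented density, CDF and sampler.
"""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import genextreme, kstest

from axonmetrics.gev import (
    GEVParams,
    GEVPosterior,
    GEVPriors,
    fit_gev_mcmc,
    gev_cdf,
    gev_logpdf,
    gev_mean,
    gev_mode,
    gev_pdf,
    gev_ppf,
    gev_sample,
    hpd_interval,
    predictive_check,
)


@pytest.mark.parametrize("xi", [-0.3, -0.1, 0.0, 0.1, 0.2, 0.5])
def test_pdf_cdf_ppf_match_scipy_oracle(xi):
    p = GEVParams(mu=0.5, sigma=0.15, xi=xi)
    x = np.linspace(-1.0, 4.0, 801)
    np.testing.assert_allclose(
        gev_pdf(x, p), genextreme.pdf(x, -xi, loc=0.5, scale=0.15), atol=1e-12
    )
    np.testing.assert_allclose(
        gev_cdf(x, p), genextreme.cdf(x, -xi, loc=0.5, scale=0.15), atol=1e-12
    )
    q = np.linspace(0.01, 0.99, 99)
    np.testing.assert_allclose(
        gev_ppf(q, p), genextreme.ppf(q, -xi, loc=0.5, scale=0.15), rtol=1e-9
    )


def test_pdf_normalizes_by_quadrature():
    p = GEVParams(mu=0.5, sigma=0.15, xi=0.2)
    lo, hi = p.support()
    total, _ = integrate.quad(lambda x: gev_pdf(x, p), lo, 50.0, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_gumbel_branch_density_at_location():
    # xi -> 0, x = mu: t = 1, density = 1/(sigma*e)
    p = GEVParams(mu=0.5, sigma=0.15, xi=0.0)
    assert gev_pdf(0.5, p) == pytest.approx(1.0 / (0.15 * np.e), rel=1e-12)
    # tiny nonzero xi agrees with the Gumbel limit
    p_eps = GEVParams(mu=0.5, sigma=0.15, xi=1e-9)
    assert gev_pdf(0.5, p_eps) == pytest.approx(1.0 / (0.15 * np.e), rel=1e-6)


def test_mode_matches_grid_argmax():
    p = GEVParams(mu=0.5, sigma=0.15, xi=0.2)
    x = np.linspace(0.0, 2.0, 2_000_001)
    grid_mode = x[np.argmax(gev_pdf(x, p))]
    assert gev_mode(p) == pytest.approx(grid_mode, abs=1e-4)


def test_density_zero_outside_support():
    p = GEVParams(mu=0.5, sigma=0.15, xi=0.2)
    lo, _ = p.support()
    assert gev_pdf(lo - 0.01, p) == 0.0
    assert gev_logpdf(lo - 0.01, p) == -np.inf


def test_invalid_sigma_rejected():
    with pytest.raises(ValueError):
        GEVParams(mu=0.5, sigma=0.0, xi=0.1)


class TestSampling:
    def test_empty(self):
        assert gev_sample(GEVParams(0.5, 0.15, 0.1), 0).size == 0

    def test_reproducible_under_seed(self):
        p = GEVParams(0.5, 0.15, 0.1)
        np.testing.assert_array_equal(gev_sample(p, 100, 5), gev_sample(p, 100, 5))

    def test_draws_respect_support(self):
        p = GEVParams(0.5, 0.15, 0.2)
        lo, _ = p.support()
        assert (gev_sample(p, 10000, 1) > lo).all()

    def test_ks_against_analytic_cdf(self):
        p = GEVParams(0.5, 0.15, 0.2)
        draws = gev_sample(p, 100_000, seed=12)
        stat = kstest(
            draws, lambda x: genextreme.cdf(x, -p.xi, loc=p.mu, scale=p.sigma)
        ).statistic
        assert stat < 0.01

    def test_sample_mean_matches_analytic(self):
        p = GEVParams(0.5, 0.15, 0.1)
        d = gev_sample(p, 100_000, seed=3)
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - gev_mean(p)) < 3 * se


class TestHPD:
    def test_narrowest_window_on_known_shape(self):
        # asymmetric draws: the 50% HPD of Exp(1) hugs zero
        rng = np.random.default_rng(0)
        d = rng.exponential(size=100_000)
        lo, hi = hpd_interval(d, 0.5)
        assert lo < 0.01
        assert hi == pytest.approx(np.log(2), abs=0.02)

    def test_contains_requested_mass(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=10_000)
        lo, hi = hpd_interval(d, 0.99)
        frac = np.mean((d >= lo) & (d <= hi))
        assert frac >= 0.99


class TestMCMCFit:
    def test_parameter_recovery_inside_hpd(self):
        truth = GEVParams(0.5, 0.15, 0.2)
        data = gev_sample(truth, 5000, seed=21)
        post = fit_gev_mcmc(data, chains=4, draws=300, warmup=600, seed=22)
        for name, val in (("mu", 0.5), ("sigma", 0.15), ("xi", 0.2)):
            lo, hi = post.hpd99[name]
            assert lo <= val <= hi, f"{name} truth {val} outside [{lo}, {hi}]"
            assert post.rhat[name] < 1.01
            assert post.ess[name] > 400

    def test_location_equivariance(self):
        truth = GEVParams(0.5, 0.12, 0.1)
        data = gev_sample(truth, 2000, seed=5)
        post0 = fit_gev_mcmc(data, chains=2, draws=200, warmup=400, seed=6)
        post1 = fit_gev_mcmc(data + 0.25, chains=2, draws=200, warmup=400, seed=6)
        assert post1.mean("mu") - post0.mean("mu") == pytest.approx(0.25, abs=0.02)
        assert post1.mean("sigma") == pytest.approx(post0.mean("sigma"), abs=0.02)
        assert post1.mean("xi") == pytest.approx(post0.mean("xi"), abs=0.05)

    def test_scale_equivariance(self):
        truth = GEVParams(0.5, 0.12, 0.1)
        data = gev_sample(truth, 2000, seed=7)
        a = 1.5
        post = fit_gev_mcmc(a * data, chains=2, draws=200, warmup=400, seed=8)
        ref = fit_gev_mcmc(data, chains=2, draws=200, warmup=400, seed=8)
        assert post.mean("mu") == pytest.approx(a * ref.mean("mu"), rel=0.03)
        assert post.mean("sigma") == pytest.approx(a * ref.mean("sigma"), rel=0.08)
        assert post.mean("xi") == pytest.approx(ref.mean("xi"), abs=0.05)

    def test_deterministic_under_seed(self):
        data = gev_sample(GEVParams(0.5, 0.15, 0.1), 300, seed=1)
        p1 = fit_gev_mcmc(data, chains=1, draws=50, warmup=50, seed=9)
        p2 = fit_gev_mcmc(data, chains=1, draws=50, warmup=50, seed=9)
        np.testing.assert_array_equal(p1.samples["mu"], p2.samples["mu"])

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_gev_mcmc([])


class TestPredictiveChecks:
    def test_posterior_concentrated_at_truth_recovers_density(self):
        truth = GEVParams(0.5, 0.15, 0.1)
        const = {
            "mu": np.full((2, 50), truth.mu),
            "sigma": np.full((2, 50), truth.sigma),
            "xi": np.full((2, 50), truth.xi),
        }
        post = GEVPosterior(
            samples=const, hpd99={}, rhat={}, ess={},
        )
        x = np.linspace(*np.asarray(gev_ppf([0.025, 0.975], truth)), 200)
        out = predictive_check(post, n_draws=20, data_size=50, seed=0, x_grid=x)
        ref = gev_pdf(x, truth)
        assert np.max(np.abs(out["mean_curve"] - ref)) / ref.max() < 0.05

    def test_curve_count(self):
        priors = GEVPriors()
        out = predictive_check(priors, n_draws=150, data_size=30, seed=1)
        assert out["curves"].shape[0] == 150
        assert out["datasets"].shape == (150, 30)

    def test_prior_scale_draws_positive(self):
        thetas = GEVPriors().sample(500, seed=2)
        assert (thetas[:, 1] > 0).all()  # sigma
        assert (thetas[:, 0] > 0).all()  # mu truncated above zero
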