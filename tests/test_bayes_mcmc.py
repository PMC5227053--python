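"""Priors, R-hat, and posterior summaries against a 3-D quadrature oracle."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma, multivariate_normal, norm

from ar1bench import (
    GenParams,
    PriorSpec,
    RngSpec,
    gelman_rubin,
    log_prior,
    phi_prior_density,
    sample_posterior,
    simulate_ar1,
    summarize_posterior,
)
from ar1bench.bayes_mcmc import PARAM_NAMES, PosteriorDraws


def quadrature_posterior_moments(y, prior, n_phi=200, n_mu=100, n_sig=100):
    """Riemann-sum posterior mean/SD of phi via the dense-Gaussian likelihood."""
    T = len(y)
    phis = np.linspace(-0.995, 0.995, n_phi)
    mus = np.linspace(-5, 5, n_mu)
    sigs = np.linspace(0.02, 4.5, n_sig)
    ll = np.empty((n_phi, n_sig, n_mu))
    idx = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    for i, ph in enumerate(phis):
        R = ph**idx / (1 - ph**2)
        for j, sg in enumerate(sigs):
            mvn = multivariate_normal(mean=np.zeros(T), cov=sg**2 * R)
            ll[i, j, :] = mvn.logpdf(y[None, :] - mus[:, None])
    lp = (
        np.log(phi_prior_density(phis, prior.phi_prior))[:, None, None]
        + gamma.logpdf(sigs, prior.sigma_shape, scale=1 / prior.sigma_rate)[None, :, None]
        + norm.logpdf(mus, prior.mu_mean, prior.mu_sd)[None, None, :]
    )
    w = np.exp(ll + lp - (ll + lp).max())
    w /= w.sum()
    wphi = w.sum(axis=(1, 2))
    mean = (wphi * phis).sum()
    sd = np.sqrt((wphi * phis**2).sum() - mean**2)
    return mean, sd


class TestPriors:
    def test_symmetrized_reference_density_values(self):
        assert phi_prior_density(0.0, "symmetrized_reference") == pytest.approx(
            1 / (2 * np.pi), abs=1e-5
        )
        assert phi_prior_density(0.99, "symmetrized_reference") == pytest.approx(1.1286, abs=1e-3)
        assert phi_prior_density(-0.7, "symmetrized_reference") == pytest.approx(
            phi_prior_density(0.7, "symmetrized_reference")
        )

    def test_flat_density(self):
        assert phi_prior_density(0.3, "flat") == phi_prior_density(-0.8, "flat") == 0.5
        assert phi_prior_density(1.5, "flat") == 0.0

    def test_prior_masses_by_quadrature(self):
        mass_sr, _ = integrate.quad(lambda p: phi_prior_density(p, "symmetrized_reference"), -1, 1)
        mass_f, _ = integrate.quad(lambda p: phi_prior_density(p, "flat"), -1, 1)
        assert mass_sr == pytest.approx(0.5, abs=1e-6)
        assert mass_f == pytest.approx(1.0, abs=1e-12)

    def test_log_prior_support(self):
        pr = PriorSpec()
        assert log_prior(1.0, 0.0, 1.0, pr) == -np.inf
        assert log_prior(0.5, 0.0, -1.0, pr) == -np.inf
        expected = (
            np.log(0.5)
            + norm.logpdf(0.3, 0, 2)
            + gamma.logpdf(1.2, 2, scale=0.5)
        )
        assert log_prior(0.5, 0.3, 1.2, pr) == pytest.approx(expected)

    def test_priorspec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(phi_prior="jeffreys")
        with pytest.raises(ValueError):
            PriorSpec(mu_sd=0.0)


class TestGelmanRubin:
    def test_identical_chains_hand_value(self):
        # B = 0 so R-hat = sqrt((n-1)/n) = sqrt(0.75)
        assert gelman_rubin([[1, 2, 3, 4], [1, 2, 3, 4]]) == pytest.approx(np.sqrt(0.75))

    def test_converged_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 5000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_chains_undefined(self):
        assert np.isnan(gelman_rubin([[0, 0, 0, 0], [10, 10, 10, 10]]))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin([[1.0, 2.0]])


@pytest.fixture(scope="module")
def fixture_series():
    return simulate_ar1(GenParams(phi=-0.5), 8, RngSpec(17, 0, 0))


class TestSampler:
    @pytest.mark.parametrize("kind", ["flat", "symmetrized_reference"])
    def test_matches_quadrature_oracle(self, fixture_series, kind):
        prior = PriorSpec(phi_prior=kind)
        qmean, qsd = quadrature_posterior_moments(fixture_series, prior)
        draws = sample_posterior(fixture_series, prior=prior, n_chains=8, n_iter=20_000, seed=4)
        res = summarize_posterior(draws)
        assert res.phi_hat == pytest.approx(qmean, abs=0.02)
        assert res.se_hat == pytest.approx(qsd, abs=0.02)

    def test_support_and_diagnostics(self, fixture_series):
        draws = sample_posterior(fixture_series, n_chains=4, n_iter=1000, seed=1)
        assert np.all(np.abs(draws.chains[:, :, 0]) < 1.0)
        assert np.all(draws.chains[:, :, 2] > 0.0)
        assert set(draws.rhat) == set(PARAM_NAMES)
        assert all(0.0 <= v <= 1.0 for v in draws.accept_rate.values())

    def test_sr_prior_pulls_towards_boundary(self):
        """On a series with clearly positive r1, B_sr exceeds B_f in |posterior mean|."""
        y = simulate_ar1(GenParams(phi=0.8), 15, RngSpec(41, 0, 1))
        flat = summarize_posterior(
            sample_posterior(y, PriorSpec(phi_prior="flat"), n_chains=4, n_iter=4000, seed=2)
        )
        sr = summarize_posterior(
            sample_posterior(
                y, PriorSpec(phi_prior="symmetrized_reference"), n_chains=4, n_iter=4000, seed=2
            )
        )
        assert abs(sr.phi_hat) > abs(flat.phi_hat)

    def test_sign_flip_symmetry(self, fixture_series):
        """Negating the series leaves the phi posterior unchanged, flips mu."""
        draws_a = sample_posterior(fixture_series, n_chains=4, n_iter=6000, seed=3)
        draws_b = sample_posterior(-fixture_series, n_chains=4, n_iter=6000, seed=7)
        a = summarize_posterior(draws_a)
        b = summarize_posterior(draws_b)
        assert b.phi_hat == pytest.approx(a.phi_hat, abs=0.03)
        mu_a = draws_a.chains[:, :, 1].mean()
        mu_b = draws_b.chains[:, :, 1].mean()
        assert mu_b == pytest.approx(-mu_a, abs=0.05)

    def test_iteration_and_chain_validation(self, fixture_series):
        with pytest.raises(ValueError):
            sample_posterior(fixture_series, n_iter=100)
        with pytest.raises(ValueError):
            sample_posterior(fixture_series, n_chains=1)


class TestSummaries:
    def _draws(self, values):
        arr = np.array(values, dtype=float)
        chains = np.zeros((2, arr.size // 2, 3))
        chains[:, :, 0] = arr.reshape(2, -1)
        chains[:, :, 2] = 1.0
        return PosteriorDraws(
            chains=chains, rhat={p: 1.0 for p in PARAM_NAMES},
            accept_rate={p: 0.4 for p in PARAM_NAMES}, prior=PriorSpec(),
        )

    def test_pooled_mean_point_estimate(self):
        res = summarize_posterior(self._draws([-0.2, 0.0, 0.2, 0.4]))
        assert res.phi_hat == pytest.approx(0.1)
        assert res.method == "bayes_flat"

    def test_credible_interval_decision(self):
        res = summarize_posterior(self._draws(np.linspace(0.1, 0.9, 40)))
        assert res.diagnostics["reject"] is True
        res2 = summarize_posterior(self._draws(np.linspace(-0.4, 0.5, 40)))
        assert res2.diagnostics["reject"] is False

    def test_median_option(self):
        res = summarize_posterior(self._draws([0.0, 0.1, 0.2, 0.9]), point="median")
        assert res.phi_hat == pytest.approx(0.15)
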