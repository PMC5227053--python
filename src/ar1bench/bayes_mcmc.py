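"""Bayesian AR(1) estimation by component-wise adaptive random-walk Metropolis.

Two priors on the autocorrelation are supported on the stationary region
(-1, 1): the flat prior pi_f(phi) = 1/2 and the symmetrized reference prior
pi_sr(phi) = 1 / (2 pi sqrt(1 - phi^2)), which places more mass near |phi| = 1.
(pi_sr as written integrates to 1/2 over (-1, 1); the missing normalisation is
irrelevant to MCMC.)  The mean gets a normal prior and the innovation SD a
gamma prior (shape-rate), defaulting to mu ~ N(0, 2^2) and sigma_e ~ Gamma(2, 2).

The sampler updates (phi, mu, sigma_e) one component at a time with Gaussian
proposals whose step sizes adapt during warmup towards 30-50 % acceptance.
Proposals outside the support are rejected through a -inf prior.  The first
half of each chain is discarded; chains are pooled for summaries, while the
Gelman-Rubin R-hat is computed before pooling.  The core runs many series and
chains simultaneously as (n_series, n_chains) arrays, which is what makes the
Monte Carlo studies tractable; a single series is the n_series = 1 case.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .base import BaseAR1Estimator, EstimateResult
from .errors import StepAdaptationError
from .likelihood_mle import SuffStats, _loglik_suff
from .model import validate_series

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "log_prior",
    "phi_prior_density",
    "sample_posterior",
    "sample_posterior_batch",
    "gelman_rubin",
    "summarize_posterior",
    "BayesAR1",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

PARAM_NAMES = ("phi", "mu", "sigma_e")

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.40  # centre of the 30-50 % band


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Prior configuration for (phi, mu, sigma_e).

    ``phi_prior`` is ``"flat"`` or ``"symmetrized_reference"``; ``mu`` is
    normal with mean ``mu_mean`` and SD ``mu_sd``; ``sigma_e`` is gamma with
    ``sigma_shape`` and ``sigma_rate`` (shape-rate convention).  The defaults
    match the generating model of the simulation studies (mean 0, unit
    innovation variance).
    """

    phi_prior: str = "flat"
    mu_mean: float = 0.0
    mu_sd: float = 2.0
    sigma_shape: float = 2.0
    sigma_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.phi_prior not in ("flat", "symmetrized_reference"):
            raise ValueError(f"unknown phi_prior {self.phi_prior!r}")
        if self.mu_sd <= 0 or self.sigma_shape <= 0 or self.sigma_rate <= 0:
            raise ValueError("mu_sd, sigma_shape and sigma_rate must be > 0")

    @property
    def method_name(self) -> str:
        return "bayes_flat" if self.phi_prior == "flat" else "bayes_sr"


def phi_prior_density(phi, kind: str):
    """Density of the phi prior on (-1, 1): pi_f = 1/2 or pi_sr = 1/(2 pi sqrt(1-phi^2))."""
    phi = np.asarray(phi, dtype=float)
    inside = np.abs(phi) < 1.0
    if kind == "flat":
        dens = np.where(inside, 0.5, 0.0)
    elif kind == "symmetrized_reference":
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = np.where(inside, 1.0 / (2.0 * np.pi * np.sqrt(1.0 - phi**2)), 0.0)
    else:
        raise ValueError(f"unknown phi prior kind {kind!r}")
    return dens if dens.ndim else float(dens)


def log_prior(phi, mu, sigma_e, prior: PriorSpec):
    """Joint log prior log pi(phi) + log N(mu) + log Gamma(sigma_e); -inf off support.

    Broadcasts over array arguments.  Values are unnormalised only in the
    sense that pi_sr integrates to 1/2; all constant offsets are kept.
    """
    phi = np.asarray(phi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma_e = np.asarray(sigma_e, dtype=float)
    valid = (np.abs(phi) < 1.0) & (sigma_e > 0.0)
    phi_c = np.where(valid, phi, 0.0)
    sig_c = np.where(valid, sigma_e, 1.0)

    if prior.phi_prior == "flat":
        lp_phi = np.log(0.5)
    else:
        # log pi_sr = -log(2*pi*sqrt(1-phi^2)) = -log(2*pi) - 0.5*log(1-phi^2)
        lp_phi = -np.log(2.0 * np.pi) - 0.5 * np.log1p(-(phi_c**2))
    lp_mu = -0.5 * ((mu - prior.mu_mean) / prior.mu_sd) ** 2 - np.log(prior.mu_sd) - 0.5 * _LOG_2PI
    a, b = prior.sigma_shape, prior.sigma_rate
    lp_sig = a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(sig_c) - b * sig_c

    out = np.where(valid, lp_phi + lp_mu + lp_sig, -np.inf)
    return out if out.ndim else float(out)


@dataclasses.dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws for one series.

    ``chains`` has shape (n_chains, n_kept, 3) with parameter order
    (phi, mu, sigma_e).  ``rhat`` and ``accept_rate`` are keyed by parameter.
    """

    chains: np.ndarray
    rhat: dict[str, float]
    accept_rate: dict[str, float]
    prior: PriorSpec

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def n_kept(self) -> int:
        return self.chains.shape[1]

    def pooled(self, param: str = "phi") -> np.ndarray:
        k = PARAM_NAMES.index(param)
        return self.chains[:, :, k].reshape(-1)


def gelman_rubin(chains: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor R-hat.

    ``chains`` is (n_chains, n) with n_chains >= 2 and equal lengths n >= 2.
    W is the mean within-chain variance, B/n the variance of the chain means,
    var+ = (n-1)/n * W + B/n, and R-hat = sqrt(var+ / W).  Returns NaN when
    W = 0 (degenerate chains).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = arr.shape[1]
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = arr.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return float("nan")
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def _stack_stats(Y: np.ndarray) -> SuffStats:
    """Sufficient statistics of each row, stored as (S, 1) arrays for broadcasting."""
    col = lambda v: np.asarray(v, dtype=float)[:, None]
    return SuffStats(
        T=Y.shape[1],
        y1=col(Y[:, 0]),
        q11=col(np.einsum("ij,ij->i", Y[:, 1:], Y[:, 1:])),
        q00=col(np.einsum("ij,ij->i", Y[:, :-1], Y[:, :-1])),
        q01=col(np.einsum("ij,ij->i", Y[:, 1:], Y[:, :-1])),
        s1=col(Y[:, 1:].sum(axis=1)),
        s0=col(Y[:, :-1].sum(axis=1)),
    )


def _log_post(st: SuffStats, prior: PriorSpec, phi, mu, sigma):
    valid = (np.abs(phi) < 1.0) & (sigma > 0.0)
    phi_c = np.where(valid, phi, 0.0)
    sig_c = np.where(valid, sigma, 1.0)
    ll = _loglik_suff(st, mu, phi_c, sig_c**2)
    lp = log_prior(phi_c, mu, sig_c, prior)
    return np.where(valid, ll + lp, -np.inf)


def _run_sampler(
    Y: np.ndarray,
    prior: PriorSpec,
    n_chains: int,
    n_iter: int,
    rng: np.random.Generator,
    store_all: bool = False,
):
    """Vectorised Metropolis over (n_series, n_chains) states.

    Returns phi draws (S, C, kept), running moments of mu and sigma_e per
    chain, per-parameter pooled post-warmup acceptance rates, the kept length,
    and (when ``store_all``) the full (S, C, kept, 3) draw array.
    """
    S = Y.shape[0]
    C = n_chains
    warmup = n_iter // 2
    kept = n_iter - warmup
    st = _stack_stats(Y)
    sd_y = Y.std(axis=1, ddof=1)[:, None]
    ybar = Y.mean(axis=1)[:, None]

    phi = rng.uniform(-0.9, 0.9, (S, C))
    mu = ybar + sd_y * rng.standard_normal((S, C))
    sigma = sd_y * np.exp(rng.uniform(-1.0, 1.0, (S, C)))
    logp = _log_post(st, prior, phi, mu, sigma)

    steps = [0.3 * np.ones((S, C)), np.broadcast_to(sd_y, (S, C)).copy(), 0.5 * np.ones((S, C))]
    state = [phi, mu, sigma]

    acc_window = np.zeros((3, S, C))
    accepted_warmup = np.zeros((3, S, C), dtype=bool)
    acc_sampling = np.zeros(3)

    phi_draws = np.empty((S, C, kept))
    all_draws = np.empty((S, C, kept, 3)) if store_all else None
    mu_sum = np.zeros((S, C))
    mu_sumsq = np.zeros((S, C))
    sig_sum = np.zeros((S, C))
    sig_sumsq = np.zeros((S, C))

    for i in range(n_iter):
        in_warmup = i < warmup
        for k in range(3):
            prop = list(state)
            prop[k] = state[k] + steps[k] * rng.standard_normal((S, C))
            logp_new = _log_post(st, prior, prop[0], prop[1], prop[2])
            accept = np.log(rng.uniform(size=(S, C))) < logp_new - logp
            state[k] = np.where(accept, prop[k], state[k])
            logp = np.where(accept, logp_new, logp)
            if in_warmup:
                acc_window[k] += accept
                accepted_warmup[k] |= accept
            else:
                acc_sampling[k] += accept.mean()
        if in_warmup and (i + 1) % _ADAPT_WINDOW == 0:
            rate = acc_window / _ADAPT_WINDOW
            for k in range(3):
                steps[k] = np.clip(steps[k] * np.exp(rate[k] - _TARGET_ACCEPT), 1e-6, 50.0)
            acc_window[:] = 0.0
        if not in_warmup:
            j = i - warmup
            phi_draws[:, :, j] = state[0]
            mu_sum += state[1]
            mu_sumsq += state[1] ** 2
            sig_sum += state[2]
            sig_sumsq += state[2] ** 2
            if store_all:
                for k in range(3):
                    all_draws[:, :, j, k] = state[k]

    if not accepted_warmup.all():
        raise StepAdaptationError(
            "Metropolis step-size adaptation failed: some chain accepted no "
            "proposal for at least one parameter during warmup"
        )

    accept_rate = {PARAM_NAMES[k]: float(acc_sampling[k] / kept) for k in range(3)}
    moments = {
        "mu": (mu_sum / kept, mu_sumsq / kept),
        "sigma_e": (sig_sum / kept, sig_sumsq / kept),
    }
    return phi_draws, moments, accept_rate, kept, all_draws


def _rhat_from_moments(mean_c: np.ndarray, meansq_c: np.ndarray, n: int) -> np.ndarray:
    """R-hat per series from per-chain first/second moments, shapes (S, C)."""
    within = (meansq_c - mean_c**2) * n / (n - 1)
    W = within.mean(axis=1)
    B_over_n = mean_c.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(((n - 1) / n * W + B_over_n) / W)


def sample_posterior_batch(
    Y: np.ndarray,
    prior: PriorSpec = PriorSpec(),
    n_chains: int = 4,
    n_iter: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, np.ndarray]:
    """Run the sampler on every row of ``Y``; return per-series posterior summaries.

    Keys: ``phi_mean``, ``phi_sd``, ``ci_low``, ``ci_high`` (central 95 % CrI),
    ``reject`` (CrI excludes 0), ``mu_mean``, ``sigma_e_mean``, ``rhat_phi``,
    ``rhat_mu``, ``rhat_sigma_e``, ``phi_median``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200")
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2")
    rng = np.random.default_rng(seed)
    phi_draws, moments, accept_rate, kept, _ = _run_sampler(Y, prior, n_chains, n_iter, rng)

    S, C, _ = phi_draws.shape
    pooled = phi_draws.reshape(S, C * kept)
    ci = np.percentile(pooled, [2.5, 97.5], axis=1)
    phi_mean_c = phi_draws.mean(axis=2)
    phi_meansq_c = (phi_draws**2).mean(axis=2)
    out = {
        "phi_mean": pooled.mean(axis=1),
        "phi_sd": pooled.std(axis=1, ddof=1),
        "phi_median": np.median(pooled, axis=1),
        "ci_low": ci[0],
        "ci_high": ci[1],
        "reject": (ci[0] > 0.0) | (ci[1] < 0.0),
        "mu_mean": moments["mu"][0].mean(axis=1),
        "sigma_e_mean": moments["sigma_e"][0].mean(axis=1),
        "rhat_phi": _rhat_from_moments(phi_mean_c, phi_meansq_c, kept),
        "rhat_mu": _rhat_from_moments(*moments["mu"], kept),
        "rhat_sigma_e": _rhat_from_moments(*moments["sigma_e"], kept),
        "accept_rate": accept_rate,
    }
    return out


def sample_posterior(
    series,
    prior: PriorSpec = PriorSpec(),
    n_chains: int = 4,
    n_iter: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> PosteriorDraws:
    """Sample the posterior of (phi, mu, sigma_e) for one series.

    ``n_iter`` is the total per-chain iteration count; the first half is
    warmup and is discarded.
    """
    y = validate_series(series)
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200")
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2")
    rng = np.random.default_rng(seed)
    _, _, accept_rate, kept, all_draws = _run_sampler(
        y[None, :], prior, n_chains, n_iter, rng, store_all=True
    )
    chains = all_draws[0]  # (n_chains, kept, 3)

    rhat = {
        PARAM_NAMES[k]: gelman_rubin(chains[:, :, k]) for k in range(3)
    }
    return PosteriorDraws(chains=chains, rhat=rhat, accept_rate=accept_rate, prior=prior)


def summarize_posterior(draws: PosteriorDraws, point: str = "mean") -> EstimateResult:
    """Posterior summaries of phi: point estimate, SD, central 95 % CrI, decision.

    ``point`` selects the posterior mean (default) or median.  The decision
    ingredient recorded in diagnostics is whether the CrI excludes zero.
    """
    pooled = draws.pooled("phi")
    if pooled.size == 0:
        raise ValueError("empty draws")
    if point == "mean":
        phi_hat = float(pooled.mean())
    elif point == "median":
        phi_hat = float(np.median(pooled))
    else:
        raise ValueError("point must be 'mean' or 'median'")
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    return EstimateResult(
        method=draws.prior.method_name,
        phi_hat=phi_hat,
        se_hat=float(pooled.std(ddof=1)),
        stationary_flag=True,
        diagnostics={
            "ci_low": float(lo),
            "ci_high": float(hi),
            "reject": bool(lo > 0.0 or hi < 0.0),
            "rhat": dict(draws.rhat),
            "accept_rate": dict(draws.accept_rate),
        },
    )


class BayesAR1(BaseAR1Estimator):
    """Bayesian lag-1 autocorrelation estimator (posterior mean of phi).

    Parameters
    ----------
    prior : "flat", "sr", or a :class:`PriorSpec`.
    n_chains, n_iter : chain count and total per-chain iterations (half warmup).
    seed : RNG seed for proposals and initial states.
    point : "mean" or "median" posterior point estimate.
    """

    def __init__(self, prior="flat", n_chains: int = 4, n_iter: int = 2000,
                 seed: int = 0, point: str = "mean"):
        self.prior = prior
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.seed = seed
        self.point = point

    def _prior_spec(self) -> PriorSpec:
        if isinstance(self.prior, PriorSpec):
            return self.prior
        if self.prior in ("flat",):
            return PriorSpec(phi_prior="flat")
        if self.prior in ("sr", "symmetrized_reference"):
            return PriorSpec(phi_prior="symmetrized_reference")
        raise ValueError(f"unknown prior {self.prior!r}")

    def _fit(self, y: np.ndarray) -> None:
        spec = self._prior_spec()
        draws = sample_posterior(y, prior=spec, n_chains=self.n_chains,
                                 n_iter=self.n_iter, seed=self.seed)
        res = summarize_posterior(draws, point=self.point)
        self.method = res.method
        self.phi_ = res.phi_hat
        self.se_ = res.se_hat
        self.stationary_ = True
        self.diagnostics_ = res.diagnostics
        self.draws_ = draws
        self.mu_ = float(draws.chains[:, :, 1].mean())
        self.sigma_e_ = float(draws.chains[:, :, 2].mean())
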