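# Methods

## Generating model and simulator

Series are drawn from the mean-centred Gaussian ARMA(1,1)

```
y_t - mu = phi (y_{t-1} - mu) + theta e_{t-1} + e_t,   e_t ~ N(0, sigma_e^2),
```

with |phi| < 1 (stationarity) and |theta| < 1 (invertibility) enforced at
construction; theta = 0 gives the AR(1) case, and the AR(1) simulator is the
theta = 0 path of the same code, so the two agree bit-for-bit under the same
seed. We use the centred form for both models so that `mu` is the process
mean in every case (the uncentred ARMA convention shifts the mean to
mu/(1-phi); the two coincide at mu = 0, the only value the studies use).

Initialisation is not part of the model statement, so we chose one mechanism
for both models: start at the mean (y_0 = mu, e_0 = 0), apply the recursion
as a linear filter with zero initial state, and discard a 100-step burn-in.
For the |phi| <= 0.90 grids used here the distance from stationarity after
burn-in is at most phi^100 ~ 3e-5 in the autocovariances, i.e. negligible
against Monte Carlo error, which the moment tests confirm (sample mean,
variance and lag-1 autocorrelation of 1e5-point runs match mu,
sigma_e^2/(1-phi^2) and the closed-form ARMA(1,1) rho_1).

Randomness is counter-based: the triple (master_seed, condition_index,
replication_index) seeds an independent PCG64 stream per series. Conditions
are therefore order-independent and embarrassingly parallel, any single
series can be regenerated in isolation, and the batch simulator is provably
(and testedly) row-identical to the single-series API.

The simulator emulates the studies' conditions exactly: mu = 0, sigma_e = 1,
Gaussian innovations. It does not emulate features of real diary data —
non-Gaussian or heteroscedastic innovations, measurement rounding, missing
observations, higher-order dependence — so passing benchmarks here speak to
estimator behaviour under the clean model, not to robustness against those
complications (except the deliberate moving-average misspecification of the
second study design).

## Estimators

**r1 (Yule–Walker).** phi_hat = sum_{t<T}(y_t-ybar)(y_{t+1}-ybar) /
sum_t(y_t-ybar)^2; |phi_hat| < 1 always (Cauchy–Schwarz). Its SE recipe
sqrt(sigma_e^2_hat/((T-1) s_y^2)) leaves the two variance estimates
unspecified; we take s_y^2 as the usual sample variance (divisor T-1) and
sigma_e^2_hat = s_y^2 (1 - phi_hat^2), the Yule–Walker innovation-variance
identity, making the recipe self-contained: SE = sqrt((1-phi_hat^2)/(T-1)).

**C-statistic.** Young's bias compensation adds
[(y_1-ybar)^2 + (y_T-ybar)^2] / (2 sum_t(y_t-ybar)^2) to r1. Some sources
print the numerator as a *product* of the two end-point squares; the product
has the wrong units (fourth power over second power) and cannot be
asymptotically unbiased, so the sum is the default and the product form is
available behind `correction="product"` for comparison. The correction is
non-negative, so phi_hat_C >= phi_hat_r1 always, and on pathological series
it can push the estimate past 1; for the t test such estimates are clipped
to +/-0.9999 and flagged.

**OLS.** Same numerator over sum_{t<T}(y_t-ybar)^2, so |phi_hat| > 1 is
possible; results are reported both including all estimates (OLS-A) and
excluding the non-stationary ones (OLS-S, strict |phi_hat| > 1 exclusion —
the boundary counts as stationary). The asymptotic SE formula
sqrt((T-(T-1)phi_hat^2-1)/(T^2-T-T y_T^2)) is implemented literally. Its
denominator depends on the last *raw* observation, which breaks scale
invariance and allows non-positive values; we suspect a transcription slip
in the source literature, but keep the formula as printed, returning an
undefined-SE marker (NaN plus diagnostics) whenever the radicand or
denominator is non-positive. Downstream averages skip and count these.

**Exact MLE.** The likelihood is the exact stationary Gaussian one — y_1
drawn from N(mu, sigma_e^2/(1-phi^2)), later terms conditioned on their
predecessor — not the conditional likelihood (which would reproduce least
squares and defeat the comparison). It is evaluated through five O(T)-setup
sufficient statistics, making each evaluation O(1), and maximised by BFGS
with the analytic gradient in unconstrained coordinates (mu, atanh(phi),
log sigma_e), so |phi_hat| < 1 by construction. Start at the r1 estimate
(clipped to +/-0.95) with fallback restarts at phi_0 = 0 and -r1; gradient
tolerance 1e-8, at most 500 iterations; non-convergence is flagged and the
best visited point returned. Unimodality is not assumed — the multistart is
validated against a dense-matrix profile grid search (phi step 1e-3, GLS
profiling of mu and sigma) on short fixtures, and against statsmodels'
exact ARIMA(1,0,0) MLE on longer ones.

A note on the asymptotic bias: the classic result for the AR(1) MLE with
estimated mean is bias ~ -(1+3 phi)/T. Part of the literature prints this
with the sign of the phi term flipped, as (-3 phi + 1)/T;
`asymptotic_bias("mle_mu_estimated", ...)` reproduces that printed form
because it serves as an oracle for the claims being benchmarked, but our
empirical bias tests assert the classic -(1+3 phi)/T, which the exact MLE
demonstrably follows (at T = 25 the empirical bias is -0.016/-0.039/-0.057
at phi = -0.2/0/0.2, versus -0.016/-0.040/-0.064 predicted).

**Bayesian MCMC.** Posterior ∝ exact likelihood × prior, with either the
flat prior pi_f(phi) = 1/2 on (-1, 1) or the symmetrized reference prior
pi_sr(phi) = 1/(2 pi sqrt(1-phi^2)) (as written it integrates to 1/2 on the
stationary region — it is the stationary half of the symmetrized prior —
which is irrelevant to MCMC), plus mu ~ N(0, 2^2) and sigma_e ~ Gamma(2, 2)
in the shape–rate convention. The Gamma's ambiguity (rate vs scale) and the
credible-interval convention (central percentile, not HPD) were resolved to
the defaults of the common Bayesian tooling.

The sampler is a component-wise random-walk Metropolis: Gaussian proposals
per parameter, proposals outside the support rejected via a -inf prior (no
reflection), step sizes adapted every 50 warmup iterations by a
multiplicative rule targeting ~40 % acceptance (within the usual 30–50 %
band for component-wise updates). Defaults are 4 chains × 2000 iterations
with the first half discarded; chains are pooled for summaries (posterior
mean — or median on request — SD, central 95 % interval), while the classic
Gelman–Rubin R-hat (var+ = (n-1)/n W + B/n, R-hat = sqrt(var+/W); undefined
when W = 0) is computed per parameter before pooling. A chain that accepts
no proposal for some parameter during the whole warmup raises a step-size
adaptation error rather than returning garbage. The sampler runs all
replications and chains of a condition simultaneously as
(n_series, n_chains) arrays; correctness is checked against a 3-D
Riemann-quadrature oracle built on the dense multivariate-normal likelihood,
for both priors.

A gradient-based sampler would mix faster per iteration, but for a
3-parameter posterior the adaptive random-walk reaches R-hat < 1.02 in
essentially all replications at the default settings, and posterior
summaries — the quantities being benchmarked — agree with quadrature to
well within Monte Carlo error.

## Evaluation

Per condition (method, T, phi[, theta]) over N replications: bias =
mean(phi_hat) - phi; empirical SD with divisor N-1; mean estimated SE over
the replications where it is defined; SE bias = mean SE - empirical SD; EPr
= rejection fraction at alpha = 0.05 (actual type-I rate at phi = 0, power
elsewhere); mean estimate with its 2.5th/97.5th percentiles (linear
interpolation between order statistics — the interval-summary convention we
adopted where the source description is ambiguous). Tests are two-sided.
Decision routing: r1, C, MLE and OLS-S through the correlation t statistic
phi_hat sqrt(T-2)/sqrt(1-phi_hat^2) with df = T-3; OLS-A through
phi_hat/SE with df = T-3 (undefined SEs count as recorded non-rejections and
are tallied as dropped); Bayesian methods through the credible interval.

## Study designs and problem sizes

Defaults mirror the benchmark designs: Study 1 crosses T in
{10, 25, 40, 50, 100} with phi from -0.90 to 0.90 in steps of 0.10 (19
values, theta = 0, all six methods); Study 2 crosses T in {25, 50} with phi
and theta from -0.90 to 0.90 in steps of 0.15 (13 values each; MLE and B_sr
only); the prior-sensitivity design fixes T = 10, phi in {-0.5, 0, 0.5} and
varies the hyperpriors over seven columns at 1000 replications. The
replication default is N = 2000 per condition (the source design is
internally inconsistent between 2000 and 5000; both are a config value
away). The acceptance script and test suite use the replication counts
listed with each check (50 000 for the closed-form bias anchors, 20 000 for
the OLS non-stationarity rate, 2000 for the T = 100 rejection rates,
500–1000 for the MCMC-based anchors) — sizes at which the Monte Carlo error
is comfortably inside each comparison's tolerance.

## Known limitations

- Only ARMA orders up to (1,1), Gaussian innovations, complete series.
- The OLS SE formula is reproduced as printed, including its scale
  non-invariance; treat `se_hat` for OLS as a benchmark artefact, not a
  recommended uncertainty estimate.
- The Metropolis sampler is tuned for this 3-parameter posterior; it is not
  a general-purpose MCMC engine.
- Posterior summaries carry Monte Carlo error of order
  posterior-SD/sqrt(effective draws); the defaults keep this near 0.01 for
  phi, which matters only if you push tolerances below that.
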