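# ar1bench

Benchmarking estimators of the lag-1 autocorrelation in short time series.

Short intensive-longitudinal series — daily mood ratings, single-case
designs, physiological diaries — are routinely modelled as a first-order
autoregression,

```
y_t = mu + phi (y_{t-1} - mu) + e_t,      e_t ~ N(0, sigma_e^2),  |phi| < 1,
```

yet with T between 10 and 100 observations every standard estimator of phi is
noticeably biased and variable, and the estimators disagree with each other.
`ar1bench` implements six of them side by side, with the simulation and
evaluation machinery needed to compare them honestly:

| method | estimator | estimated SE | H0: phi=0 decision |
|---|---|---|---|
| `r1` | Yule–Walker lag-1 sample autocorrelation | sqrt(sigma_e^2/((T-1) s_y^2)) | correlation t, df = T-3 |
| `c_stat` | Young's C-statistic (r1 + end-point correction) | sqrt((T-2)/((T-1)(T+1))) | correlation t, df = T-3 |
| `ols` | least squares (can give \|phi_hat\| > 1) | asymptotic formula (may be undefined) | OLS-A: t = phi/SE; OLS-S: correlation t on the stationary subset |
| `mle` | exact stationary Gaussian MLE (BFGS, tanh/log coordinates) | r1 recipe with the MLE innovation variance | correlation t, df = T-3 |
| `bayes_flat` | posterior mean, flat prior pi_f(phi) = 1/2 | posterior SD | 95 % credible interval excludes 0 |
| `bayes_sr` | posterior mean, symmetrized reference prior pi_sr(phi) = 1/(2 pi sqrt(1-phi^2)) | posterior SD | 95 % credible interval excludes 0 |

The Bayesian posteriors use mu ~ N(0, 2^2) and sigma_e ~ Gamma(2, 2)
(shape–rate) hyperpriors and a component-wise adaptive random-walk Metropolis
sampler (4 chains × 2000 iterations by default, half warmup, Gelman–Rubin
R-hat per parameter), vectorised across replications so full Monte Carlo
conditions run in seconds.

On top of the estimators sit a stationary AR(1)/ARMA(1,1) simulator
(Gaussian innovations, burn-in initialisation, counter-based seeding) and
study runners for a fully crossed estimator-comparison design, an
ARMA(1,1)-misspecification design (data generated with a moving-average
term theta but analysed as AR(1)), and a hyperprior-sensitivity design.

## Worked example

```
$ ar1bench simulate --T 25 --phi 0.6 --seed 11 --out demo.csv
wrote 25 observations to demo.csv
$ ar1bench estimate --method all --in demo.csv --seed 3
        r1: phi_hat=+0.3954  se=0.1875  stationary=True
         c: phi_hat=+0.4122  se=0.1920  stationary=True
       ols: phi_hat=+0.3973  se=0.1837  stationary=True
       mle: phi_hat=+0.3938  se=0.1831  stationary=True
bayes-flat: phi_hat=+0.4453  se=0.2020  stationary=True
  bayes-sr: phi_hat=+0.4794  se=0.2050  stationary=True
```

The series was generated with phi = 0.60; at T = 25 all frequentist
estimators land near 0.40 — the familiar downward small-sample bias — while
the symmetrized reference prior, which places extra mass near |phi| = 1,
pulls the posterior mean closest to the truth. Add `--json` for
machine-readable output including R-hat and acceptance-rate diagnostics.

The same API is available programmatically as scikit-learn-style estimators:

```python
import ar1bench as ab

y = ab.simulate_ar1(ab.GenParams(phi=0.6), T=25, rng=ab.RngSpec(11))
est = ab.ExactMLEAR1().fit(y)
est.phi_, est.se_, est.mu_, est.sigma_e_
```

Monte Carlo studies run from Python or the shell:

```python
cfg = ab.StudyConfig.study1(T_grid=[10, 25], n_reps=2000, master_seed=1,
                            output_dir="out/")
table = ab.run_study(cfg)   # bias, sd_emp, mean_se, se_bias, epr, percentiles
```

`ar1bench study1|study2|priors --reps ... --seed ... --out DIR` does the same
from the command line, writing a long-format CSV per condition incrementally
(interrupted runs resume where they stopped).

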