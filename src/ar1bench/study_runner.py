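"""Monte Carlo study orchestration: estimator comparison and misspecification.

Study 1 simulates correct AR(1) data over a (T, phi) grid and evaluates all
six estimators; Study 2 simulates ARMA(1,1) data over a (T, phi, theta) grid
and evaluates the exact MLE and the symmetrized-reference-prior Bayesian
estimator, analysing the data as if it were AR(1).  A paired design is used:
within a condition every method sees the identical simulated series.  OLS is
expanded into two reporting variants, OLS-A (all estimates, SE-based t test)
and OLS-S (non-stationary estimates dropped, correlation t test).

Seeds derive from (master_seed, condition_index, replication_index), so any
condition can be recomputed in isolation and execution order is irrelevant.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import closed_form, likelihood_mle
from .bayes_mcmc import PriorSpec, sample_posterior_batch
from .evaluation import (
    ConditionSummary,
    correlation_test_reject,
    se_test_reject,
    summarize_condition_arrays,
)
from .model import GenParams, simulate_batch

__all__ = [
    "StudyConfig",
    "ALL_METHODS",
    "TABLE2_PRIORS",
    "run_study",
    "run_prior_sensitivity",
    "compare_methods",
]

ALL_METHODS = ("r1", "c_stat", "ols", "mle", "bayes_flat", "bayes_sr")

#: The seven hyperprior columns of the prior-sensitivity design:
#: (mu_mean, mu_sd, sigma_shape, sigma_rate).
TABLE2_PRIORS = (
    (0.0, 2.0, 2.0, 2.0),
    (1.0, 2.0, 2.0, 2.0),
    (0.0, 5.0, 2.0, 2.0),
    (1.0, 5.0, 2.0, 2.0),
    (0.0, 2.0, 1.0, 1.0),
    (0.0, 2.0, 1.0, 2.0),
    (0.0, 2.0, 2.0, 1.0),
)

CSV_COLUMNS = [
    "method", "T", "phi", "theta", "n_reps", "bias", "sd_emp", "mean_se",
    "se_bias", "epr", "mean_phi_hat", "p2_5", "p97_5", "n_dropped",
]


def _grid(start: float, stop: float, step: float) -> list[float]:
    return [round(v, 10) for v in np.arange(start, stop + step / 2, step)]


@dataclasses.dataclass
class StudyConfig:
    """Configuration of one simulation study."""

    study: str = "study1"
    T_grid: list[int] = dataclasses.field(default_factory=lambda: [10, 25, 40, 50, 100])
    phi_grid: list[float] = dataclasses.field(default_factory=lambda: _grid(-0.9, 0.9, 0.1))
    theta_grid: list[float] = dataclasses.field(default_factory=lambda: [0.0])
    n_reps: int = 2000
    master_seed: int = 0
    methods: tuple[str, ...] = ALL_METHODS
    n_chains: int = 4
    n_iter: int = 2000
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for phi in self.phi_grid:
            if abs(phi) >= 1.0:
                raise ValueError(f"phi grid value {phi} is non-stationary")
        for th in self.theta_grid:
            if abs(th) >= 1.0:
                raise ValueError(f"theta grid value {th} is non-invertible")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not self.methods:
            raise ValueError("methods must be nonempty")

    @classmethod
    def study1(cls, **overrides) -> "StudyConfig":
        """Correct-specification design: T in {10,25,40,50,100}, phi step 0.10."""
        return cls(study="study1", **overrides)

    @classmethod
    def study2(cls, **overrides) -> "StudyConfig":
        """Misspecification design: ARMA(1,1) data, MLE and B_sr only."""
        defaults = dict(
            study="study2",
            T_grid=[25, 50],
            phi_grid=_grid(-0.9, 0.9, 0.15),
            theta_grid=_grid(-0.9, 0.9, 0.15),
            methods=("mle", "bayes_sr"),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def prior_sensitivity(cls, **overrides) -> "StudyConfig":
        """Hyperprior sensitivity design: T = 10, phi in {-0.5, 0, 0.5}, 1000 reps."""
        defaults = dict(
            study="prior_sensitivity",
            T_grid=[10],
            phi_grid=[-0.5, 0.0, 0.5],
            theta_grid=[0.0],
            n_reps=1000,
            methods=("bayes_flat", "bayes_sr"),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def conditions(self):
        """Enumerate (condition_index, T, phi, theta) over the full crossed grid."""
        prod = itertools.product(self.T_grid, self.phi_grid, self.theta_grid)
        for idx, (T, phi, theta) in enumerate(prod):
            yield idx, T, phi, theta


def _bayes_seed(master_seed: int, condition_index: int, offset: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((master_seed, condition_index, 1_000_003 + offset))


def _analyse_condition(
    Y: np.ndarray,
    config: StudyConfig,
    condition_index: int,
    T: int,
    phi: float,
    theta: float,
) -> list[ConditionSummary]:
    """Apply every requested method to the shared series batch of one condition."""
    rows: list[ConditionSummary] = []
    common = dict(phi_true=phi, T=T, theta_true=theta)

    if "r1" in config.methods:
        est, se = closed_form.r1_batch(Y)
        rej = correlation_test_reject(est, T)
        rows.append(summarize_condition_arrays("r1", est, se, rej, **common))
    if "c_stat" in config.methods:
        est, se = closed_form.c_stat_batch(Y)
        rej = correlation_test_reject(est, T, clip=True)
        rows.append(summarize_condition_arrays("c_stat", est, se, rej, **common))
    if "ols" in config.methods:
        est, se, stationary = closed_form.ols_batch(Y)
        rej_a = se_test_reject(est, se, T)
        rows.append(summarize_condition_arrays("ols_a", est, se, rej_a, **common))
        # OLS-S: correlation t test on the stationary subset only.
        rej_s = np.zeros(est.size, dtype=bool)
        interior = np.abs(est) < 1.0
        rej_s[interior] = correlation_test_reject(est[interior], T)
        rej_s[np.abs(est) == 1.0] = True  # |t| -> infinity at the boundary
        rows.append(
            summarize_condition_arrays("ols_s", est, se, rej_s, stationary_only=True, **common)
        )
    if "mle" in config.methods:
        fit = likelihood_mle.mle_batch(Y)
        rej = correlation_test_reject(fit["phi"], T)
        rows.append(summarize_condition_arrays("mle", fit["phi"], fit["se"], rej, **common))
    for offset, (name, kind) in enumerate(
        [("bayes_flat", "flat"), ("bayes_sr", "symmetrized_reference")]
    ):
        if name not in config.methods:
            continue
        prior = PriorSpec(phi_prior=kind)
        post = sample_posterior_batch(
            Y,
            prior=prior,
            n_chains=config.n_chains,
            n_iter=config.n_iter,
            seed=_bayes_seed(config.master_seed, condition_index, offset),
        )
        rows.append(
            summarize_condition_arrays(
                name, post["phi_mean"], post["phi_sd"], post["reject"], **common
            )
        )
    return rows


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run a full crossed study; returns one row per (method-variant, condition).

    When ``config.output_dir`` is set, rows are appended to
    ``results_long.csv`` as each condition finishes; conditions already
    present in that file are skipped, making interrupted runs resumable.
    Per-method CSVs and a config sidecar are written at the end.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    long_path = out_dir / "results_long.csv" if out_dir else None
    done: set[tuple] = set()
    existing = None
    if long_path is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        if long_path.exists():
            existing = pd.read_csv(long_path)
            done = {
                (r.T, round(r.phi, 10), round(r.theta, 10))
                for r in existing.itertuples(index=False)
            }

    frames = [existing] if existing is not None else []
    for idx, T, phi, theta in config.conditions():
        if (T, round(phi, 10), round(theta, 10)) in done:
            continue
        params = GenParams(mu=0.0, phi=phi, theta=theta, sigma_e=1.0)
        Y = simulate_batch(params, T, config.n_reps, config.master_seed, idx)
        rows = _analyse_condition(Y, config, idx, T, phi, theta)
        frame = pd.DataFrame([r.as_row() for r in rows], columns=CSV_COLUMNS)
        frames.append(frame)
        if long_path is not None:
            frame.to_csv(long_path, mode="a", header=not long_path.exists(), index=False)
        if progress:
            print(f"[{config.study}] condition {idx}: T={T} phi={phi} theta={theta} done")

    result = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        for method, sub in result.groupby("method"):
            sub.to_csv(out_dir / f"{config.study}_{method}.csv", index=False)
        sidecar = dataclasses.asdict(config)
        sidecar["methods"] = list(sidecar["methods"])
        (out_dir / "config.json").write_text(json.dumps(sidecar, indent=2))
    return result


def run_prior_sensitivity(config: StudyConfig | None = None, progress: bool = False) -> pd.DataFrame:
    """Replication-level sensitivity of the posterior to the hyperpriors.

    For each of the seven hyperprior columns, each true phi and both phi
    priors, reports the mean and SD over replications of the posterior means
    of phi, mu and sigma_e.  The same simulated series are reused across
    hyperprior columns (paired design).
    """
    if config is None:
        config = StudyConfig.prior_sensitivity()
    T = config.T_grid[0]
    records = []
    for cond_idx, phi_true in enumerate(config.phi_grid):
        params = GenParams(mu=0.0, phi=phi_true, theta=0.0, sigma_e=1.0)
        Y = simulate_batch(params, T, config.n_reps, config.master_seed, cond_idx)
        for test_no, (mm, msd, sh, rt) in enumerate(TABLE2_PRIORS, start=1):
            for offset, kind in enumerate(("flat", "symmetrized_reference")):
                prior = PriorSpec(
                    phi_prior=kind, mu_mean=mm, mu_sd=msd, sigma_shape=sh, sigma_rate=rt
                )
                post = sample_posterior_batch(
                    Y,
                    prior=prior,
                    n_chains=config.n_chains,
                    n_iter=config.n_iter,
                    seed=_bayes_seed(config.master_seed, cond_idx, 100 * test_no + offset),
                )
                for pname, key in (
                    ("phi", "phi_mean"),
                    ("mu", "mu_mean"),
                    ("sigma_e", "sigma_e_mean"),
                ):
                    vals = post[key]
                    records.append(
                        {
                            "test": test_no,
                            "prior": prior.method_name,
                            "phi_true": phi_true,
                            "parameter": pname,
                            "mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=1)),
                        }
                    )
            if progress:
                print(f"[priors] test {test_no} phi={phi_true} done")
    df = pd.DataFrame.from_records(records)
    if config.output_dir:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "prior_sensitivity.csv", index=False)
    return df


def compare_methods(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Per-condition differences (a minus b) of bias, sd_emp and epr.

    Both inputs must cover the same (T, phi, theta) conditions; a final
    ``max_abs`` row holds the maximum absolute difference of each metric.
    """
    keys = ["T", "phi", "theta"]
    a = summary_a.set_index(keys)
    b = summary_b.set_index(keys)
    unmatched = a.index.symmetric_difference(b.index)
    if len(unmatched):
        raise ValueError(f"condition keys do not match: {list(unmatched)}")
    diff = pd.DataFrame(
        {
            "d_bias": a["bias"] - b["bias"],
            "d_sd_emp": a["sd_emp"] - b["sd_emp"],
            "d_epr": a["epr"] - b["epr"],
        }
    ).reset_index()
    max_row = {k: np.nan for k in keys}
    max_row.update(
        {
            "d_bias": diff["d_bias"].abs().max(),
            "d_sd_emp": diff["d_sd_emp"].abs().max(),
            "d_epr": diff["d_epr"].abs().max(),
        }
    )
    max_df = pd.DataFrame([max_row])
    max_df.insert(0, "row", ["max_abs"])
    diff.insert(0, "row", "condition")
    return pd.concat([diff, max_df], ignore_index=True)
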