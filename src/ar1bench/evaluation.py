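"""Per-series hypothesis decisions and per-condition Monte Carlo metrics.

Three decision rules are used, matching each estimator's routing:

* r1, C-statistic, MLE and OLS-S use the t statistic for a correlation
  coefficient, t = phi_hat * sqrt(T-2) / sqrt(1 - phi_hat^2) with df = T - 3;
* OLS-A, whose estimate can exceed 1 in absolute value, uses
  t = phi_hat / SE(phi_hat) with df = T - 3;
* the Bayesian methods reject H0: phi = 0 when the central 95 % credible
  interval excludes zero.

Per condition (method, T, phi[, theta]) the Monte Carlo summary reports bias,
empirical SD of the estimates (divisor N-1), mean estimated SE, SE bias
(mean SE minus empirical SD), the empirical rejection probability EPr, the
mean estimate and its 2.5/97.5 percentiles (linear interpolation between order
statistics).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .base import EstimateResult

__all__ = [
    "ALPHA",
    "Decision",
    "ConditionSummary",
    "t_test_correlation",
    "t_test_se",
    "correlation_test_reject",
    "se_test_reject",
    "summarize_condition",
    "summarize_condition_arrays",
]

ALPHA = 0.05

#: C-statistic estimates at or beyond |1| are clipped to this for the t statistic.
PHI_CLIP = 0.9999


@dataclasses.dataclass(frozen=True)
class Decision:
    """One hypothesis-test decision for H0: phi = 0 at alpha = 0.05.

    t-based decisions carry (statistic, df, p_value); credible-interval
    decisions carry none of these, only ``reject``.
    """

    method: str
    reject: bool
    statistic: float | None = None
    df: int | None = None
    p_value: float | None = None


def t_test_correlation(phi_hat: float, T: int, method: str = "") -> Decision:
    """Two-sided correlation t test: t = phi*sqrt(T-2)/sqrt(1-phi^2), df = T-3."""
    if not abs(phi_hat) < 1.0:
        raise ValueError(f"correlation t test requires |phi_hat| < 1, got {phi_hat}")
    if T < 4:
        raise ValueError("T must be >= 4 for df = T - 3 >= 1")
    t = phi_hat * np.sqrt(T - 2) / np.sqrt(1.0 - phi_hat**2)
    df = T - 3
    p = float(2.0 * sps.t.sf(abs(t), df))
    return Decision(method=method, reject=p < ALPHA, statistic=float(t), df=df, p_value=p)


def t_test_se(phi_hat: float, se_hat: float, T: int, method: str = "ols") -> Decision:
    """Two-sided t test on phi_hat / SE with df = T - 3 (OLS-A rule).

    An undefined SE (NaN or non-positive) yields a recorded non-rejection so
    the replication can be counted as dropped rather than crash a study.
    """
    if T < 4:
        raise ValueError("T must be >= 4 for df = T - 3 >= 1")
    if not np.isfinite(se_hat) or se_hat <= 0.0:
        return Decision(method=method, reject=False, statistic=None, df=None, p_value=None)
    t = phi_hat / se_hat
    df = T - 3
    p = float(2.0 * sps.t.sf(abs(t), df))
    return Decision(method=method, reject=p < ALPHA, statistic=float(t), df=df, p_value=p)


def correlation_test_reject(phi: np.ndarray, T: int, clip: bool = False) -> np.ndarray:
    """Vectorised correlation-t rejection indicator; optionally clip |phi| >= 1.

    ``clip=True`` (used for the C-statistic, whose additive correction can
    push the estimate past 1 on pathological series) clips to +/-0.9999 so the
    statistic stays defined.
    """
    phi = np.asarray(phi, dtype=float)
    if clip:
        phi = np.clip(phi, -PHI_CLIP, PHI_CLIP)
    elif np.any(np.abs(phi) >= 1.0):
        raise ValueError("correlation t test requires |phi_hat| < 1 for all estimates")
    t = phi * np.sqrt(T - 2) / np.sqrt(1.0 - phi**2)
    p = 2.0 * sps.t.sf(np.abs(t), T - 3)
    return p < ALPHA


def se_test_reject(phi: np.ndarray, se: np.ndarray, T: int) -> np.ndarray:
    """Vectorised SE-based t rejection indicator; undefined SE -> non-reject."""
    phi = np.asarray(phi, dtype=float)
    se = np.asarray(se, dtype=float)
    defined = np.isfinite(se) & (se > 0.0)
    t = np.where(defined, phi / np.where(defined, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), T - 3)
    return defined & (p < ALPHA)


@dataclasses.dataclass
class ConditionSummary:
    """Monte Carlo metrics for one (method, T, phi[, theta]) condition."""

    method: str
    T: int
    phi_true: float
    theta_true: float
    n_reps: int
    bias: float
    sd_emp: float
    mean_se: float
    se_bias: float
    epr: float
    mean_phi_hat: float
    pctl_2_5: float
    pctl_97_5: float
    n_dropped: int

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "T": self.T,
            "phi": self.phi_true,
            "theta": self.theta_true,
            "n_reps": self.n_reps,
            "bias": self.bias,
            "sd_emp": self.sd_emp,
            "mean_se": self.mean_se,
            "se_bias": self.se_bias,
            "epr": self.epr,
            "mean_phi_hat": self.mean_phi_hat,
            "p2_5": self.pctl_2_5,
            "p97_5": self.pctl_97_5,
            "n_dropped": self.n_dropped,
        }


def summarize_condition_arrays(
    method: str,
    phi_hat: np.ndarray,
    se_hat: np.ndarray,
    reject: np.ndarray,
    phi_true: float,
    T: int,
    theta_true: float = 0.0,
    stationary_only: bool = False,
    n_extra_dropped: int = 0,
) -> ConditionSummary:
    """Build a :class:`ConditionSummary` from per-replication arrays.

    With ``stationary_only`` the replications with |phi_hat| > 1 are excluded
    (the OLS-S convention) and counted in ``n_dropped``; undefined SEs are
    skipped in the mean-SE average and also counted.
    """
    phi_hat = np.asarray(phi_hat, dtype=float)
    se_hat = np.asarray(se_hat, dtype=float)
    reject = np.asarray(reject, dtype=bool)
    keep = np.ones(phi_hat.size, dtype=bool)
    if stationary_only:
        keep = np.abs(phi_hat) <= 1.0
    n_filtered = int((~keep).sum())
    phi_hat, se_hat, reject = phi_hat[keep], se_hat[keep], reject[keep]
    N = phi_hat.size
    if N < 2:
        raise ValueError(f"condition empty after filtering (N={N})")
    se_defined = np.isfinite(se_hat)
    mean_se = float(se_hat[se_defined].mean()) if se_defined.any() else float("nan")
    sd_emp = float(phi_hat.std(ddof=1))
    mean_phi = float(phi_hat.mean())
    lo, hi = np.percentile(phi_hat, [2.5, 97.5])
    return ConditionSummary(
        method=method,
        T=int(T),
        phi_true=float(phi_true),
        theta_true=float(theta_true),
        n_reps=N,
        bias=mean_phi - phi_true,
        sd_emp=sd_emp,
        mean_se=mean_se,
        se_bias=mean_se - sd_emp,
        epr=float(reject.mean()),
        mean_phi_hat=mean_phi,
        pctl_2_5=float(lo),
        pctl_97_5=float(hi),
        n_dropped=n_filtered + int((~se_defined).sum()) + n_extra_dropped,
    )


def summarize_condition(
    estimates: Sequence[EstimateResult],
    decisions: Iterable[Decision | bool],
    phi_true: float,
    T: int | None = None,
    theta_true: float = 0.0,
    filter: str = "all",
) -> ConditionSummary:
    """Summarise a list of per-series results and decisions for one condition.

    ``filter`` is ``"all"`` or ``"stationary_only"`` (the OLS-S rule).
    ``decisions`` may be :class:`Decision` objects or plain booleans.
    """
    if filter not in ("all", "stationary_only"):
        raise ValueError("filter must be 'all' or 'stationary_only'")
    if not estimates:
        raise ValueError("no estimates supplied")
    if T is None:
        raise ValueError("T must be supplied")
    phi_hat = np.array([e.phi_hat for e in estimates])
    se_hat = np.array([e.se_hat for e in estimates])
    reject = np.array(
        [d.reject if isinstance(d, Decision) else bool(d) for d in decisions], dtype=bool
    )
    if reject.size != phi_hat.size:
        raise ValueError("estimates and decisions must have equal length")
    method = estimates[0].method
    if filter == "stationary_only" and method == "ols":
        method = "ols_s"
    return summarize_condition_arrays(
        method=method,
        phi_hat=phi_hat,
        se_hat=se_hat,
        reject=reject,
        phi_true=phi_true,
        T=T,
        theta_true=theta_true,
        stationary_only=(filter == "stationary_only"),
    )
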