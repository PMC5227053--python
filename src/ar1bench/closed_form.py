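"""Closed-form lag-1 autocorrelation estimators: r1 (Yule-Walker), C-statistic, OLS.

All three share the lag-1 cross-product numerator sum_{t<T} (y_t - ybar)(y_{t+1} - ybar)
and differ in the denominator and in their estimated standard errors:

* r1 divides by the full sum of squares, so |phi_hat| < 1 by Cauchy-Schwarz;
  SE = sqrt(sigma_e^2_hat / ((T-1) sigma_y^2_hat)) with the Yule-Walker
  innovation-variance identity sigma_e^2_hat = sigma_y^2_hat (1 - phi_hat^2).
* The C-statistic adds Young's end-point correction
  [(y_1-ybar)^2 + (y_T-ybar)^2] / (2 sum (y_t-ybar)^2) to r1, reducing the
  small-sample bias; its SE sqrt((T-2)/((T-1)(T+1))) depends on T only.
* OLS divides by the sum of squares of the first T-1 terms, so |phi_hat| > 1
  (a non-stationary estimate) is possible; its asymptotic SE
  sqrt((T - (T-1) phi_hat^2 - 1) / (T^2 - T - T y_T^2)) involves the last raw
  observation, can have a non-positive radicand, and is then reported as NaN.

Vectorised ``*_batch`` helpers operate on (n_series, T) arrays for Monte Carlo
work; the estimator classes and ``estimate_*`` functions handle single series.
"""

from __future__ import annotations

import numpy as np

from .base import BaseAR1Estimator, EstimateResult
from .model import validate_series

__all__ = [
    "YuleWalkerAR1",
    "CStatisticAR1",
    "OLSAR1",
    "estimate_r1",
    "estimate_c",
    "estimate_ols",
    "r1_batch",
    "c_stat_batch",
    "ols_batch",
]


def _centered(Y: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return Y - Y.mean(axis=1, keepdims=True)


def r1_batch(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised r1 estimate and SE for each row of ``Y`` ((n, T) array)."""
    d = _centered(Y)
    T = d.shape[1]
    num = np.einsum("ij,ij->i", d[:, :-1], d[:, 1:])
    den = np.einsum("ij,ij->i", d, d)
    phi = num / den
    # SE_r1 = sqrt(sigma_e^2 / ((T-1) sigma_y^2)) with sigma_e^2 = sigma_y^2 (1-phi^2)
    se = np.sqrt(np.maximum(1.0 - phi**2, 0.0) / (T - 1))
    return phi, se


def c_stat_batch(Y: np.ndarray, correction: str = "sum") -> tuple[np.ndarray, np.ndarray]:
    """Vectorised C-statistic estimate and SE for each row of ``Y``.

    ``correction="sum"`` uses Young's end-point correction
    (y_1-ybar)^2 + (y_T-ybar)^2 over twice the sum of squares;
    ``correction="product"`` is a compatibility switch multiplying the two
    end-point squares instead (dimensionally inconsistent, kept for comparison
    with sources that print the product form).
    """
    d = _centered(Y)
    T = d.shape[1]
    phi_r1, _ = r1_batch(Y)
    den = np.einsum("ij,ij->i", d, d)
    if correction == "sum":
        corr = (d[:, 0] ** 2 + d[:, -1] ** 2) / (2.0 * den)
    elif correction == "product":
        corr = (d[:, 0] ** 2 * d[:, -1] ** 2) / (2.0 * den)
    else:
        raise ValueError(f"correction must be 'sum' or 'product', got {correction!r}")
    phi = phi_r1 + corr
    se = np.full_like(phi, np.sqrt((T - 2) / ((T - 1) * (T + 1))))
    return phi, se


def ols_batch(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS estimate, SE (NaN when undefined) and stationarity flag.

    The SE formula is applied literally; rows where the radicand or its
    denominator is non-positive get ``se = NaN``.  ``stationary`` is
    ``|phi_hat| <= 1`` (the boundary counts as stationary).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d = _centered(Y)
    T = d.shape[1]
    num = np.einsum("ij,ij->i", d[:, :-1], d[:, 1:])
    den = np.einsum("ij,ij->i", d[:, :-1], d[:, :-1])
    if np.any(den == 0.0):
        raise ZeroDivisionError("OLS denominator sum_{t<T} (y_t - ybar)^2 is zero")
    phi = num / den
    radicand = T - (T - 1) * phi**2 - 1.0
    se_den = T**2 - T - T * Y[:, -1] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where((radicand > 0) & (se_den > 0), np.sqrt(radicand / se_den), np.nan)
    stationary = np.abs(phi) <= 1.0
    return phi, se, stationary


class YuleWalkerAR1(BaseAR1Estimator):
    """Yule-Walker (r1) estimator of the lag-1 autocorrelation."""

    method = "r1"

    def _fit(self, y: np.ndarray) -> None:
        phi, se = r1_batch(y[None, :])
        self.phi_ = float(phi[0])
        self.se_ = float(se[0])
        self.stationary_ = True
        self.diagnostics_ = {
            "residual_variance": float(np.var(y, ddof=1) * (1.0 - self.phi_**2))
        }


class CStatisticAR1(BaseAR1Estimator):
    """Young's C-statistic: r1 plus an end-point bias correction.

    Parameters
    ----------
    correction : "sum" (default) or "product"; see :func:`c_stat_batch`.
    """

    method = "c_stat"

    def __init__(self, correction: str = "sum"):
        self.correction = correction

    def _fit(self, y: np.ndarray) -> None:
        phi, se = c_stat_batch(y[None, :], correction=self.correction)
        phi_r1, _ = r1_batch(y[None, :])
        self.phi_ = float(phi[0])
        self.se_ = float(se[0])
        self.stationary_ = bool(abs(self.phi_) <= 1.0)
        self.diagnostics_ = {"correction_term": float(phi[0] - phi_r1[0])}


class OLSAR1(BaseAR1Estimator):
    """Ordinary least squares estimator; may return |phi_hat| > 1."""

    method = "ols"

    def _fit(self, y: np.ndarray) -> None:
        phi, se, stationary = ols_batch(y[None, :])
        self.phi_ = float(phi[0])
        self.se_ = float(se[0])
        self.stationary_ = bool(stationary[0])
        T = y.size
        self.diagnostics_ = {
            "se_defined": bool(np.isfinite(se[0])),
            "se_radicand": float(T - (T - 1) * phi[0] ** 2 - 1.0),
            "se_denominator": float(T**2 - T - T * y[-1] ** 2),
        }


def estimate_r1(series) -> EstimateResult:
    """r1 (Yule-Walker) estimate with its standard error."""
    return YuleWalkerAR1().fit(validate_series(series)).to_result()


def estimate_c(series, correction: str = "sum") -> EstimateResult:
    """C-statistic estimate with its (data-free) standard error."""
    return CStatisticAR1(correction=correction).fit(validate_series(series)).to_result()


def estimate_ols(series) -> EstimateResult:
    """OLS estimate, SE (NaN if undefined) and stationarity flag."""
    return OLSAR1().fit(validate_series(series)).to_result()
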