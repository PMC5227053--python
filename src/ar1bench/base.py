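"""Shared result container and the estimator base class."""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator

from .model import validate_series

#: Canonical method names used throughout result tables.
METHOD_NAMES = ("r1", "c_stat", "ols", "mle", "bayes_flat", "bayes_sr")


@dataclasses.dataclass
class EstimateResult:
    """One estimator's output on one series.

    ``se_hat`` is NaN when the estimated standard error is undefined (the OLS
    formula can have a non-positive radicand); ``diagnostics`` records why.
    ``stationary_flag`` is True iff |phi_hat| <= 1 (only OLS can violate it).
    """

    method: str
    phi_hat: float
    se_hat: float
    stationary_flag: bool
    diagnostics: dict[str, Any] = dataclasses.field(default_factory=dict)

    @property
    def se_defined(self) -> bool:
        return math.isfinite(self.se_hat)


class BaseAR1Estimator(BaseEstimator):
    """Base class for lag-1 autocorrelation estimators.

    Subclasses implement ``_fit(y)`` on a validated 1-D array and set the
    fitted attributes ``phi_``, ``se_``, ``stationary_`` and ``diagnostics_``.
    """

    method: str = ""

    def fit(self, X, y=None):
        series = validate_series(X)
        self._fit(series)
        return self

    def _fit(self, y: np.ndarray) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def to_result(self) -> EstimateResult:
        """Package the fitted attributes as an :class:`EstimateResult`."""
        if not hasattr(self, "phi_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return EstimateResult(
            method=self.method,
            phi_hat=float(self.phi_),
            se_hat=float(self.se_),
            stationary_flag=bool(self.stationary_),
            diagnostics=dict(self.diagnostics_),
        )
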