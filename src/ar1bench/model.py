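"""Stationary AR(1)/ARMA(1,1) simulation, closed-form oracles and series I/O.

The generating model is the Gaussian ARMA(1,1) in mean-centred form,

    y_t - mu = phi * (y_{t-1} - mu) + theta * e_{t-1} + e_t,
    e_t ~ N(0, sigma_e^2),

with theta = 0 giving the AR(1) special case.  Simulated series start at the
process mean (e_0 = 0) and a 100-step burn-in is discarded, so the returned
values are stationary to machine precision for the |phi| <= 0.9 grids used in
the studies.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import DegenerateSeriesError, StationarityError

#: Number of leading observations discarded so the process forgets its start.
BURNIN = 100

MIN_LENGTH = 3


@dataclasses.dataclass(frozen=True)
class GenParams:
    """Generating-model parameters (mu, phi, theta, sigma_e).

    Parameters
    ----------
    mu : process mean.
    phi : lag-1 autoregressive parameter, |phi| < 1 (stationarity).
    theta : moving-average parameter, |theta| < 1 (invertibility); 0 for AR(1).
    sigma_e : innovation standard deviation, > 0.
    """

    mu: float = 0.0
    phi: float = 0.0
    theta: float = 0.0
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu, self.phi, self.theta, self.sigma_e]).all():
            raise ValueError("GenParams fields must be finite")
        if abs(self.phi) >= 1.0:
            raise StationarityError(f"|phi| must be < 1, got phi={self.phi}")
        if abs(self.theta) >= 1.0:
            raise StationarityError(f"|theta| must be < 1, got theta={self.theta}")
        if self.sigma_e <= 0.0:
            raise ValueError(f"sigma_e must be > 0, got {self.sigma_e}")


@dataclasses.dataclass(frozen=True)
class RngSpec:
    """Deterministic identifier of a single simulated series.

    The triple (master_seed, condition_index, replication_index) seeds an
    independent PCG64 stream, so any series in any study can be regenerated in
    isolation and conditions can be processed in any order.
    """

    master_seed: int
    condition_index: int = 0
    replication_index: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")

    def generator(self) -> np.random.Generator:
        seq = np.random.SeedSequence(
            (self.master_seed, self.condition_index, self.replication_index)
        )
        return np.random.Generator(np.random.PCG64(seq))


def _as_generator(rng: RngSpec | np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng, RngSpec):
        return rng.generator()
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _check_length(T: int) -> None:
    if not isinstance(T, (int, np.integer)) or T < MIN_LENGTH:
        raise ValueError(f"T must be an integer >= {MIN_LENGTH}, got {T!r}")


def simulate_arma11(
    params: GenParams, T: int, rng: RngSpec | np.random.Generator | int
) -> np.ndarray:
    """Simulate one stationary Gaussian ARMA(1,1) series of length ``T``.

    The recursion is applied to T + BURNIN innovations with zero initial
    conditions (y_0 = mu, e_0 = 0) via a linear filter; the burn-in is dropped.
    """
    _check_length(T)
    g = _as_generator(rng)
    e = g.standard_normal(T + BURNIN) * params.sigma_e
    x = lfilter([1.0, params.theta], [1.0, -params.phi], e)
    return params.mu + x[BURNIN:]


def simulate_ar1(
    params: GenParams, T: int, rng: RngSpec | np.random.Generator | int
) -> np.ndarray:
    """Simulate one stationary Gaussian AR(1) series (requires theta = 0)."""
    if params.theta != 0.0:
        raise ValueError("simulate_ar1 requires theta = 0; use simulate_arma11")
    return simulate_arma11(params, T, rng)


def simulate_batch(
    params: GenParams,
    T: int,
    n_reps: int,
    master_seed: int,
    condition_index: int = 0,
) -> np.ndarray:
    """Simulate ``n_reps`` series as an (n_reps, T) array.

    Row ``r`` is bit-identical to
    ``simulate_arma11(params, T, RngSpec(master_seed, condition_index, r))``:
    each replication has its own counter-derived stream, so the batch is just a
    vectorised convenience, not a different random law.
    """
    _check_length(T)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    e = np.empty((n_reps, T + BURNIN))
    for r in range(n_reps):
        g = RngSpec(master_seed, condition_index, r).generator()
        e[r] = g.standard_normal(T + BURNIN)
    e *= params.sigma_e
    x = lfilter([1.0, params.theta], [1.0, -params.phi], e, axis=1)
    return params.mu + x[:, BURNIN:]


def arma11_lag1_autocorrelation(phi: float, theta: float) -> float:
    """Population lag-1 autocorrelation of a stationary ARMA(1,1)."""
    return (1.0 + phi * theta) * (phi + theta) / (1.0 + 2.0 * phi * theta + theta**2)


_BIAS_FORMULAS = {
    "r1": lambda phi, T: -(1.0 + 4.0 * phi) / T,
    "mle_mu_known": lambda phi, T: -2.0 * phi / T,
    "mle_mu_estimated": lambda phi, T: (-3.0 * phi + 1.0) / T,
}


def asymptotic_bias(method: str, phi: float, T: int) -> float:
    """Closed-form asymptotic (order 1/T) bias of an AR(1) estimator.

    ``r1``: -(1+4*phi)/T.  ``mle_mu_known``: -2*phi/T.  ``mle_mu_estimated``
    (mean estimated alongside phi): (-3*phi+1)/T.
    """
    if method not in _BIAS_FORMULAS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_BIAS_FORMULAS)}")
    if abs(phi) >= 1.0:
        raise StationarityError(f"|phi| must be < 1, got {phi}")
    if T < 1:
        raise ValueError("T must be >= 1")
    return _BIAS_FORMULAS[method](phi, T)


def validate_series(y) -> np.ndarray:
    """Validate and coerce a series to a 1-D float array.

    Requires length >= 3, all values finite, and positive sample variance.
    """
    arr = np.asarray(y, dtype=float).squeeze()
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {np.shape(y)}")
    if arr.size < MIN_LENGTH:
        raise DegenerateSeriesError(f"series must have T >= {MIN_LENGTH}, got T={arr.size}")
    if not np.isfinite(arr).all():
        raise DegenerateSeriesError("series contains non-finite values")
    if np.var(arr) == 0.0:
        raise DegenerateSeriesError("series is constant (zero sample variance)")
    return arr


def read_series(path: str | Path) -> np.ndarray:
    """Read a series from plain text (one float per line) or CSV with a ``y`` column."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    try:
        float(first.split(",")[0])
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, header=header)
    if header == 0:
        if "y" not in df.columns:
            raise ValueError(f"CSV {path} has a header but no 'y' column")
        values = df["y"].to_numpy(dtype=float)
    else:
        values = df.iloc[:, 0].to_numpy(dtype=float)
    return values


def write_series(y, path: str | Path) -> None:
    """Write a series as single-column CSV with header ``y``."""
    arr = np.asarray(y, dtype=float)
    pd.DataFrame({"y": arr}).to_csv(path, index=False)
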