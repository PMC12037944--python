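"""Forecasting models: the random walk in closed form, and ARIMA(p,d,q).

The random walk with drift — ARIMA(0,1,0) with a constant — forecasts the
next value as the last observation plus the mean first difference of the
training window; its only parameters are that intercept and the innovation
variance sigma².  It is the benchmark against which every other
specification is judged.

General ARIMA fitting differences the window ``d`` times and estimates an
ARMA(p,q) with a constant on the differenced scale (mean form): the
``intercept`` field of :class:`ArimaFit` is the process mean of the
d-times-differenced series.  Numerical estimation is delegated to
:mod:`statsmodels`; the one-step conditional-mean forecast is computed here
directly from the fitted coefficients via the conditional-sum-of-squares
innovation recursion, so it is a pure function of (fit, window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArimaSpec",
    "ArimaFit",
    "RandomWalkFit",
    "InsufficientDataError",
    "FitFailedError",
    "fit_random_walk",
    "forecast_random_walk",
    "fit_arima",
    "forecast_one_step",
]


class InsufficientDataError(ValueError):
    """The training window is too short for the requested model."""


class FitFailedError(RuntimeError):
    """Parameter estimation failed outright (numerical error)."""


@dataclass(frozen=True, order=True)
class ArimaSpec:
    """ARIMA order (p, d, q): AR terms, differencing, MA terms."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.d < 0 or self.q < 0:
            raise ValueError("p, d, q must be non-negative integers")

    @property
    def is_random_walk(self) -> bool:
        return (self.p, self.d, self.q) == (0, 1, 0)

    @property
    def n_params(self) -> int:
        return self.p + self.d + self.q

    @classmethod
    def from_string(cls, text: str) -> "ArimaSpec":
        """Parse the "p,d,q" CLI/config format, e.g. "0,1,0"."""
        parts = text.split(",")
        if len(parts) != 3:
            raise ValueError(f"spec must be 'p,d,q', got {text!r}")
        return cls(*(int(s.strip()) for s in parts))

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})"


@dataclass(frozen=True)
class RandomWalkFit:
    """Random-walk-with-drift parameters over one training window.

    ``intercept`` is the mean first difference (BPM/min); ``sigma2`` the
    sample variance of the first differences (BPM²), carried for
    diagnostics — the point forecast is the conditional mean and adds no
    noise.
    """

    intercept: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


@dataclass(frozen=True)
class ArimaFit:
    """Fitted ARIMA(p,d,q): coefficients on the d-times-differenced scale."""

    spec: ArimaSpec
    phi: np.ndarray
    theta: np.ndarray
    intercept: float
    sigma2: float
    train_len: int
    converged: bool = True
    diagnostic: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if len(self.phi) != self.spec.p or len(self.theta) != self.spec.q:
            raise ValueError("coefficient vectors must match the spec orders")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


def fit_random_walk(window: np.ndarray) -> RandomWalkFit:
    """Closed-form random-walk-with-drift fit: moments of the differences."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise InsufficientDataError("random walk needs a window of >= 2 values")
    diffs = np.diff(w)
    intercept = float(diffs.mean())
    sigma2 = float(diffs.var(ddof=1)) if len(diffs) > 1 else 0.0
    return RandomWalkFit(intercept=intercept, sigma2=sigma2)


def forecast_random_walk(fit: RandomWalkFit, last_value: float) -> float:
    """Point forecast: last observation plus the drift intercept."""
    return float(last_value) + fit.intercept


def _difference(window: np.ndarray, d: int) -> np.ndarray:
    z = np.asarray(window, dtype=float)
    for _ in range(d):
        z = np.diff(z)
    return z


def fit_arima(
    window: np.ndarray, spec: ArimaSpec, include_constant: bool = True
) -> ArimaFit:
    """Estimate ARIMA(p,d,q) on a training window.

    Pure-difference specs (p = q = 0) have a closed form: after differencing
    ``d`` times the series is white noise around a mean, so the intercept is
    the sample mean and sigma² the sample variance of the differenced window
    — for (0,1,0) this is exactly :func:`fit_random_walk`.  Specs with AR or
    MA terms are estimated by Gaussian maximum likelihood (statsmodels
    state-space ARIMA) on the differenced scale.

    A non-convergent optimisation returns a fit flagged ``converged=False``
    with a diagnostic message rather than raising, so a rolling engine can
    record the step as failed and continue.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise ValueError("window must be a 1-D vector")
    if len(w) < spec.n_params + 2:
        raise InsufficientDataError(
            f"spec {spec} needs a window of >= {spec.n_params + 2} values, "
            f"got {len(w)}"
        )
    z = _difference(w, spec.d)
    if len(z) < 2:
        raise InsufficientDataError("differenced window too short")

    if spec.p == 0 and spec.q == 0:
        mu = float(z.mean()) if include_constant else 0.0
        sigma2 = float(z.var(ddof=1)) if len(z) > 1 else 0.0
        return ArimaFit(
            spec=spec,
            phi=np.empty(0),
            theta=np.empty(0),
            intercept=mu,
            sigma2=sigma2,
            train_len=len(w),
        )

    from statsmodels.tsa.arima.model import ARIMA as _SmARIMA

    trend = "c" if include_constant else "n"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _SmARIMA(z, order=(spec.p, 0, spec.q), trend=trend)
            res = model.fit()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FitFailedError(f"ARIMA{spec} estimation failed: {exc}") from exc

    params = dict(zip(res.model.param_names, res.params))
    phi = np.array([params.get(f"ar.L{i}", 0.0) for i in range(1, spec.p + 1)])
    theta = np.array([params.get(f"ma.L{j}", 0.0) for j in range(1, spec.q + 1)])
    mu = float(params.get("const", 0.0))
    sigma2 = float(max(params.get("sigma2", 0.0), 0.0))
    retvals = getattr(res, "mle_retvals", None) or {}
    converged = bool(retvals.get("converged", True))
    return ArimaFit(
        spec=spec,
        phi=phi,
        theta=theta,
        intercept=mu,
        sigma2=sigma2,
        train_len=len(w),
        converged=converged,
        diagnostic="" if converged else "optimizer did not converge",
    )


def forecast_one_step(fit: ArimaFit, window: np.ndarray) -> float:
    """Conditional-mean one-step-ahead forecast from a fitted ARIMA.

    Works on the d-times-differenced, mean-centred scale: innovations are
    reconstructed by the conditional-sum-of-squares recursion with zero
    pre-sample errors, the next differenced value is the AR + MA conditional
    mean, and the result is integrated back to levels.  For (0,1,0) this
    reduces exactly to last value + intercept (the random-walk path).
    """
    w = np.asarray(window, dtype=float)
    if len(w) != fit.train_len:
        raise ValueError(
            f"window length {len(w)} does not match fit.train_len {fit.train_len}"
        )
    spec = fit.spec
    z = _difference(w, spec.d)
    zc = z - fit.intercept
    n = len(zc)
    p, q = spec.p, spec.q

    eps = np.zeros(n)
    if q > 0:
        for t in range(n):
            ar = sum(fit.phi[i] * zc[t - 1 - i] for i in range(p) if t - 1 - i >= 0)
            ma = sum(fit.theta[j] * eps[t - 1 - j] for j in range(q) if t - 1 - j >= 0)
            eps[t] = zc[t] - ar - ma

    ar_next = sum(fit.phi[i] * zc[n - 1 - i] for i in range(p) if n - 1 - i >= 0)
    ma_next = sum(fit.theta[j] * eps[n - 1 - j] for j in range(q) if n - 1 - j >= 0)
    z_hat = fit.intercept + ar_next + ma_next

    # integrate the d-fold-differenced forecast back to the level scale
    forecast = z_hat
    x = w
    for _ in range(spec.d):
        forecast += x[-1]
        x = np.diff(x)
    return float(forecast)
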