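"""Adaptive rolling-window one-step-ahead forecasting engine.

The evaluation protocol holds out the final N minutes of a series in
chronological order.  At each of the N steps the model is refitted from
scratch on exactly the ``w`` observations immediately preceding the held-out
minute — the window slides forward, discarding the oldest minute as the new
actual is ingested — and emits a single one-step-ahead forecast (horizon
fixed at 1).  Retraining at every step keeps the model current under
concept drift (activity changes, stress, sleep); with horizon 1 the number
of steps equals N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .forecasters import (
    ArimaSpec,
    FitFailedError,
    fit_arima,
    forecast_one_step,
)
from .series import MinuteSeries

__all__ = ["EngineConfig", "ForecastResult", "run_rolling_forecast"]

#: Window sizes evaluated in the study, in minutes.
DEFAULT_WINDOW_SIZES = (15, 30, 45, 90, 150)

#: Out-of-sample evaluation length, in minutes (>= 200 recommended for
#: reliable out-of-sample scores; the study uses 220).
DEFAULT_OOS_N = 220


@dataclass(frozen=True)
class EngineConfig:
    """Rolling-forecast settings: window size w, OOS length N, horizon H=1."""

    window_size: int
    oos_n: int = DEFAULT_OOS_N
    horizon: int = 1
    retrain: bool = True
    max_window: int = max(DEFAULT_WINDOW_SIZES)

    def __post_init__(self) -> None:
        if not (2 <= self.window_size <= self.max_window):
            raise ValueError(
                f"window_size must lie in [2, max_window={self.max_window}]"
            )
        if self.oos_n < 1:
            raise ValueError("oos_n must be >= 1")
        if self.horizon != 1:
            raise ValueError("horizon is fixed at 1 (one-step-ahead only)")
        if not self.retrain:
            raise ValueError("retrain is fixed True: a fresh fit at every step")


@dataclass
class ForecastResult:
    """Aligned actual/forecast/residual vectors for the N out-of-sample steps.

    ``forecast`` is NaN at failed steps (non-convergent fits); those indices
    are listed in ``failed_steps`` and excluded from :meth:`mae`.
    """

    minute_index: np.ndarray
    actual: np.ndarray
    forecast: np.ndarray
    residual: np.ndarray
    spec: ArimaSpec
    config: EngineConfig
    failed_steps: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        n = self.config.oos_n
        for name in ("minute_index", "actual", "forecast", "residual"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length oos_n={n}")

    @property
    def n_failed(self) -> int:
        return int(len(self.failed_steps))

    @property
    def ok(self) -> np.ndarray:
        """Boolean mask of successful steps."""
        mask = np.ones(len(self.forecast), dtype=bool)
        mask[self.failed_steps] = False
        return mask

    def mae(self) -> float:
        """Mean absolute error over successful steps."""
        ok = self.ok
        if not ok.any():
            raise ValueError("no successful forecasting steps")
        return float(np.abs(self.residual[ok]).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute_index": self.minute_index,
                "actual": self.actual,
                "forecast": self.forecast,
                "residual": self.residual,
            }
        )

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Serialize to CSV (per-step vectors) plus JSON run metadata."""
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {
                "spec": str(self.spec),
                "window_size": self.config.window_size,
                "oos_n": self.config.oos_n,
                "horizon": self.config.horizon,
                "failed_steps": [int(i) for i in self.failed_steps],
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)
                fh.write("\n")


def run_rolling_forecast(
    series: MinuteSeries,
    spec: ArimaSpec,
    config: EngineConfig,
    include_constant: bool = True,
    forecaster: Callable[[np.ndarray], float] | None = None,
) -> ForecastResult:
    """Run the retrain-per-step rolling forecast over the final N minutes.

    The series must be gap-free (interpolated).  With ``t = len(series) - N``,
    the held-out observation of step k (k = 1..N) sits at position
    ``t + k - 1`` and the model trains on the w values at
    ``[t + k - 1 - w, t + k - 1)`` — only data strictly before the target.

    ``forecaster`` optionally replaces the fit+forecast pair with any
    callable mapping a training window to a point forecast (used for
    instrumentation and custom baselines); by default each step fits
    ``spec`` afresh and takes its conditional-mean one-step forecast.
    """
    if series.missing.any():
        raise ValueError("series contains missing minutes; interpolate first")
    values = series.values
    w, n = config.window_size, config.oos_n
    if len(values) < w + n:
        raise ValueError(
            f"series of length {len(values)} too short: rolling forecast needs "
            f"window + OOS = {w} + {n} = {w + n} minutes"
        )
    t = len(values) - n

    forecasts = np.empty(n)
    failed: list[int] = []
    for k in range(n):
        window = values[t + k - w : t + k]
        if forecaster is not None:
            forecasts[k] = forecaster(window)
            continue
        try:
            fit = fit_arima(window, spec, include_constant=include_constant)
        except FitFailedError:
            forecasts[k] = np.nan
            failed.append(k)
            continue
        if not fit.converged:
            forecasts[k] = np.nan
            failed.append(k)
            continue
        forecasts[k] = forecast_one_step(fit, window)

    if len(failed) == n:
        raise RuntimeError(f"every forecasting step failed for spec {spec}")

    actual = values[t:].copy()
    return ForecastResult(
        minute_index=series.index[t:].copy(),
        actual=actual,
        forecast=forecasts,
        residual=actual - forecasts,
        spec=spec,
        config=config,
        failed_steps=np.array(failed, dtype=int),
    )
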