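"""Metrics, the experiment grid, and top-k specification ranking.

Scores are mean absolute error (MAE), which stays on the BPM scale of the
data.  MAPE is provided but guarded: with actual values inside (−1, 1) the
denominator inflates percentage errors arbitrarily, so such inputs are
refused — relevant in this domain because differenced HR series routinely
cross zero.

The experiment grid crosses users × window sizes × ARIMA specifications
(× time-of-day period, when the data carries a clock).  Rankings follow
the study protocol: within each (dataset, period, window size) group,
specifications are ordered by their median per-user MAE and the per-group
top-k are reported; the union over groups may exceed k when groups
disagree.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import DEFAULT_OOS_N, DEFAULT_WINDOW_SIZES, EngineConfig, run_rolling_forecast
from .forecasters import ArimaSpec
from .series import MinuteSeries

__all__ = [
    "ScoreRecord",
    "GridConfig",
    "mae",
    "mape",
    "run_grid",
    "rank_top_specifications",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


def default_spec_set() -> tuple[ArimaSpec, ...]:
    """The study grid: p < 5, d < 2, q < 5 (strict bounds), 50 specs."""
    return tuple(
        ArimaSpec(p, d, q)
        for p, d, q in itertools.product(range(5), range(2), range(5))
    )


def mae(actual: Sequence[float], forecast: Sequence[float]) -> float:
    """Mean absolute error, in the units of the data (BPM here)."""
    a = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if a.size == 0:
        raise ValueError("mae of empty vectors is undefined")
    if a.shape != f.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {f.shape}")
    return float(np.abs(a - f).mean())


def mape(actual: Sequence[float], forecast: Sequence[float]) -> float:
    """Mean absolute percentage error, with a denominator guard.

    Raises if any actual value lies in the open interval (−1, 1): such
    denominators inflate the percentage arbitrarily and make the metric
    misleading, which is why MAE is preferred on this data.
    """
    a = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if a.size == 0:
        raise ValueError("mape of empty vectors is undefined")
    if a.shape != f.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {f.shape}")
    if np.any(np.abs(a) < 1):
        raise ValueError(
            "mape is unreliable when actual values lie in (-1, 1) "
            "(denominator hazard); use mae instead"
        )
    return float(np.abs((a - f) / a).mean() * 100.0)


@dataclass(frozen=True)
class ScoreRecord:
    """One grid cell: per-user MAE for a (period, window, spec) setting."""

    user_id: str
    dataset_label: str
    period: str
    window_size: int
    spec: ArimaSpec
    mae: float
    n_failed_steps: int = 0

    def __post_init__(self) -> None:
        if self.mae < 0:
            raise ValueError("mae must be >= 0")


@dataclass(frozen=True)
class GridConfig:
    """Experiment-grid settings (defaults reproduce the study protocol)."""

    spec_set: tuple[ArimaSpec, ...] = field(default_factory=default_spec_set)
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    oos_n: int = DEFAULT_OOS_N
    top_k: int = 6
    include_constant: bool = True

    def __post_init__(self) -> None:
        if not self.spec_set:
            raise ValueError("spec_set must be non-empty")
        if not self.window_sizes:
            raise ValueError("window_sizes must be non-empty")


def run_grid(
    series_by_user: Mapping[str, MinuteSeries],
    grid: GridConfig,
    dataset_label: str = "synthetic",
) -> list[ScoreRecord]:
    """One ScoreRecord per (user, window size, spec) cell.

    The period is taken from each series' ``period_label``; run a separate
    grid per period slice to cross time-of-day.  Per-cell failures are
    logged and skipped, never fatal.
    """
    max_w = max(grid.window_sizes)
    records: list[ScoreRecord] = []
    for user_id, series in series_by_user.items():
        for w in grid.window_sizes:
            config = EngineConfig(window_size=w, oos_n=grid.oos_n, max_window=max_w)
            for spec in grid.spec_set:
                try:
                    result = run_rolling_forecast(
                        series, spec, config, include_constant=grid.include_constant
                    )
                    records.append(
                        ScoreRecord(
                            user_id=str(user_id),
                            dataset_label=dataset_label,
                            period=series.period_label,
                            window_size=w,
                            spec=spec,
                            mae=result.mae(),
                            n_failed_steps=result.n_failed,
                        )
                    )
                except Exception:
                    logger.warning(
                        "grid cell failed: user=%s w=%d spec=%s",
                        user_id,
                        w,
                        spec,
                        exc_info=True,
                    )
                logger.debug("grid cell done: user=%s w=%d spec=%s", user_id, w, spec)
    return records


def records_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    """Tidy DataFrame of score records (one row per grid cell)."""
    rows = [
        {
            "user_id": r.user_id,
            "dataset_label": r.dataset_label,
            "period": r.period,
            "window_size": r.window_size,
            "p": r.spec.p,
            "d": r.spec.d,
            "q": r.spec.q,
            "spec": str(r.spec),
            "mae": r.mae,
            "n_failed_steps": r.n_failed_steps,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def rank_top_specifications(
    records: Sequence[ScoreRecord], k: int = 6
) -> pd.DataFrame:
    """Per-group top-k specifications by median per-user MAE.

    Groups are (dataset_label, period, window_size).  Within each group the
    median MAE across users is computed per spec; ties break toward
    parsimony (fewer total parameters p+d+q, then lexicographic (p, d, q)).
    The returned frame holds the union of per-group winners with their group
    membership and rank, so the union may exceed ``k`` specs overall.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("no records to rank")

    df = records_to_frame(records)
    dupes = df.duplicated(
        subset=["user_id", "dataset_label", "period", "window_size", "spec"]
    )
    if dupes.any():
        raise ValueError(
            f"{int(dupes.sum())} duplicate grid cells detected; "
            "each (user, dataset, period, window, spec) may appear once"
        )

    out_rows = []
    group_cols = ["dataset_label", "period", "window_size"]
    for keys, grp in df.groupby(group_cols, sort=True):
        med = (
            grp.groupby(["spec", "p", "d", "q"], as_index=False)["mae"]
            .median()
            .rename(columns={"mae": "median_mae"})
        )
        med["n_params"] = med["p"] + med["d"] + med["q"]
        med = med.sort_values(
            ["median_mae", "n_params", "p", "d", "q"], kind="mergesort"
        ).head(k)
        for rank, (_, row) in enumerate(med.iterrows(), start=1):
            out_rows.append(
                dict(
                    zip(group_cols, keys),
                    spec=row["spec"],
                    p=int(row["p"]),
                    d=int(row["d"]),
                    q=int(row["q"]),
                    median_mae=float(row["median_mae"]),
                    rank=rank,
                )
            )
    return pd.DataFrame(out_rows)
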