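#!/usr/bin/env python
"""Run the rolling-forecast experiment grid over the cohort.

Crosses users x time-of-day x window sizes {30, 90} x six ARIMA
specifications (the random walk (0,1,0), its near neighbours (0,1,1) and
(1,1,1), plus (0,0,0), (1,0,0) and (2,0,0)), each evaluated over 60
one-step-ahead out-of-sample forecasts with a fresh fit at every step.
This is a desk-scale cut of the full 50-spec, 5-window protocol; the full
grid is one GridConfig away.

Output: results/scores.csv (one row per grid cell: user, period, window,
spec, MAE in BPM, failed-step count).
"""

import time
from pathlib import Path

from hrforecast import ArimaSpec, GridConfig, run_grid
from hrforecast.evaluation import records_to_frame
from hrforecast.preprocess import read_minute_csv

ROOT = Path(__file__).resolve().parents[1]
MINUTES = ROOT / "scratch" / "minutes"
RESULTS = ROOT / "results"

SPECS = (
    ArimaSpec(0, 1, 0),
    ArimaSpec(0, 1, 1),
    ArimaSpec(1, 1, 1),
    ArimaSpec(0, 0, 0),
    ArimaSpec(1, 0, 0),
    ArimaSpec(2, 0, 0),
)
GRID = GridConfig(spec_set=SPECS, window_sizes=(30, 90), oos_n=60)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    all_records = []
    t0 = time.time()
    for period in ("diurnal", "nocturnal"):
        series_by_user = {
            p.stem.removesuffix(f"_{period}"): read_minute_csv(p)
            for p in sorted(MINUTES.glob(f"user*_{period}.csv"))
        }
        for s in series_by_user.values():
            s.period_label = period
        records = run_grid(series_by_user, GRID)
        all_records.extend(records)
        print(f"{period}: {len(records)} cells from {len(series_by_user)} users")

    df = records_to_frame(all_records)
    df.to_csv(RESULTS / "scores.csv", index=False)
    print(f"\n{len(df)} score records in {time.time() - t0:.0f} s")
    print("median MAE (BPM) by spec and period:")
    print(
        df.groupby(["period", "spec"])["mae"].median().unstack(0).round(3).to_string()
    )


if __name__ == "__main__":
    main()
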