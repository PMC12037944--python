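#!/usr/bin/env python
"""Clean each user's beat stream and build minute-level period slices.

For every cohort member: remove non-physiological beats (running-median
rule + 25-250 BPM band), aggregate to minute BPM, linearly interpolate the
few missing minutes, then cut one diurnal and one nocturnal slice of 150
min (60 out-of-sample minutes + the largest 90-min window used in 03).

Reports cleaning recall against the ground-truth artifact positions saved
by 01 — the audit that the artifact rule removes what was injected and
little else.

Outputs (scratch/minutes/): user##_{diurnal,nocturnal}.csv;
results/cleaning_summary.csv.
"""

import json
from pathlib import Path

import pandas as pd

from hrforecast.preprocess import (
    aggregate_minutes,
    clean_beats,
    interpolate_missing,
    read_beats,
    slice_period,
    write_minute_csv,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
OUT = ROOT / "scratch" / "minutes"
RESULTS = ROOT / "results"
SLICE_MIN = 150  # 60 OOS + 90 max window (03's desk-scale grid)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for beat_file in sorted(COHORT.glob("user*.csv")):
        user = beat_file.stem
        beats = read_beats(beat_file, "mmash")
        cleaned, report = clean_beats(beats)
        injected = set(json.loads((COHORT / f"{user}.artifacts.json").read_text()))
        removed = set(report.removed_positions.tolist())
        recall = len(removed & injected) / max(len(injected), 1)
        false_rate = len(removed - injected) / (len(beats) - len(injected))

        minutes = interpolate_missing(aggregate_minutes(cleaned))
        for period in ("diurnal", "nocturnal"):
            sliced = slice_period(minutes, period, length_min=SLICE_MIN)
            write_minute_csv(sliced, OUT / f"{user}_{period}.csv")

        rows.append(
            {
                "user_id": user,
                "n_beats": len(beats),
                "n_injected": len(injected),
                "n_removed": report.n_removed,
                "recall": round(recall, 4),
                "false_removal_rate": round(false_rate, 6),
            }
        )
        print(
            f"{user}: {len(beats)} beats, recall {recall:.1%}, "
            f"false removals {false_rate:.3%}"
        )

    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cleaning_summary.csv", index=False)
    print(f"\ncleaning recall >= 95% for all users: "
          f"{bool((summary['recall'] >= 0.95).all())}")
    print(f"minute slices in {OUT}; summary in {RESULTS/'cleaning_summary.csv'}")


if __name__ == "__main__":
    main()
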