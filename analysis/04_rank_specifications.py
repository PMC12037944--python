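#!/usr/bin/env python
"""Rank ARIMA specifications by median per-user MAE, per experiment group.

Within each (period, window size) group the specifications are ordered by
their median MAE across users, ties broken toward parsimony.  The question
the ranking answers: does any specification with AR/MA terms beat the
random walk by a meaningful margin — i.e., is past information beyond the
last observation actually exploited?

Output: results/ranking.csv; prints the top specs and how far each group's
winner is from the random walk.
"""

from pathlib import Path

import pandas as pd

from hrforecast import ArimaSpec, ScoreRecord, rank_top_specifications

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
TOP_K = 3


def main() -> None:
    df = pd.read_csv(RESULTS / "scores.csv")
    records = [
        ScoreRecord(
            user_id=str(r.user_id),
            dataset_label=str(r.dataset_label),
            period=str(r.period),
            window_size=int(r.window_size),
            spec=ArimaSpec(int(r.p), int(r.d), int(r.q)),
            mae=float(r.mae),
            n_failed_steps=int(r.n_failed_steps),
        )
        for r in df.itertuples()
    ]
    ranking = rank_top_specifications(records, k=TOP_K)
    ranking.to_csv(RESULTS / "ranking.csv", index=False)
    print(ranking.to_string(index=False))

    rw = (
        df[df["spec"] == "(0,1,0)"]
        .groupby(["period", "window_size"])["mae"]
        .median()
        .rename("rw_median")
    )
    best = (
        ranking[ranking["rank"] == 1]
        .set_index(["period", "window_size"])[["spec", "median_mae"]]
    )
    joined = best.join(rw)
    joined["rw_gap_pct"] = 100 * (joined["rw_median"] / joined["median_mae"] - 1)
    print("\ngroup winners vs the random-walk baseline:")
    print(joined.round(3).to_string())
    print(
        "\nrw_gap_pct is how much worse (percent) the random walk's median MAE "
        "is than the group winner's; small values mean past information buys "
        "little."
    )


if __name__ == "__main__":
    main()
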