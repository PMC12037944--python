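"""Raw beats to clean minute-level BPM series.

The pipeline is: read RR intervals in one of two CSV dialects, remove
non-physiological beats (motion artifacts), aggregate to a minute grid,
linearly interpolate the few missing minutes, and optionally slice a
contiguous diurnal or nocturnal segment for period-specific evaluation.

Dialects
--------
``mmash``
    Timestamped inter-beat intervals: header ``time,ibi_s``, one beat per
    row with its wall-clock time (HH:MM:SS[.fff]) and IBI in seconds.  The
    first row's time becomes ``clock_origin``.
``rrits``
    One RR interval in milliseconds per line, no header and no time-of-day
    information, so ``clock_origin`` stays unset and day/night slicing is
    unavailable.
"""

from __future__ import annotations

import datetime as _dt
from collections import deque
from pathlib import Path

import numpy as np
import pandas as pd

from .series import HR_MAX_BPM, HR_MIN_BPM, BeatSeries, CleaningReport, MinuteSeries

__all__ = [
    "DialectParseError",
    "QualityError",
    "read_beats",
    "clean_beats",
    "aggregate_minutes",
    "interpolate_missing",
    "slice_period",
    "write_minute_csv",
    "read_minute_csv",
]


class DialectParseError(ValueError):
    """A beat file does not parse under the named dialect."""


class QualityError(ValueError):
    """The data fails a quality precondition (too sparse, too many gaps)."""


def _parse_clock(text: str, line_no: int) -> _dt.time:
    for fmt in ("%H:%M:%S.%f", "%H:%M:%S", "%H:%M"):
        try:
            return _dt.datetime.strptime(text.strip(), fmt).time()
        except ValueError:
            continue
    raise DialectParseError(f"line {line_no}: unparseable time {text!r}")


def read_beats(path: str | Path, dialect: str) -> BeatSeries:
    """Read a beat file in the ``mmash`` or ``rrits`` dialect.

    Onset times are reconstructed as cumulative RR sums with the first beat
    at t = 0 (each RR is the interval starting at its beat, so
    ``onset[i] = sum(rr[:i])``).
    """
    path = Path(path)
    if dialect == "rrits":
        rr = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    val = float(line)
                except ValueError as exc:
                    raise DialectParseError(f"line {i}: not a number: {line!r}") from exc
                if val <= 0:
                    raise ValueError(f"line {i}: non-positive RR interval {val}")
                rr.append(val)
        if not rr:
            raise QualityError(f"{path}: empty beat file")
        rr_arr = np.array(rr)
        onset = np.concatenate([[0.0], np.cumsum(rr_arr[:-1]) / 1000.0])
        return BeatSeries(onset_s=onset, rr_ms=rr_arr, clock_origin=None)

    if dialect == "mmash":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error detail
            raise DialectParseError(f"{path}: {exc}") from exc
        cols = {c.lower(): c for c in df.columns}
        if "time" not in cols or "ibi_s" not in cols:
            raise DialectParseError(
                f"{path}: mmash dialect needs columns 'time' and 'ibi_s', "
                f"found {list(df.columns)}"
            )
        if df.empty:
            raise QualityError(f"{path}: empty beat file")
        ibi = pd.to_numeric(df[cols["ibi_s"]], errors="coerce")
        bad = np.where(ibi.isna())[0]
        if bad.size:
            raise DialectParseError(f"line {bad[0] + 2}: malformed IBI value")
        if (ibi <= 0).any():
            line = int(np.where(ibi <= 0)[0][0]) + 2
            raise ValueError(f"line {line}: non-positive IBI")
        rr_arr = ibi.to_numpy() * 1000.0
        onset = np.concatenate([[0.0], np.cumsum(rr_arr[:-1]) / 1000.0])
        origin = _parse_clock(str(df[cols["time"]].iloc[0]), line_no=2)
        return BeatSeries(onset_s=onset, rr_ms=rr_arr, clock_origin=origin)

    raise ValueError(f"unknown dialect {dialect!r} (expected 'mmash' or 'rrits')")


def clean_beats(
    beats: BeatSeries,
    max_rel_change: float = 0.20,
    median_window: int = 5,
) -> tuple[BeatSeries, CleaningReport]:
    """Remove beats with non-physiological RR shifts.

    Two rules, applied in one pass:

    1. A beat whose implied HR falls outside [25, 250] BPM is removed
       unconditionally.
    2. A beat whose RR deviates from the running median of the previous
       ``median_window`` *accepted* RR values by more than ``max_rel_change``
       (relative to that median) is removed.

    The first beats are accepted on rule 1 alone until the median buffer has
    content.  Retained beats keep their original onset times, so a removal
    leaves a gap rather than shifting the record.
    """
    if len(beats) == 0:
        raise QualityError("cannot clean an empty beat series")
    if not (0 < max_rel_change < 1):
        raise ValueError("max_rel_change must lie in (0, 1)")
    if median_window < 3 or median_window % 2 == 0:
        raise ValueError("median_window must be an odd integer >= 3")

    rr = beats.rr_ms
    hr = beats.instantaneous_hr
    keep = np.ones(len(beats), dtype=bool)
    buffer: deque[float] = deque(maxlen=median_window)
    for i in range(len(beats)):
        if not (HR_MIN_BPM <= hr[i] <= HR_MAX_BPM):
            keep[i] = False
            continue
        if buffer:
            med = float(np.median(buffer))
            if abs(rr[i] - med) / med > max_rel_change:
                keep[i] = False
                continue
        buffer.append(rr[i])

    removed = np.where(~keep)[0]
    if not keep.any():
        raise QualityError(
            "cleaning removed every beat; review max_rel_change/median_window"
        )
    cleaned = BeatSeries(
        onset_s=beats.onset_s[keep],
        rr_ms=rr[keep],
        clock_origin=beats.clock_origin,
    )
    report = CleaningReport(
        n_input_beats=len(beats),
        n_removed=int(removed.size),
        removed_positions=removed,
        rule_parameters={
            "max_rel_change": max_rel_change,
            "median_window": median_window,
            "hr_band_bpm": [HR_MIN_BPM, HR_MAX_BPM],
        },
    )
    return cleaned, report


def aggregate_minutes(
    beats: BeatSeries, min_beats: int = 10, method: str = "mean_hr"
) -> MinuteSeries:
    """Aggregate beats to a minute grid of BPM values.

    Minute bins are half-open ``[m, m+1)`` minutes from record start; a
    beat belongs to the bin containing its onset.  With the default
    ``method="mean_hr"`` each bin's BPM is the mean of the instantaneous
    per-beat HR (60000 / RR) — robust to within-minute beat-count
    variation; ``method="inverse_mean_rr"`` uses 60000 / mean(RR) instead.
    Bins with fewer than ``min_beats`` beats are marked missing.
    """
    if method not in ("mean_hr", "inverse_mean_rr"):
        raise ValueError("method must be 'mean_hr' or 'inverse_mean_rr'")
    if len(beats) == 0:
        return MinuteSeries(
            index=np.array([], dtype=int),
            bpm=np.array([]),
            missing=np.array([], dtype=bool),
            clock_origin=beats.clock_origin,
        )
    minute_of = (beats.onset_s // 60.0).astype(int)
    n_minutes = int(minute_of.max()) + 1
    counts = np.bincount(minute_of, minlength=n_minutes)
    missing = counts < min_beats
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "mean_hr":
            sums = np.bincount(
                minute_of, weights=beats.instantaneous_hr, minlength=n_minutes
            )
            bpm = sums / counts
        else:
            rr_sums = np.bincount(minute_of, weights=beats.rr_ms, minlength=n_minutes)
            bpm = 60000.0 / (rr_sums / counts)
    bpm[missing] = np.nan
    return MinuteSeries(
        index=np.arange(n_minutes),
        bpm=bpm,
        missing=missing,
        clock_origin=beats.clock_origin,
    )


def interpolate_missing(
    series: MinuteSeries, max_missing_frac: float = 0.10
) -> MinuteSeries:
    """Fill internal gaps by linear interpolation between flanking minutes.

    Refuses records that are too incomplete (missing fraction above
    ``max_missing_frac``) or that start/end with a gap, since extrapolation
    would invent data.
    """
    if len(series) == 0 or not series.missing.any():
        return MinuteSeries(
            index=series.index.copy(),
            bpm=series.bpm.copy(),
            missing=series.missing.copy(),
            clock_origin=series.clock_origin,
            period_label=series.period_label,
        )
    if series.missing[0] or series.missing[-1]:
        raise QualityError("leading/trailing minutes are missing; cannot interpolate")
    frac = series.missing_fraction
    if frac > max_missing_frac:
        raise QualityError(
            f"missing fraction {frac:.3f} exceeds limit {max_missing_frac:.3f}"
        )
    pos = np.arange(len(series))
    present = ~series.missing
    bpm = series.bpm.copy()
    bpm[~present] = np.interp(pos[~present], pos[present], series.bpm[present])
    return MinuteSeries(
        index=series.index.copy(),
        bpm=bpm,
        missing=np.zeros(len(series), dtype=bool),
        clock_origin=series.clock_origin,
        period_label=series.period_label,
    )


def slice_period(
    series: MinuteSeries,
    period: str,
    length_min: int = 370,
    night_span: tuple[float, float] = (23.0, 6.0),
) -> MinuteSeries:
    """Extract a contiguous slice entirely inside the day or night span.

    ``period`` is ``"diurnal"`` or ``"nocturnal"``; ``night_span`` gives the
    clock hours of nighttime (wrap across midnight allowed).  The default
    length, 370 min, accommodates 220 out-of-sample minutes plus the largest
    rolling window (150 min).  Returns the first feasible slice, labelled
    with the period.
    """
    if period not in ("diurnal", "nocturnal"):
        raise ValueError("period must be 'diurnal' or 'nocturnal'")
    if series.clock_origin is None:
        raise QualityError(
            "series has no time-of-day (rrits dialect); use period 'unspecified' "
            "on the full record instead"
        )
    if length_min < 1 or length_min > len(series):
        raise ValueError("length_min must lie in [1, len(series)]")
    hours = series.clock_hours()
    ns, ne = night_span
    night_len = (ne - ns) % 24.0
    in_night = ((hours - ns) % 24.0) < night_len
    in_period = in_night if period == "nocturnal" else ~in_night

    # first run of >= length_min consecutive in-period minutes
    run = 0
    for i, ok in enumerate(in_period):
        run = run + 1 if ok else 0
        if run >= length_min:
            start = i - length_min + 1
            return MinuteSeries(
                index=series.index[start : i + 1].copy(),
                bpm=series.bpm[start : i + 1].copy(),
                missing=series.missing[start : i + 1].copy(),
                clock_origin=series.clock_origin,
                period_label=period,
            )
    raise ValueError(
        f"no contiguous {period} window of {length_min} min inside the record"
    )


def write_minute_csv(
    series: MinuteSeries, path: str | Path, imputed: np.ndarray | None = None
) -> None:
    """Minute-series CSV: minute_index, clock_time, bpm, imputed_flag."""
    if imputed is None:
        imputed = np.zeros(len(series), dtype=bool)
    if series.clock_origin is not None:
        hours = series.clock_hours()
        clock = [
            f"{int(h):02d}:{int(h * 60) % 60:02d}:{int(h * 3600) % 60:02d}"
            for h in hours
        ]
    else:
        clock = [""] * len(series)
    df = pd.DataFrame(
        {
            "minute_index": series.index,
            "clock_time": clock,
            "bpm": series.bpm,
            "imputed_flag": imputed.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_minute_csv(path: str | Path) -> MinuteSeries:
    """Read a minute-series CSV written by :func:`write_minute_csv`."""
    df = pd.read_csv(path)
    clock = df["clock_time"].iloc[0] if "clock_time" in df else ""
    origin = None
    if isinstance(clock, str) and clock.strip():
        origin = _parse_clock(clock, line_no=2)
    bpm = df["bpm"].to_numpy(dtype=float)
    return MinuteSeries(
        index=df["minute_index"].to_numpy(dtype=int),
        bpm=bpm,
        missing=np.isnan(bpm),
        clock_origin=origin,
    )
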