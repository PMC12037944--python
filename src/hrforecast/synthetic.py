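"""Synthetic wearable heart-rate streams.

Real 24-h wearable recordings show a circadian level shift (higher BPM during
daytime activity than during sleep), strong short-term autocorrelation at the
minute scale, occasional motion-artifact beats with non-physiological RR
values, and a small fraction of missing minutes.  This module generates
beat-level and minute-level streams with exactly that structure so the whole
pipeline — cleaning, aggregation, forecasting, diagnostics — is testable
without any data download.

The generator is fully deterministic given ``SyntheticConfig.seed``: a single
master seed is split into named sub-streams (minute-level innovations,
missingness) via :class:`numpy.random.SeedSequence`, so beat-level and
minute-level views of the same configuration share one underlying BPM
process.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .series import BeatSeries, MinuteSeries

__all__ = [
    "SyntheticConfig",
    "circadian_baseline",
    "generate_minute_series",
    "generate_beat_series",
    "inject_artifacts",
    "write_mmash_csv",
    "write_rrits_csv",
    "write_config_sidecar",
]

#: Non-physiological RR ranges (ms) used for injected motion artifacts.
#: Both lie outside the plausible beat interval band [240, 2400] ms
#: (= HR 25–250 BPM), so a correct cleaning rule must remove them.
ARTIFACT_LOW_MS = (100.0, 250.0)
ARTIFACT_HIGH_MS = (3000.0, 6000.0)

#: Width of the cosine day/night transition, in minutes.
TRANSITION_MIN = 60.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic heart-rate generator.

    Attributes
    ----------
    duration_min
        Length of the record in minutes (24 h = 1440).
    day_bpm, night_bpm
        Mean diurnal / nocturnal heart rate.  Daytime HR is higher.
    night_span
        Pair of clock hours ``(start, end)`` delimiting nighttime;
        defaults to 23:00–06:00.
    ar_coef
        Lag-1 autoregressive coefficient of the minute-level BPM deviations
        around the circadian baseline (|ar_coef| < 1).
    innovation_sd
        Standard deviation of the AR(1) innovations, in BPM.
    artifact_rate
        Expected motion artifacts per 1000 beats (used by the beat-level
        writers / :func:`inject_artifacts`).
    missing_rate
        Fraction of minutes masked missing, uniformly at random.
    seed
        Master seed; all randomness derives from it.
    """

    duration_min: int = 1440
    day_bpm: float = 80.0
    night_bpm: float = 60.0
    night_span: tuple[float, float] = (23.0, 6.0)
    ar_coef: float = 0.8
    innovation_sd: float = 2.0
    artifact_rate: float = 5.0
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("duration_min must be >= 1")
        if not (25.0 <= self.night_bpm <= self.day_bpm <= 200.0):
            raise ValueError(
                "day_bpm/night_bpm must satisfy 25 <= night_bpm <= day_bpm <= 200"
            )
        if not abs(self.ar_coef) < 1:
            raise ValueError("ar_coef must satisfy |ar_coef| < 1")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        ns, ne = self.night_span
        if not (0 <= ns < 24 and 0 <= ne < 24):
            raise ValueError("night_span hours must lie in [0, 24)")


def _signed_hour_distance(hours: np.ndarray, boundary: float) -> np.ndarray:
    """Circular signed distance (in hours) from ``boundary``, in (-12, 12]."""
    return ((np.asarray(hours, dtype=float) - boundary + 12.0) % 24.0) - 12.0


def circadian_baseline(config: SyntheticConfig, clock_hours: np.ndarray) -> np.ndarray:
    """Deterministic day/night BPM baseline at the given clock hours.

    The level is ``day_bpm`` by day and ``night_bpm`` by night, with a
    half-cosine ramp of :data:`TRANSITION_MIN` minutes centred on each
    night-span boundary, so there is no artificial level jump at 23:00
    or 06:00.
    """
    h = np.asarray(clock_hours, dtype=float)
    ns, ne = config.night_span
    half = TRANSITION_MIN / 60.0 / 2.0  # ramp half-width in hours
    night_len = (ne - ns) % 24.0

    d_start = _signed_hour_distance(h, ns)  # day -> night boundary
    d_end = _signed_hour_distance(h, ne)  # night -> day boundary
    into_night = (h - ns) % 24.0

    # night weight s in [0, 1]
    s = np.where(into_night < night_len, 1.0, 0.0)
    ramp_in = np.abs(d_start) <= half
    s = np.where(ramp_in, 0.5 * (1.0 + np.sin(np.pi * d_start / (2 * half))), s)
    ramp_out = np.abs(d_end) <= half
    s = np.where(ramp_out, 0.5 * (1.0 - np.sin(np.pi * d_end / (2 * half))), s)
    return config.day_bpm - (config.day_bpm - config.night_bpm) * s


def _substreams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _minute_bpm(config: SyntheticConfig) -> np.ndarray:
    """Baseline + AR(1) deviation process; shared by both generators."""
    n = config.duration_min
    minutes = np.arange(n)
    hours = (minutes / 60.0) % 24.0  # record starts at midnight
    base = circadian_baseline(config, hours)

    rng = _substreams(config.seed)[0]
    dev = np.zeros(n)
    if config.innovation_sd > 0:
        eps = rng.normal(0.0, config.innovation_sd, size=n)
        # stationary start so the deviation variance is flat over the record
        dev[0] = eps[0] / np.sqrt(1.0 - config.ar_coef**2)
        for t in range(1, n):
            dev[t] = config.ar_coef * dev[t - 1] + eps[t]
    bpm = base + dev
    # HR cannot leave the physiological band however unlucky the draws
    return np.clip(bpm, 25.0, 250.0)


def generate_minute_series(config: SyntheticConfig) -> MinuteSeries:
    """Minute-level BPM series: circadian baseline + AR(1) deviations.

    ``missing_rate`` of the minutes are masked missing (BPM set to NaN),
    uniformly at random.  The record starts at midnight, so a 24-h record
    contains both full periods.
    """
    bpm = _minute_bpm(config)
    n = config.duration_min
    rng_missing = _substreams(config.seed)[1]
    missing = rng_missing.random(n) < config.missing_rate
    out = bpm.copy()
    out[missing] = np.nan
    return MinuteSeries(
        index=np.arange(n),
        bpm=out,
        missing=missing,
        clock_origin=_dt.time(0, 0, 0),
    )


def generate_beat_series(config: SyntheticConfig) -> BeatSeries:
    """Beat-level RR stream consistent with the minute-level BPM process.

    Within each minute beats are emitted at the minute's instantaneous rate
    (RR = 60000 / BPM ms), so aggregating the beats back to minutes recovers
    the underlying BPM to within one beat per minute.  Onset times are the
    cumulative sums of the RR intervals, first beat at t = 0.
    """
    bpm = _minute_bpm(config)
    total_s = config.duration_min * 60.0
    onsets: list[float] = []
    rrs: list[float] = []
    t = 0.0
    while t < total_s:
        minute = min(int(t // 60.0), config.duration_min - 1)
        rr = 60000.0 / bpm[minute]
        onsets.append(t)
        rrs.append(rr)
        t += rr / 1000.0
    return BeatSeries(
        onset_s=np.array(onsets),
        rr_ms=np.array(rrs),
        clock_origin=_dt.time(0, 0, 0),
    )


def inject_artifacts(
    beats: BeatSeries, rate: float, seed: int
) -> tuple[BeatSeries, np.ndarray]:
    """Corrupt a Poisson-sampled subset of beats with non-physiological RRs.

    ``rate`` is expected artifacts per 1000 beats.  Each corrupted beat gets
    an RR drawn uniformly from either :data:`ARTIFACT_LOW_MS` or
    :data:`ARTIFACT_HIGH_MS` (coin flip), mimicking the spikes and dropouts
    motion artifacts produce.  Returns the corrupted series and the sorted
    array of altered positions, so cleaning recall is verifiable.
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(beats)
    n_artifacts = min(int(rng.poisson(rate / 1000.0 * n)), n)
    if n_artifacts == 0:
        return beats, np.array([], dtype=int)
    positions = np.sort(rng.choice(n, size=n_artifacts, replace=False))
    rr = beats.rr_ms.copy()
    high = rng.random(n_artifacts) < 0.5
    lo_a, lo_b = ARTIFACT_LOW_MS
    hi_a, hi_b = ARTIFACT_HIGH_MS
    rr[positions] = np.where(
        high,
        rng.uniform(hi_a, hi_b, size=n_artifacts),
        rng.uniform(lo_a, lo_b, size=n_artifacts),
    )
    return beats.replace(rr_ms=rr), positions


# ---------------------------------------------------------------------------
# Writers for the two CSV dialects the preprocess module reads.
# ---------------------------------------------------------------------------


def _clock_str(origin: _dt.time, onset_s: float) -> str:
    base = origin.hour * 3600 + origin.minute * 60 + origin.second
    total = (base + onset_s) % 86400.0
    h = int(total // 3600)
    m = int(total % 3600 // 60)
    s = total % 60
    return f"{h:02d}:{m:02d}:{s:06.3f}"


def write_mmash_csv(beats: BeatSeries, path: str | Path) -> None:
    """Write the timestamped dialect: header ``time,ibi_s``, IBI in seconds."""
    origin = beats.clock_origin or _dt.time(0, 0, 0)
    with open(path, "w") as fh:
        fh.write("time,ibi_s\n")
        for onset, rr in zip(beats.onset_s, beats.rr_ms):
            fh.write(f"{_clock_str(origin, onset)},{rr / 1000.0:.6f}\n")


def write_rrits_csv(beats: BeatSeries, path: str | Path) -> None:
    """Write the bare dialect: one RR interval in ms per line, no time-of-day."""
    with open(path, "w") as fh:
        for rr in beats.rr_ms:
            fh.write(f"{rr:.3f}\n")


def write_config_sidecar(config: SyntheticConfig, path: str | Path) -> None:
    """JSON sidecar recording the full generator configuration."""
    d = dataclasses.asdict(config)
    d["night_span"] = list(d["night_span"])
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")
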