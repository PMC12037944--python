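"""Core containers for beat-level and minute-level heart-rate streams.

A wearable records inter-beat (RR) intervals; downstream analysis works on a
minute-indexed BPM series.  ``BeatSeries`` holds the raw (or cleaned) beats,
``MinuteSeries`` the aggregated minute grid with an explicit missing mask.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BeatSeries", "MinuteSeries", "CleaningReport"]

#: Physiological heart-rate range in beats per minute; instantaneous HR
#: outside this band is treated as a recording error.
HR_MIN_BPM = 25.0
HR_MAX_BPM = 250.0


@dataclass(frozen=True)
class BeatSeries:
    """Timestamped RR-interval stream at beat granularity.

    Parameters
    ----------
    onset_s
        Beat onset times in seconds from record start, strictly increasing.
    rr_ms
        Inter-beat interval ending at each onset, in milliseconds (> 0).
    clock_origin
        Wall-clock time of the first beat, if known.  RR-only exports (one
        interval per line) carry no time-of-day and leave this ``None``.
    """

    onset_s: np.ndarray
    rr_ms: np.ndarray
    clock_origin: _dt.time | None = None

    def __post_init__(self) -> None:
        onset = np.asarray(self.onset_s, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "onset_s", onset)
        object.__setattr__(self, "rr_ms", rr)
        if onset.ndim != 1 or rr.ndim != 1 or len(onset) != len(rr):
            raise ValueError("onset_s and rr_ms must be 1-D and equally long")
        if len(rr) and np.any(rr <= 0):
            raise ValueError("rr_ms must be strictly positive")
        if len(onset) > 1 and np.any(np.diff(onset) <= 0):
            raise ValueError("onset_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def instantaneous_hr(self) -> np.ndarray:
        """Per-beat heart rate, 60000 / RR(ms), in BPM."""
        return 60000.0 / self.rr_ms

    def replace(self, **kwargs) -> "BeatSeries":
        return replace(self, **kwargs)


@dataclass
class MinuteSeries:
    """Minute-indexed BPM values with an explicit missing mask.

    ``index`` counts minutes from the record origin; ``bpm`` is NaN wherever
    ``missing`` is True.  ``period_label`` tags slices extracted from the
    diurnal or nocturnal part of the day ("unspecified" otherwise).
    """

    index: np.ndarray
    bpm: np.ndarray
    missing: np.ndarray
    clock_origin: _dt.time | None = None
    period_label: str = "unspecified"

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=int)
        self.bpm = np.asarray(self.bpm, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.index) == len(self.bpm) == len(self.missing)):
            raise ValueError("index, bpm and missing must be equally long")
        if self.period_label not in ("diurnal", "nocturnal", "unspecified"):
            raise ValueError(f"unknown period_label {self.period_label!r}")

    def __len__(self) -> int:
        return len(self.bpm)

    @property
    def values(self) -> np.ndarray:
        """BPM vector; only meaningful where ``missing`` is False."""
        return self.bpm

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean()) if len(self) else 0.0

    def clock_hours(self) -> np.ndarray:
        """Clock hour (fractional, in [0, 24)) of each minute.

        Requires ``clock_origin``; RR-only data has no time-of-day.
        """
        if self.clock_origin is None:
            raise ValueError("series has no clock_origin (no time-of-day)")
        t0 = self.clock_origin
        origin_h = t0.hour + t0.minute / 60.0 + t0.second / 3600.0
        return (origin_h + self.index / 60.0) % 24.0


@dataclass(frozen=True)
class CleaningReport:
    """Audit trail of beat cleaning: how many beats were removed and where."""

    n_input_beats: int
    n_removed: int
    removed_positions: np.ndarray
    rule_parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.removed_positions, dtype=int)
        object.__setattr__(self, "removed_positions", pos)
        if self.n_removed != len(pos):
            raise ValueError("n_removed must equal len(removed_positions)")
        if self.n_removed > self.n_input_beats:
            raise ValueError("cannot remove more beats than were supplied")

    def to_dict(self) -> dict:
        return {
            "n_input_beats": int(self.n_input_beats),
            "n_removed": int(self.n_removed),
            "removed_positions": [int(p) for p in self.removed_positions],
            "rule_parameters": dict(self.rule_parameters),
        }
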