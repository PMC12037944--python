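"""Preprocessing: dialect parsing, cleaning, aggregation, interpolation."""

import datetime as dt

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrforecast import (
    BeatSeries,
    MinuteSeries,
    SyntheticConfig,
    aggregate_minutes,
    clean_beats,
    generate_beat_series,
    inject_artifacts,
    interpolate_missing,
    read_beats,
    slice_period,
)
from hrforecast.preprocess import QualityError, read_minute_csv, write_minute_csv


def beats_from_rr(rr_ms, clock_origin=None):
    rr = np.asarray(rr_ms, dtype=float)
    onset = np.concatenate([[0.0], np.cumsum(rr[:-1]) / 1000.0])
    return BeatSeries(onset_s=onset, rr_ms=rr, clock_origin=clock_origin)


class TestReadBeats:
    def test_rrits_cumulative_onsets(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("800\n810\n790\n")
        beats = read_beats(p, "rrits")
        assert len(beats) == 3
        npt.assert_allclose(beats.onset_s, [0.0, 0.8, 1.61])
        assert beats.clock_origin is None

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(QualityError):
            read_beats(p, "rrits")

    def test_mmash_units_and_clock(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("time,ibi_s\n14:00:00,1.000\n14:00:01,1.000\n")
        beats = read_beats(p, "mmash")
        npt.assert_allclose(beats.rr_ms, [1000.0, 1000.0])
        assert beats.clock_origin == dt.time(14, 0, 0)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("800\nxyz\n")
        with pytest.raises(ValueError, match="line 2"):
            read_beats(p, "rrits")

    def test_nonpositive_rr_rejected(self, tmp_path):
        p = tmp_path / "neg.txt"
        p.write_text("800\n-5\n")
        with pytest.raises(ValueError):
            read_beats(p, "rrits")


class TestCleanBeats:
    def test_steady_beats_unchanged(self):
        beats = beats_from_rr([800.0] * 50)
        cleaned, report = clean_beats(beats)
        assert report.n_removed == 0
        npt.assert_array_equal(cleaned.rr_ms, beats.rr_ms)

    def test_single_spike_removed(self):
        rr = [800.0] * 25 + [200.0] + [800.0] * 25
        cleaned, report = clean_beats(beats_from_rr(rr))
        assert report.n_removed == 1
        assert report.removed_positions.tolist() == [25]
        assert 200.0 not in cleaned.rr_ms

    def test_small_alternation_kept(self):
        rr = [780.0, 820.0] * 25
        _, report = clean_beats(beats_from_rr(rr))
        assert report.n_removed == 0

    def test_out_of_band_hr_always_removed(self):
        # 3000 ms -> 20 BPM, below the 25 BPM physiological floor
        rr = [800.0] * 10 + [3000.0] + [800.0] * 10
        _, report = clean_beats(beats_from_rr(rr))
        assert 10 in report.removed_positions.tolist()

    def test_all_removed_raises(self):
        beats = beats_from_rr([5000.0, 5000.0, 5000.0])
        with pytest.raises(QualityError):
            clean_beats(beats)

    @pytest.mark.parametrize("kwargs", [{"max_rel_change": 0.0},
                                        {"max_rel_change": 1.5},
                                        {"median_window": 4},
                                        {"median_window": 1}])
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            clean_beats(beats_from_rr([800.0] * 10), **kwargs)

    def test_recall_and_false_removal_on_injected_artifacts(self):
        """Cleaning recovers >=95% of injected artifacts, removes <=1% clean beats."""
        cfg = SyntheticConfig(duration_min=120, missing_rate=0.0, seed=21)
        beats = generate_beat_series(cfg)
        corrupted, positions = inject_artifacts(beats, rate=10.0, seed=22)
        assert positions.size > 20
        _, report = clean_beats(corrupted)
        removed = set(report.removed_positions.tolist())
        injected = set(positions.tolist())
        recall = len(removed & injected) / len(injected)
        false_rate = len(removed - injected) / (len(beats) - len(injected))
        assert recall >= 0.95
        assert false_rate <= 0.01


class TestAggregateMinutes:
    def test_uniform_1000ms_gives_60_bpm(self):
        agg = aggregate_minutes(beats_from_rr([1000.0] * 60))
        assert len(agg) == 1
        npt.assert_allclose(agg.bpm[0], 60.0)

    def test_mixed_rate_minute_mean_instantaneous_hr(self):
        # 30 beats at 800 ms (75 BPM) + 30 at 1200 ms (50 BPM) = one minute
        agg = aggregate_minutes(beats_from_rr([800.0] * 30 + [1200.0] * 30))
        assert len(agg) == 1
        npt.assert_allclose(agg.bpm[0], 62.5)

    def test_inverse_mean_rr_alternative(self):
        # 60000 / mean(800, 1200) = 60 BPM, vs 62.5 under mean-HR
        beats = beats_from_rr([800.0] * 30 + [1200.0] * 30)
        agg = aggregate_minutes(beats, method="inverse_mean_rr")
        npt.assert_allclose(agg.bpm[0], 60.0)
        with pytest.raises(ValueError, match="method"):
            aggregate_minutes(beats, method="harmonic")

    def test_sparse_minute_marked_missing(self):
        agg = aggregate_minutes(beats_from_rr([1000.0, 1000.0, 1000.0]))
        assert agg.missing[0]

    def test_empty_input_gives_empty_series(self):
        empty = BeatSeries(onset_s=np.array([]), rr_ms=np.array([]))
        assert len(aggregate_minutes(empty)) == 0

    def test_minute_bpm_within_instantaneous_range(self):
        beats = generate_beat_series(SyntheticConfig(duration_min=30, seed=8))
        agg = aggregate_minutes(beats)
        minute_of = (beats.onset_s // 60.0).astype(int)
        hr = beats.instantaneous_hr
        for m in range(len(agg)):
            if agg.missing[m]:
                continue
            sel = hr[minute_of == m]
            assert sel.min() - 1e-9 <= agg.bpm[m] <= sel.max() + 1e-9


class TestInterpolateMissing:
    def _series(self, bpm):
        bpm = np.asarray(bpm, dtype=float)
        return MinuteSeries(
            index=np.arange(len(bpm)), bpm=bpm, missing=np.isnan(bpm)
        )

    def test_single_gap_midpoint(self):
        out = interpolate_missing(
            self._series([60.0, np.nan, 70.0]), max_missing_frac=0.5
        )
        npt.assert_allclose(out.bpm, [60.0, 65.0, 70.0])
        assert not out.missing.any()

    def test_double_gap_equal_thirds(self):
        out = interpolate_missing(
            self._series([60.0, np.nan, np.nan, 72.0]), max_missing_frac=0.5
        )
        npt.assert_allclose(out.bpm, [60.0, 64.0, 68.0, 72.0])

    def test_no_missing_is_noop(self):
        out = interpolate_missing(self._series([60.0, 61.0, 62.0]))
        npt.assert_array_equal(out.bpm, [60.0, 61.0, 62.0])

    def test_excess_missing_rejected(self):
        bpm = [60.0] + [np.nan] * 5 + [60.0]
        with pytest.raises(QualityError, match="missing fraction"):
            interpolate_missing(self._series(bpm), max_missing_frac=0.10)

    def test_boundary_gap_rejected(self):
        with pytest.raises(QualityError, match="leading/trailing"):
            interpolate_missing(self._series([np.nan, 60.0, 61.0]))

    @given(
        slope=st.floats(-2, 2, allow_nan=False),
        offset=st.floats(40, 100, allow_nan=False),
        gap_start=st.integers(1, 8),
        gap_len=st.integers(1, 3),
    )
    def test_exact_on_linear_data(self, slope, offset, gap_start, gap_len):
        n = 14
        line = offset + slope * np.arange(n)
        bpm = line.copy()
        bpm[gap_start : gap_start + gap_len] = np.nan
        out = interpolate_missing(self._series(bpm), max_missing_frac=0.5)
        npt.assert_allclose(out.bpm, line, atol=1e-9)


class TestSlicePeriod:
    def test_nocturnal_slice_inside_night(self, day_series):
        sliced = slice_period(day_series, "nocturnal", 370)
        assert len(sliced) == 370
        assert sliced.period_label == "nocturnal"
        hours = sliced.clock_hours()
        in_night = ((hours - 23.0) % 24.0) < 7.0
        assert in_night.all()

    def test_diurnal_slice_inside_day(self, day_series):
        sliced = slice_period(day_series, "diurnal", 370)
        hours = sliced.clock_hours()
        assert (((hours - 6.0) % 24.0) < 17.0).all()

    def test_no_clock_origin_rejected(self):
        series = MinuteSeries(
            index=np.arange(10), bpm=np.full(10, 70.0), missing=np.zeros(10, bool)
        )
        with pytest.raises(QualityError, match="time-of-day"):
            slice_period(series, "nocturnal", 5)

    def test_infeasible_length_rejected(self, day_series):
        with pytest.raises(ValueError):
            slice_period(day_series, "nocturnal", 2000)


def test_pipeline_smooths_first_differences():
    """Cleaning + aggregation damp the jumpiness artifacts introduce."""
    cfg = SyntheticConfig(duration_min=120, missing_rate=0.0, seed=13)
    beats = generate_beat_series(cfg)
    corrupted, _ = inject_artifacts(beats, rate=10.0, seed=14)
    raw_var = np.diff(corrupted.instantaneous_hr).var()
    cleaned, _ = clean_beats(corrupted)
    minutes = aggregate_minutes(cleaned)
    agg_var = np.diff(minutes.bpm[~minutes.missing]).var()
    assert agg_var < raw_var


def test_minute_csv_round_trip(tmp_path, quiet_series):
    path = tmp_path / "minutes.csv"
    write_minute_csv(quiet_series, path)
    back = read_minute_csv(path)
    npt.assert_allclose(back.bpm, quiet_series.bpm)
    assert back.clock_origin is not None
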