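"""Residual diagnostics: standardization, Durbin-Watson, normality, histogram."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrforecast import (
    ArimaSpec,
    EngineConfig,
    MinuteSeries,
    classify_dw,
    durbin_watson,
    normality_tests,
    residual_report,
    run_rolling_forecast,
    standardize_residuals,
)

from conftest import make_rw_series

RW = ArimaSpec(0, 1, 0)


class TestStandardize:
    def test_output_has_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        std = standardize_residuals(rng.normal(3.0, 2.5, size=200))
        assert std.mean() == pytest.approx(0.0, abs=1e-12)
        assert std.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        e = np.array([0.3, -1.2, 0.9, 2.1, -0.4])
        npt.assert_allclose(
            standardize_residuals(3.0 * e + 7.0), standardize_residuals(e), atol=1e-12
        )

    def test_two_point_case_sample_convention(self):
        # sample (ddof=1) sd of [1, -1] is sqrt(2) -> output is +-1/sqrt(2);
        # population convention would give +-1
        out = standardize_residuals(np.array([1.0, -1.0]))
        npt.assert_allclose(out, [1.0 / np.sqrt(2), -1.0 / np.sqrt(2)])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_residuals(np.full(10, 2.0))


class TestDurbinWatson:
    @pytest.mark.parametrize(
        "residuals,expected",
        [
            ([1.0, 1.0, 1.0, 1.0], 0.0),
            ([1.0, -1.0, 1.0, -1.0], 3.0),
            ([1.0, 2.0, 3.0, 4.0], 0.1),
        ],
    )
    def test_hand_computed_values(self, residuals, expected):
        assert durbin_watson(np.array(residuals)) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(5))

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=30),
        st.sampled_from([-3.0, -0.5, 0.25, 2.0]),
    )
    def test_scale_invariance(self, residuals, scale):
        e = np.array(residuals)
        if np.sum(e**2) == 0:
            return
        assert durbin_watson(scale * e) == pytest.approx(durbin_watson(e), rel=1e-9)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.stattools import durbin_watson as sm_dw

        rng = np.random.default_rng(5)
        e = rng.normal(size=500)
        assert durbin_watson(e) == pytest.approx(float(sm_dw(e)), abs=1e-12)

    def test_large_sample_identity_with_lag1_autocorrelation(self):
        rng = np.random.default_rng(6)
        e = np.zeros(2000)
        for t in range(1, 2000):
            e[t] = 0.4 * e[t - 1] + rng.normal()
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert abs(durbin_watson(e) - 2.0 * (1.0 - r1)) < 0.05


class TestClassify:
    @pytest.mark.parametrize(
        "dw,expected",
        [
            (2.0, "none"),
            (2.6, "negative_autocorr"),
            (1.5, "none"),
            (2.5, "none"),
            (1.49, "positive_autocorr"),
            (0.0, "none_or_pos"),
        ],
    )
    def test_boundaries(self, dw, expected):
        if expected == "none_or_pos":
            assert classify_dw(dw) == "positive_autocorr"
        else:
            assert classify_dw(dw) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            classify_dw(4.5)


class TestNormality:
    def test_uniform_residuals_rejected_as_normal(self):
        rng = np.random.default_rng(7)
        std = standardize_residuals(rng.uniform(-10, 10, size=500))
        sw_p, _ = normality_tests(std)
        assert sw_p < 0.01

    def test_gaussian_residuals_pass(self):
        rng = np.random.default_rng(8)
        std = standardize_residuals(rng.normal(size=500))
        sw_p, ks_p = normality_tests(std)
        assert sw_p > 0.05
        assert ks_p > 0.05

    def test_ks_detects_contamination(self):
        """Replacing part of a Gaussian sample with wide uniform noise moves
        the standardized sample measurably away from normality.  (The KS
        distance is not monotone in the contamination fraction because
        standardization rescales the mixture, so the assertion is clean
        vs. contaminated, not ordered by fraction.)"""
        from scipy import stats

        rng = np.random.default_rng(9)
        base = rng.normal(size=500)
        ds, ps = [], []
        for frac in (0.0, 0.2, 0.5):
            e = base.copy()
            k = int(frac * len(e))
            if k:
                e[:k] = rng.uniform(-8, 8, size=k)
            std = standardize_residuals(e)
            ps.append(normality_tests(std)[1])
            ds.append(stats.kstest(std, "norm").statistic)
        assert ds[0] < min(ds[1:])
        assert ps[0] > 0.05
        assert max(ps[1:]) < 0.01

    def test_undersized_input_rejected(self):
        with pytest.raises(ValueError):
            normality_tests(np.array([0.1, -0.1]))


class TestResidualReport:
    def test_rw_on_gaussian_random_walk_has_uncorrelated_residuals(self):
        series = make_rw_series(seed=10, n=400)
        result = run_rolling_forecast(
            series, RW, EngineConfig(window_size=30, oos_n=220), include_constant=False
        )
        report = residual_report(result)
        assert abs(report.dw - 2.0) < 0.3
        assert report.dw_class == "none"

    def test_rw_on_white_noise_levels_gives_negative_autocorrelation(self):
        """Differencing white noise yields rho(1) = -0.5, hence DW near 3."""
        rng = np.random.default_rng(11)
        n = 1500
        series = MinuteSeries(
            index=np.arange(n),
            bpm=70.0 + rng.normal(size=n),
            missing=np.zeros(n, bool),
        )
        result = run_rolling_forecast(
            series, RW, EngineConfig(window_size=30, oos_n=1000), include_constant=False
        )
        report = residual_report(result)
        assert abs(report.dw - 3.0) < 0.2
        assert report.dw_class == "negative_autocorr"

    def test_histogram_counts_conserve_n(self):
        series = make_rw_series(seed=12, n=300)
        result = run_rolling_forecast(
            series, RW, EngineConfig(window_size=15, oos_n=220)
        )
        report = residual_report(result)
        assert int(report.hist_counts.sum()) == len(report.std_residuals) == 220

    def test_rw_on_mean_reverting_hr_tends_negative(self):
        """AR(1) levels (phi=0.5): RW residual DW exceeds 2 almost surely."""
        above = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.zeros(160)
            for t in range(1, 160):
                x[t] = 0.5 * x[t - 1] + rng.normal()
            series = MinuteSeries(
                index=np.arange(160), bpm=70 + x, missing=np.zeros(160, bool)
            )
            result = run_rolling_forecast(
                series,
                RW,
                EngineConfig(window_size=30, oos_n=100),
                include_constant=False,
            )
            if durbin_watson(result.residual) > 2.0:
                above += 1
        assert above >= 95

    def test_pooled_heterogeneous_residuals_concentrate_within_one(self):
        """Pooling users with different innovation scales is leptokurtic:
        central +-1 mass of the standardized pool exceeds the normal's 68%."""
        rng = np.random.default_rng(13)
        pooled = np.concatenate(
            [rng.normal(0, 1.0, size=220), rng.normal(0, 3.0, size=220)]
        )
        std = standardize_residuals(pooled)
        assert np.mean(np.abs(std) <= 1.0) > 0.68

    def test_report_json_round_trip(self, tmp_path):
        import json

        series = make_rw_series(seed=14, n=200)
        result = run_rolling_forecast(
            series, RW, EngineConfig(window_size=15, oos_n=100)
        )
        report = residual_report(result)
        path = tmp_path / "diag.json"
        report.write_json(path)
        data = json.loads(path.read_text())
        assert data["dw_class"] == report.dw_class
        assert sum(data["hist_counts"]) == data["n_residuals"]
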