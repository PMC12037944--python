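# Methods

This note records the models, parameter choices and numerical conventions
behind `hrforecast`, and what the synthetic data does and does not
establish.

## Forecasting protocol

The object of study is one-step-ahead univariate forecasting of minute-level
heart rate. A series is split chronologically: the final `N` minutes are
held out (default `N = 220`; at 1-min granularity this exceeds the ~200
out-of-sample observations usually recommended for reliable scores). At step
`k = 1..N` the model trains on the `w` observations immediately preceding
held-out minute `k` and emits a single forecast. Two adaptive-learning
choices are fixed by design and validated by tests:

- **rolling window** — the training slice has constant size `w`; the oldest
  minute is dropped as each actual arrives (no expanding-window mode);
- **retrain per step** — all parameters are re-estimated at every step, so
  the model tracks concept drift (activity, stress, sleep transitions)
  rather than relying on stale weights.

The horizon is hard-fixed at 1; multi-step strategies are out of scope.
`N` equals the number of forecasts and of model fits. Note the symbol `p`
is used in the field both for the AR order and for the number of forecast
iterations; the engine calls the latter `oos_n` to avoid the collision.

## Models

**Random walk with drift = ARIMA(0,1,0).** Closed form on a window `x`:
intercept `= mean(Δx)`, `σ² = var(Δx)` (sample, ddof = 1), point forecast
`= x_w + intercept`. The point forecast is the conditional mean; σ² is
carried for diagnostics, never added as noise. With the constant disabled
the forecast is exactly the last observation, which makes the out-of-sample
MAE the mean absolute first difference of the held-out segment —
bit-identical across window sizes, a property the tests assert.

**ARIMA(p,d,q).** The window is differenced `d` times in-package, then an
ARMA(p,q) with a constant is estimated on the differenced scale
(statsmodels state-space ARIMA, Gaussian ML). The stored intercept is the
*mean-form* constant μ of the differenced process; for p = q = 0 the fit is
closed-form (sample mean and variance of the differenced window), which
keeps the (0,1,0) route exactly equal to the random-walk closed form. The
one-step forecast is computed here, as a pure function of the fitted
coefficients and the window: innovations are reconstructed by the
conditional-sum-of-squares recursion with zero pre-sample errors,
`ẑ = μ + Σφ_i(z_{t+1−i} − μ) + Σϑ_j ε_{t+1−j}`, then integrated back to
levels (`d` partial sums). For pure-AR models this agrees with the
state-space forecast to ~1e-4 (asserted); for MA models the CSS recursion
is the documented convention. A constant is included by default for every
spec (the random-walk benchmark explicitly has one); a flag disables it.

Non-convergent fits do not abort a run: the step is recorded as failed,
its forecast is NaN, and MAE is computed over successful steps with the
failure count reported alongside.

## Scoring and ranking

MAE is the primary metric (same BPM scale as the data). MAPE is implemented
but raises if any actual value lies in (−1, 1): such denominators inflate
percentages arbitrarily, a real hazard once series are differenced. The
experiment grid crosses users × window sizes {15, 30, 45, 90, 150} min ×
specifications (default: all p < 5, d < 2, q < 5 — 50 specs; arbitrary
sets, including larger exceptional orders, are accepted) × time-of-day
where a clock is available. Per (dataset, period, window) group, specs are
ranked by median per-user MAE; ties break toward parsimony (smaller
p+d+q, then lexicographic (p,d,q)). The per-group top-k are reported with
membership, so the union across groups may exceed k. Duplicate grid cells
are rejected at ranking time.

## Residual diagnostics

Residuals of the selected model (in practice the random walk) are
standardized with the *sample* (ddof = 1) standard deviation — the
convention is stated in the report metadata since the population convention
gives visibly different values at small n. Normality: Shapiro–Wilk, and
Kolmogorov–Smirnov against the standard normal (scipy implementations).
Autocorrelation: the Durbin–Watson statistic computed from its definition
(cross-checked against statsmodels to 1e-12 in tests), classified with
inclusive boundaries — d in [1.5, 2.5] reads "none", below positive, above
negative. No DW p-value tables are used; the interval is a heuristic
classification, which is how it is used in this literature. Histograms use
fixed bins (width 0.25 on [−4, 4] with overflow bins) so panels are
comparable across users.

One caution from the contamination experiments: the KS distance of
*self-standardized* residuals is not monotone in the contamination
fraction (standardizing rescales the mixture), so tests assert
clean-vs-contaminated separation rather than monotonicity.

## Synthetic data

The generator emulates the features of 24-h wearable recordings that the
pipeline must survive, with defaults chosen as typical resting/ambulatory
values:

| parameter | default | meaning |
|---|---|---|
| `day_bpm` / `night_bpm` | 80 / 60 BPM | circadian levels (day > night) |
| `night_span` | 23:00–06:00 | nocturnal clock span (configurable; real datasets do not pin these boundaries) |
| transition | 60-min cosine ramp | smooth day/night level change, centred on the span boundaries |
| `ar_coef` | 0.8 | lag-1 coefficient of AR(1) minute-level deviations |
| `innovation_sd` | 2 BPM | AR(1) innovation scale |
| `artifact_rate` | 5 / 1000 beats | motion artifacts; RR drawn from [100, 250] ∪ [3000, 6000] ms, outside the physiological 25–250 BPM band *by construction* so cleaning recall is measurable |
| `missing_rate` | 1% of minutes | uniform missingness (matches the low missingness of compliant wearable wear) |

Beats are emitted at each minute's instantaneous rate (RR = 60000/BPM), so
aggregating beats recovers the minute process within ±1 BPM. A single
master seed drives everything through named `SeedSequence` sub-streams;
same config + seed is bit-reproducible. Records start at midnight; 48-h
records are used when a contiguous 370-min nocturnal slice (220 OOS + the
150-min max window) is needed, since the night span crosses midnight.

**What passing tests do not show.** The generator has no respiratory sinus
arrhythmia, no LF/HF spectral structure, no activity covariates, no ectopic
beats, and its artifacts are independent rather than burst-like. Results on
it validate the *machinery* (windowing, leak-freedom, closed forms,
classification thresholds) and the qualitative benchmark behaviour — not
physiological claims about real cohorts. Real-data loaders are provided for
the two supported CSV dialects, but no real-data numbers are asserted
anywhere.

## Numerical and design choices

- **Cleaning rule.** Artifact criteria vary across the literature; the
  implemented rule is a running median filter: reject a beat whose RR
  deviates more than 20% from the median of the last 5 *accepted* RR
  values, plus an unconditional 25–250 BPM band. Both parameters are
  exposed. Using only accepted beats in the buffer keeps a burst of
  artifacts from poisoning the reference. Removed beats leave gaps;
  retained onsets are never shifted.
- **Minute BPM = mean instantaneous HR**, not 60000/mean(RR): robust to
  within-minute beat-count variation; the alternative is a config switch.
  Bins are half-open `[m, m+1)` from the record origin; bins with < 10
  beats (configurable) are missing.
- **Interpolation** is linear between flanking present minutes, refuses
  records missing > 10% (configurable) and refuses leading/trailing gaps
  rather than extrapolate.
- **DW boundaries** are inclusive into the "none" class (exactly 1.5 or
  2.5 → none).
- **Grid bounds** p < 5, d < 2, q < 5 are treated as strict (`<`), with the
  spec set fully overridable.
- **Desk-scale profiles.** The full protocol (22 users × 50 specs × 5
  windows × 220 steps × 2 periods) is ~500k maximum-likelihood fits; the
  shipped analysis drivers and the test suite use reduced profiles (6–10
  users, 4–6 specs, windows {30, 90}, N = 60) chosen so the complete
  pipeline — including the benchmark comparison, where the reduced grid is
  {(0,1,0), (1,1,1), (0,1,1), (2,0,0)} over 10 random-walk users — runs in
  minutes while exercising every code path at full fidelity. The 220-step
  configurations are retained wherever the model is closed-form (random
  walk), where they cost nothing.
- **Seeds.** Per-user seeds are spawned from one master seed; every run
  emits a manifest (config hash, seed list, library versions) sufficient
  to replay bit-identically on the same machine.

## Known limitations

- The CSS one-step forecast for MA-bearing specs differs from the exact
  Kalman conditional mean by O(ϑ^w) edge effects; negligible at the window
  sizes used, but the two are not bit-identical.
- Statsmodels occasionally reports non-convergence on short windows with
  over-parameterized specs; those steps are skipped and counted, which
  slightly biases MAE comparisons for unstable specs (the count is
  reported so the bias is visible).
- `slice_period` returns the *first* feasible in-period window; it does not
  optimize slice placement, and period membership is by clock span, so the
  cosine transition's edges can sit inside a slice.
- Sample-variance σ² of a single 150-point window has sampling sd ≈ 0.12
  around the true innovation variance; consistency checks average several
  seeds for this reason.
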