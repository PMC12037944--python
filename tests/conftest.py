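import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrforecast import MinuteSeries, SyntheticConfig, generate_minute_series
from hrforecast.preprocess import interpolate_missing

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_rw_series(seed: int, n: int, start: float = 70.0) -> MinuteSeries:
    """Gaussian random walk in levels (innovation sd 1), as a minute series."""
    rng = np.random.default_rng(seed)
    values = start + np.cumsum(rng.normal(size=n))
    return MinuteSeries(index=np.arange(n), bpm=values, missing=np.zeros(n, bool))


@pytest.fixture(scope="session")
def day_series() -> MinuteSeries:
    """48-h synthetic HR record, gap-free, starting at midnight."""
    cfg = SyntheticConfig(duration_min=2880, seed=11)
    series = generate_minute_series(cfg)
    return interpolate_missing(series)


@pytest.fixture(scope="session")
def quiet_series() -> MinuteSeries:
    """Constant-baseline AR(1) series (no circadian ramp, no gaps)."""
    cfg = SyntheticConfig(
        duration_min=600,
        day_bpm=70.0,
        night_bpm=70.0,
        ar_coef=0.5,
        innovation_sd=2.0,
        missing_rate=0.0,
        seed=5,
    )
    return generate_minute_series(cfg)
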