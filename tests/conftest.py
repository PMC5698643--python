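import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grousepheno import pipeline
from grousepheno.simulate import SimulationConfig, simulate_bundle
from grousepheno.weather import validate_weather

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_weather(year=2000, n_days=None, start_doy=1, t_min=None, t_avg=None,
                 t_max=None, precip=0.0, snow_score=0):
    """Build a small validated weather frame from per-day arrays/scalars."""
    arrays = [np.atleast_1d(np.asarray(a, dtype=float))
              for a in (t_min, t_avg, t_max) if a is not None]
    if n_days is None:
        n_days = max((a.size for a in arrays), default=10)

    def expand(val, default):
        if val is None:
            return default
        val = np.asarray(val, dtype=float)
        return np.full(n_days, float(val)) if val.ndim == 0 else val

    t_min = expand(t_min, None)
    t_avg = expand(t_avg, None)
    t_max = expand(t_max, None)
    if t_avg is None:
        t_avg = (t_min + 1.0) if t_min is not None else np.full(n_days, 5.0)
    if t_min is None:
        t_min = t_avg - 1.0
    if t_max is None:
        t_max = t_avg + 1.0
    start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(
        days=start_doy - 1)
    dates = pd.date_range(start, periods=n_days, freq="D")
    df = pd.DataFrame({
        "date": dates, "t_min": t_min, "t_avg": t_avg, "t_max": t_max,
        "precip": expand(precip, np.zeros(n_days)),
        "snow_score": expand(snow_score, np.zeros(n_days)),
    })
    return validate_weather(df)


@pytest.fixture(scope="session")
def weather_factory():
    return make_weather


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig()


@pytest.fixture(scope="session")
def bundle(default_cfg):
    return simulate_bundle(default_cfg, seed=11)


@pytest.fixture(scope="session")
def tables(bundle):
    return pipeline.run_study(bundle)
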