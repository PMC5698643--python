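"""Weather adjustment, onset dates and window means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from grousepheno.weather import (MissingDataError, PhenologyConfig,
                                 WindowSpec, adjust_lapse_rate,
                                 frost_free_date, gdd_accumulate,
                                 gdd_onset_date, monthly_mean, snow_free_date,
                                 weekly_windows, window_mean)
from conftest import make_weather


class TestLapseRate:
    @pytest.mark.parametrize("elev, expected", [(100.0, 9.35), (0.0, 10.0)])
    def test_station_to_site_shift(self, elev, expected):
        wx = make_weather(t_avg=10.0, n_days=3)
        cfg = PhenologyConfig(elevation_diff=elev)
        out = adjust_lapse_rate(wx, cfg)
        assert out["t_avg"].iloc[0] == pytest.approx(expected)

    def test_shift_preserves_ordering_and_other_columns(self):
        wx = make_weather(t_min=0.0, t_avg=5.0, t_max=10.0, precip=2.0,
                          snow_score=3, n_days=4)
        out = adjust_lapse_rate(wx, PhenologyConfig(elevation_diff=200.0))
        assert out["t_min"].iloc[0] == pytest.approx(-1.3)
        assert out["t_avg"].iloc[0] == pytest.approx(3.7)
        assert out["t_max"].iloc[0] == pytest.approx(8.7)
        assert (out["t_min"] <= out["t_avg"]).all()
        assert (out["t_avg"] <= out["t_max"]).all()
        pd.testing.assert_series_equal(out["precip"], wx["precip"])
        pd.testing.assert_series_equal(out["snow_score"], wx["snow_score"])

    @given(elev=st.floats(-500, 500), temp=st.floats(-30, 30))
    def test_up_then_down_is_identity(self, elev, temp):
        wx = make_weather(t_avg=temp, n_days=2)
        up = adjust_lapse_rate(wx, PhenologyConfig(elevation_diff=elev))
        back = adjust_lapse_rate(up, PhenologyConfig(elevation_diff=-elev))
        np.testing.assert_allclose(back["t_avg"], wx["t_avg"], atol=1e-9)


class TestFrostFree:
    def test_never_crossing_is_missing(self):
        wx = make_weather(t_min=np.full(181, -1.0))
        assert frost_free_date(wx, 2000) is None

    def test_linear_ramp_crosses_at_first_positive_mean(self):
        days = np.arange(1, 182)
        wx = make_weather(t_min=0.2 * (days - 100))
        # centred 7-day mean at day d equals the ramp value at d: first > 0 at 101
        assert frost_free_date(wx, 2000) == 101

    def test_warm_from_january_returns_first_computable_center(self):
        wx = make_weather(t_min=np.full(30, 3.0))
        assert frost_free_date(wx, 2000) == 4

    def test_gap_in_coverage_raises(self):
        wx = make_weather(t_min=np.full(60, 3.0))
        gappy = pd.concat([wx.iloc[:20], wx.iloc[25:]])
        with pytest.raises(MissingDataError):
            frost_free_date(gappy, 2000)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_warming_never_delays_the_date(self, seed):
        rng = np.random.default_rng(seed)
        days = np.arange(1, 185)
        t = 0.1 * (days - 90) + rng.normal(0, 2, days.size)
        base = frost_free_date(make_weather(t_min=t), 2000)
        warm = frost_free_date(make_weather(t_min=t + 1.5), 2000)
        assert base is not None and warm is not None
        assert warm <= base


class TestSnowFree:
    def test_first_zero_score(self):
        wx = make_weather(start_doy=90, snow_score=[5, 3, 1, 0, 0], n_days=5)
        assert snow_free_date(wx, 2000) == 93

    def test_all_zero_gives_first_day(self):
        wx = make_weather(start_doy=50, snow_score=0, n_days=5)
        assert snow_free_date(wx, 2000) == 50

    def test_first_occurrence_even_if_snow_returns(self):
        wx = make_weather(start_doy=90, snow_score=[1, 0, 2, 0], n_days=4)
        assert snow_free_date(wx, 2000) == 91

    def test_never_melting_is_missing(self):
        wx = make_weather(snow_score=4, n_days=200)
        assert snow_free_date(wx, 2000) is None

    def test_all_scores_missing_raises(self):
        wx = make_weather(snow_score=0, n_days=10)
        wx["snow_score"] = np.nan
        with pytest.raises(MissingDataError):
            snow_free_date(wx, 2000)


class TestGdd:
    def test_constant_excess_reaches_threshold(self):
        wx = make_weather(t_avg=15.0, n_days=40)
        cum = gdd_accumulate(wx, 2000)
        assert cum.loc[1] == pytest.approx(10.0)
        assert gdd_onset_date(wx, 2000) == 20

    def test_base_temperature_clamps_to_zero(self):
        wx = make_weather(t_avg=5.0, n_days=50)
        assert (gdd_accumulate(wx, 2000) == 0).all()
        assert gdd_onset_date(wx, 2000) is None

    def test_alternating_days_hand_sum(self):
        t = np.tile([0.0, 20.0], 20)
        cum = gdd_accumulate(make_weather(t_avg=t), 2000)
        for k in range(1, 21):
            assert cum.loc[2 * k] == pytest.approx(15.0 * k)

    def test_degenerate_threshold_hits_first_accumulation_day(self):
        wx = make_weather(t_avg=15.0, n_days=10)
        cfg = PhenologyConfig(gdd_threshold=1e-12)
        assert gdd_onset_date(wx, 2000, cfg) == 1

    def test_missing_day_raises(self):
        wx = make_weather(t_avg=15.0, n_days=30)
        wx.loc[10, "t_avg"] = np.nan
        with pytest.raises(MissingDataError):
            gdd_accumulate(wx, 2000)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(8.0, 6.0, 250)
        wx = make_weather(t_avg=t)
        cum, onset = 0.0, None
        for day, temp in enumerate(t, start=1):
            cum += max(temp - 5.0, 0.0)
            if onset is None and cum >= 200.0:
                onset = day
        assert gdd_onset_date(wx, 2000) == onset
        assert (np.diff(gdd_accumulate(wx, 2000).to_numpy()) >= 0).all()


class TestWindowMean:
    def test_constant_series(self):
        wx = make_weather(t_min=7.0, n_days=120)
        assert window_mean(wx, 2000, 30, 59, "min") == pytest.approx(7.0)

    def test_linear_april_midpoint(self):
        t = np.full(200, 0.0)
        t[91:121] = np.linspace(0.0, 2.9, 30)  # April of a leap year: doy 92-121
        wx = make_weather(year=2000, t_min=t)
        assert monthly_mean(wx, 2000, 4, "min") == pytest.approx(1.45)

    def test_weekly_windows_tile_the_season(self):
        rng = np.random.default_rng(3)
        wx = make_weather(year=2001, t_avg=rng.normal(8, 4, 200))
        wins = weekly_windows(2001)
        assert len(wins) == 13
        means = [window_mean(wx, 2001, *w.resolve(), which="avg")
                 for w in wins]
        start, end = wins[0].resolve()[0], wins[-1].resolve()[1]
        assert end - start + 1 == 91
        global_mean = window_mean(wx, 2001, start, end, "avg")
        assert np.mean(means) == pytest.approx(global_mean)

    def test_missing_days_raise_with_gap_count(self):
        wx = make_weather(t_min=1.0, n_days=50)
        wx.loc[20:22, "t_min"] = np.nan
        with pytest.raises(MissingDataError, match="3 missing"):
            window_mean(wx, 2000, 10, 40, "min")

    @given(start=st.integers(1, 150), length=st.integers(1, 40),
           seed=st.integers(0, 100))
    def test_equals_bruteforce_average(self, start, length, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(0, 5, 200)
        wx = make_weather(t_avg=t)
        got = window_mean(wx, 2000, start, start + length - 1, "avg")
        expected = sum(t[start - 1:start + length - 1]) / length
        assert got == pytest.approx(expected)


class TestWindowSpec:
    def test_fixed_and_anchored_resolution(self):
        assert WindowSpec("a", 7, start_doy=91).resolve() == (91, 97)
        w = WindowSpec("b", 28, anchor="hatch", start_offset=-28)
        assert w.resolve({"hatch": 156}) == (128, 155)

    def test_requires_exactly_one_anchor_mode(self):
        with pytest.raises(ValueError):
            WindowSpec("bad", 7)
        with pytest.raises(ValueError):
            WindowSpec("bad", 7, start_doy=1, anchor="hatch")
        with pytest.raises(KeyError):
            WindowSpec("b", 7, anchor="hatch").resolve({})
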