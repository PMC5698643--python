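"""Daily weather series and derived phenological onset statistics.

A single meteorological station provides daily minimum / average / maximum
temperature (°C), precipitation (mm) and an ordinal snow-cover score (0–5).
Station temperatures are transferred to the study site with a fixed lapse
rate.  From the adjusted series three onset-of-season indicators are derived
per calendar year:

* **snow-free date** — earliest day the snow score drops to 0 (< 20 % cover);
* **frost-free date** — first day the centred 7-day moving average of the
  daily minimum temperature exceeds 0 °C;
* **GDD onset** — first day the growing-degree-day sum (base 5 °C,
  accumulated from 1 January) reaches 200, marking the "onset of summer"
  (completed bilberry shoot growth in boreal forest).

Arbitrary temperature windows (monthly means, weekly bins, breeding-season
windows anchored on hatch dates) are averaged with a strict no-gap policy:
a window mean fails loudly if any day inside it is missing.
"""

from __future__ import annotations

import calendar
import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

WEATHER_COLUMNS = ("date", "t_min", "t_avg", "t_max", "precip", "snow_score")

#: last day scanned for spring onsets (30 June of a non-leap year)
_SCAN_END_MONTH_DAY = (6, 30)


class MissingDataError(ValueError):
    """An operation needed daily records that are absent or NaN."""


@dataclass(frozen=True)
class PhenologyConfig:
    """Parameters of the station-to-site adjustment and onset definitions.

    lapse_rate      °C change per 100 m of elevation.
    elevation_diff  site minus station elevation in metres (positive when the
                    study site lies above the station; temperatures are then
                    shifted downwards).
    gdd_base        base temperature for degree-day accumulation (°C).
    gdd_threshold   cumulative degree-days defining the onset of summer.
    ma_window       moving-average width (days, odd) for the frost-free date.
    snow_free_score largest snow score still counted as snow-free.
    gdd_start_doy   day-of-year accumulation begins (1 = 1 January).
    """

    lapse_rate: float = 0.65
    elevation_diff: float = 0.0
    gdd_base: float = 5.0
    gdd_threshold: float = 200.0
    ma_window: int = 7
    snow_free_score: int = 0
    gdd_start_doy: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.elevation_diff):
            raise ValueError("elevation_diff must be finite")
        if self.lapse_rate < 0:
            raise ValueError("lapse_rate must be >= 0")
        if self.gdd_threshold <= 0:
            raise ValueError("gdd_threshold must be > 0")
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be odd and >= 1")


@dataclass(frozen=True)
class WindowSpec:
    """A labelled run of consecutive days, fixed or anchored on a named date.

    Either ``start_doy`` is given directly (fixed calendar window) or
    ``anchor`` names a phenology/breeding date that is resolved at use time;
    ``start_offset`` days are then added to the anchor. The window covers
    ``length`` days, both ends inclusive.
    """

    label: str
    length: int
    start_doy: int | None = None
    anchor: str | None = None
    start_offset: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("window length must be >= 1")
        if (self.start_doy is None) == (self.anchor is None):
            raise ValueError("give exactly one of start_doy or anchor")

    def resolve(self, anchors: Mapping[str, float] | None = None) -> tuple[int, int]:
        """Return the closed (start_doy, end_doy) range of this window."""
        if self.start_doy is not None:
            start = int(self.start_doy) + self.start_offset
        else:
            if anchors is None or self.anchor not in anchors:
                raise KeyError(f"anchor {self.anchor!r} not supplied")
            start = int(round(anchors[self.anchor])) + self.start_offset
        return start, start + self.length - 1


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw weather frame and return a normalised copy.

    Checks column presence, strictly increasing unique dates, the
    t_min <= t_avg <= t_max ordering wherever all three are present,
    non-negative precipitation and snow scores in {0..5} (or missing).
    Adds integer ``year`` and ``doy`` convenience columns.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather frame lacks columns: {missing}")
    out = df.loc[:, list(WEATHER_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"])
    if not out["date"].is_monotonic_increasing or out["date"].duplicated().any():
        raise ValueError("dates must be strictly increasing without duplicates")
    temps = out[["t_min", "t_avg", "t_max"]].to_numpy(dtype=float)
    full = ~np.isnan(temps).any(axis=1)
    if full.any():
        t = temps[full]
        if not ((t[:, 0] <= t[:, 1] + 1e-9) & (t[:, 1] <= t[:, 2] + 1e-9)).all():
            raise ValueError("t_min <= t_avg <= t_max violated")
    precip = out["precip"].to_numpy(dtype=float)
    if np.nanmin(precip, initial=0.0) < 0:
        raise ValueError("precipitation must be non-negative")
    snow = out["snow_score"].to_numpy(dtype=float)
    ok = np.isnan(snow) | (np.isin(snow, np.arange(6)))
    if not ok.all():
        raise ValueError("snow_score must be in {0..5} or missing")
    out["year"] = out["date"].dt.year.astype(int)
    out["doy"] = out["date"].dt.dayofyear.astype(int)
    return out


def load_weather(path) -> pd.DataFrame:
    """Read a weather CSV (`date,t_min,t_avg,t_max,precip,snow_score`)."""
    return validate_weather(pd.read_csv(path))


def adjust_lapse_rate(df: pd.DataFrame, cfg: PhenologyConfig) -> pd.DataFrame:
    """Transfer station temperatures to the site elevation.

    Each temperature column is shifted by ``-lapse_rate * elevation_diff/100``
    (cooler when the site lies above the station); precipitation and snow are
    untouched and row order is preserved.
    """
    shift = -cfg.lapse_rate * cfg.elevation_diff / 100.0
    out = df.copy()
    for col in ("t_min", "t_avg", "t_max"):
        out[col] = out[col] + shift
    return out


def _year_scan_end(year: int) -> int:
    m, d = _SCAN_END_MONTH_DAY
    return pd.Timestamp(year=year, month=m, day=d).dayofyear


def _contiguous_year_values(df: pd.DataFrame, year: int, column: str,
                            max_doy: int | None = None) -> tuple[np.ndarray, int]:
    """Return (values, first_doy) for one year, demanding gap-free coverage."""
    sub = df.loc[df["year"] == year]
    if max_doy is not None:
        sub = sub.loc[sub["doy"] <= max_doy]
    if sub.empty:
        raise MissingDataError(f"no records for year {year}")
    doys = sub["doy"].to_numpy()
    if not (np.diff(doys) == 1).all():
        raise MissingDataError(f"gap in daily coverage for year {year}")
    vals = sub[column].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise MissingDataError(
            f"{int(np.isnan(vals).sum())} missing {column} values in year {year}")
    return vals, int(doys[0])


def _frost_free_from_values(t_min: np.ndarray, first_doy: int,
                            ma_window: int, scan_end: int) -> int | None:
    half = ma_window // 2
    if t_min.size < ma_window:
        return None
    kernel = np.full(ma_window, 1.0 / ma_window)
    means = np.convolve(t_min, kernel, mode="valid")
    centers = np.arange(first_doy + half, first_doy + half + means.size)
    keep = centers <= scan_end
    means, centers = means[keep], centers[keep]
    pos = np.nonzero(means > 0)[0]
    if pos.size == 0:
        return None
    return int(centers[pos[0]])


def frost_free_date(df: pd.DataFrame, year: int,
                    cfg: PhenologyConfig | None = None) -> int | None:
    """Day-of-year the centred ``ma_window``-day mean of t_min first exceeds 0 °C.

    Scans 1 January – 30 June; returns ``None`` if the smoothed minimum never
    turns positive by then. A gap (or NaN) inside the scanned coverage raises
    :class:`MissingDataError`.
    """
    cfg = cfg or PhenologyConfig()
    scan_end = _year_scan_end(year)
    vals, first = _contiguous_year_values(df, year, "t_min",
                                          max_doy=scan_end + cfg.ma_window // 2)
    return _frost_free_from_values(vals, first, cfg.ma_window, scan_end)


def snow_free_date(df: pd.DataFrame, year: int,
                   cfg: PhenologyConfig | None = None) -> int | None:
    """Earliest day-of-year (Jan–Jun) with snow score <= ``snow_free_score``.

    The first occurrence counts even if snow returns later. Raises
    :class:`MissingDataError` when every score in the scanned season is
    missing; returns ``None`` when scores are present but never drop.
    """
    cfg = cfg or PhenologyConfig()
    scan_end = _year_scan_end(year)
    sub = df.loc[(df["year"] == year) & (df["doy"] <= scan_end)]
    if sub.empty:
        raise MissingDataError(f"no records for year {year}")
    scores = sub["snow_score"].to_numpy(dtype=float)
    if np.isnan(scores).all():
        raise MissingDataError(f"all snow scores missing in year {year}")
    hit = np.nonzero(scores <= cfg.snow_free_score)[0]
    if hit.size == 0:
        return None
    return int(sub["doy"].to_numpy()[hit[0]])


def gdd_accumulate(df: pd.DataFrame, year: int,
                   cfg: PhenologyConfig | None = None) -> pd.Series:
    """Cumulative growing degree days per day of one year.

    Sums ``max(t_avg - gdd_base, 0)`` from ``gdd_start_doy`` onward; the
    result is indexed by day-of-year and non-decreasing by construction.
    """
    cfg = cfg or PhenologyConfig()
    vals, first = _contiguous_year_values(df, year, "t_avg")
    if first > cfg.gdd_start_doy:
        raise MissingDataError(
            f"coverage for year {year} starts at doy {first}, "
            f"after gdd_start_doy {cfg.gdd_start_doy}")
    vals = vals[cfg.gdd_start_doy - first:]
    doys = np.arange(cfg.gdd_start_doy, cfg.gdd_start_doy + vals.size)
    cum = np.cumsum(np.maximum(vals - cfg.gdd_base, 0.0))
    return pd.Series(cum, index=doys, name="gdd")


def gdd_onset_date(df: pd.DataFrame, year: int,
                   cfg: PhenologyConfig | None = None) -> int | None:
    """First day-of-year the GDD sum reaches ``gdd_threshold`` (None if never)."""
    cfg = cfg or PhenologyConfig()
    cum = gdd_accumulate(df, year, cfg)
    hit = np.nonzero(cum.to_numpy() >= cfg.gdd_threshold)[0]
    if hit.size == 0:
        return None
    return int(cum.index[hit[0]])


_WHICH_COLUMN = {"min": "t_min", "avg": "t_avg", "max": "t_max"}


def window_mean(df: pd.DataFrame, year: int, start_doy: int, end_doy: int,
                which: str = "min") -> float:
    """Mean of a daily temperature over the closed day range [start, end].

    Every day in the range must be present and non-missing, otherwise a
    :class:`MissingDataError` reporting the number of gaps is raised.
    """
    if which not in _WHICH_COLUMN:
        raise ValueError(f"which must be one of {sorted(_WHICH_COLUMN)}")
    if end_doy < start_doy:
        raise ValueError("end_doy must be >= start_doy")
    sub = df.loc[(df["year"] == year) & (df["doy"] >= start_doy)
                 & (df["doy"] <= end_doy)]
    vals = sub[_WHICH_COLUMN[which]].to_numpy(dtype=float)
    n_expected = end_doy - start_doy + 1
    n_gaps = n_expected - int(np.isfinite(vals).sum())
    if n_gaps > 0:
        raise MissingDataError(
            f"{n_gaps} missing day(s) in window [{start_doy}, {end_doy}] "
            f"of year {year}")
    return float(vals.mean())


def month_window(year: int, month: int) -> tuple[int, int]:
    """Closed day-of-year range spanned by a calendar month."""
    start = pd.Timestamp(year=year, month=month, day=1).dayofyear
    return start, start + calendar.monthrange(year, month)[1] - 1


def monthly_mean(df: pd.DataFrame, year: int, month: int,
                 which: str = "min") -> float:
    """Mean daily temperature over one calendar month."""
    start, end = month_window(year, month)
    return window_mean(df, year, start, end, which)


def weekly_windows(year: int, n: int = 13) -> list[WindowSpec]:
    """The breeding-season bins: ``n`` consecutive 7-day windows from 1 April.

    Thirteen weekly bins tile 1 April – 30 June (91 days) exactly.
    """
    start = pd.Timestamp(year=year, month=4, day=1).dayofyear
    return [WindowSpec(label=f"week{i + 1:02d}", length=7,
                       start_doy=start + 7 * i) for i in range(n)]


def phenology_table(df: pd.DataFrame,
                    cfg: PhenologyConfig | None = None) -> pd.DataFrame:
    """Per-year derived onset dates for every year present in the series.

    Returns columns ``year, snow_free_doy, frost_free_doy, gdd200_doy``;
    a date that cannot be computed for a year (never crossed, or missing
    underlying data) is NaN.
    """
    cfg = cfg or PhenologyConfig()
    rows = []
    for year in sorted(df["year"].unique()):
        row: dict[str, float] = {"year": int(year)}
        for name, fn in (("snow_free_doy", snow_free_date),
                         ("frost_free_doy", frost_free_date),
                         ("gdd200_doy", gdd_onset_date)):
            try:
                val = fn(df, year, cfg)
            except MissingDataError:
                val = None
            row[name] = np.nan if val is None else float(val)
        rows.append(row)
    return pd.DataFrame(rows)
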