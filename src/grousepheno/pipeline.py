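"""End-to-end study pipeline: inputs -> tables -> regression battery.

Chains the stages (weather phenology, breeding windows, survey indices,
trend/response/partial regressions, mismatch analysis) on a consistent
input bundle, in memory.  This is what the command line, the acceptance
script and the replicated recovery studies all call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import breeding as breeding_mod
from . import mismatch as mismatch_mod
from . import surveys as surveys_mod
from . import trends as trends_mod
from . import weather as weather_mod
from .breeding import BLACK_GROUSE, CAPERCAILLIE, WINDOW_LABELS

METRICS = ("breeding_success", "brood_frequency", "brood_size")


@dataclass
class StudyTables:
    """Intermediate products of one pipeline run."""

    phenology: pd.DataFrame      # year, snow_free_doy, frost_free_doy, gdd200_doy
    breeding: pd.DataFrame       # per species-year breeding dates
    indices: pd.DataFrame        # per species-year demographic indices
    window_temps: pd.DataFrame   # year, species, window, t_mean
    covariates: pd.DataFrame     # year, rodent_index, fox_index


def phenology_dates(weather: pd.DataFrame,
                    cfg: weather_mod.PhenologyConfig | None = None
                    ) -> pd.DataFrame:
    """Per-year onset dates, one grouped pass over the daily series."""
    cfg = cfg or weather_mod.PhenologyConfig()
    rows = []
    for year, sub in weather.groupby("year"):
        year = int(year)
        doy = sub["doy"].to_numpy()
        scan_end = pd.Timestamp(year=year, month=6, day=30).dayofyear
        row: dict[str, float] = {"year": year, "snow_free_doy": np.nan,
                                 "frost_free_doy": np.nan,
                                 "gdd200_doy": np.nan}
        spring = sub.loc[sub["doy"] <= scan_end]
        scores = spring["snow_score"].to_numpy(dtype=float)
        hit = np.nonzero(scores <= cfg.snow_free_score)[0]
        if hit.size:
            row["snow_free_doy"] = float(spring["doy"].to_numpy()[hit[0]])
        t_min = sub["t_min"].to_numpy(dtype=float)
        contiguous = (np.diff(doy) == 1).all() and not np.isnan(t_min).any()
        if contiguous:
            ff = weather_mod._frost_free_from_values(
                t_min, int(doy[0]), cfg.ma_window, scan_end)
            if ff is not None:
                row["frost_free_doy"] = float(ff)
            t_avg = sub["t_avg"].to_numpy(dtype=float)
            if not np.isnan(t_avg).any() and doy[0] <= cfg.gdd_start_doy:
                skip = cfg.gdd_start_doy - int(doy[0])
                cum = np.cumsum(np.maximum(t_avg[skip:] - cfg.gdd_base, 0.0))
                reach = np.nonzero(cum >= cfg.gdd_threshold)[0]
                if reach.size:
                    row["gdd200_doy"] = float(doy[skip:][reach[0]])
        rows.append(row)
    return pd.DataFrame(rows)


def window_temperature_table(weather: pd.DataFrame,
                             breeding_table: pd.DataFrame,
                             which: str = "min") -> pd.DataFrame:
    """Mean temperature in each breeding window per species-year (long form)."""
    col = {"min": "t_min", "avg": "t_avg", "max": "t_max"}[which]
    by_year = _doy_arrays(weather, col)
    rows = []
    for rec in breeding_table.itertuples(index=False):
        ph = breeding_mod.BreedingPhenology(
            year=int(rec.year), species=rec.species,
            mating_doy=float(rec.mating_doy),
            incubation_start_doy=float(rec.incubation_start_doy),
            hatch_doy=float(rec.hatch_doy))
        arr = by_year.get(ph.year)
        for label, (start, end) in breeding_mod.build_windows(ph).items():
            t = _window_mean_from_array(arr, start, end)
            rows.append({"year": ph.year, "species": ph.species,
                         "window": label, "t_mean": t})
    return pd.DataFrame(rows)


def _doy_arrays(weather: pd.DataFrame, column: str) -> dict[int, np.ndarray]:
    """Per-year value arrays indexed directly by day-of-year (slot 0 unused)."""
    out = {}
    for year, sub in weather.groupby("year"):
        arr = np.full(367, np.nan)
        arr[sub["doy"].to_numpy()] = sub[column].to_numpy(dtype=float)
        out[int(year)] = arr
    return out


def _window_mean_from_array(arr: np.ndarray | None, start: int,
                            end: int) -> float:
    if arr is None or start < 1 or end >= arr.size:
        return np.nan
    vals = arr[start:end + 1]
    if np.isnan(vals).any():
        return np.nan
    return float(vals.mean())


def run_study(bundle, phen_cfg: weather_mod.PhenologyConfig | None = None,
              offsets: breeding_mod.SpeciesOffsets | None = None
              ) -> StudyTables:
    """All intermediate tables from one input bundle."""
    phen = phenology_dates(bundle.weather, phen_cfg)
    breeding_table = breeding_mod.phenology_table(bundle.mating, offsets)
    indices = surveys_mod.annual_table(bundle.survey)
    wtemps = window_temperature_table(bundle.weather, breeding_table)
    return StudyTables(phenology=phen, breeding=breeding_table,
                       indices=indices, window_temps=wtemps,
                       covariates=bundle.covariates)


def _metric_window_frame(tables: StudyTables, species: str, metric: str,
                         window: str) -> pd.DataFrame:
    idx = tables.indices.loc[tables.indices["species"] == species,
                             ["year", metric]]
    wt = tables.window_temps.loc[
        (tables.window_temps["species"] == species)
        & (tables.window_temps["window"] == window), ["year", "t_mean"]]
    merged = idx.merge(wt, on="year").merge(tables.covariates, on="year",
                                            how="left")
    return merged.dropna(subset=[metric, "t_mean"])


def response_battery(tables: StudyTables,
                     metrics: tuple[str, ...] = METRICS,
                     windows: tuple[str, ...] = WINDOW_LABELS) -> pd.DataFrame:
    """Temperature-response and partial regressions per species/metric/window.

    For every metric and breeding window: the simple OLS of the annual
    metric on the window's minimum-temperature mean, the partial regression
    controlling for sqrt-rodents and log-fox, and (attached to both species'
    rows) the interspecific slope-difference test.
    """
    rows = []
    for metric in metrics:
        for window in windows:
            fits = {}
            for species in (CAPERCAILLIE, BLACK_GROUSE):
                sub = _metric_window_frame(tables, species, metric, window)
                fit = trends_mod.temp_response(sub["t_mean"], sub[metric],
                                               variable=f"{metric}~{window}")
                try:
                    part = trends_mod.partial_regression(
                        sub[metric], sub["t_mean"], sub["rodent_index"],
                        sub["fox_index"], response=metric)
                    part_vals = (part.beta_p, part.r_p, part.p)
                except ValueError:
                    part_vals = (np.nan, np.nan, np.nan)
                fits[species] = fit
                rows.append({"response": metric, "window": window,
                             "species": species, "n": fit.n,
                             "beta": fit.beta, "r": fit.r, "p": fit.p,
                             "beta_partial": part_vals[0],
                             "r_partial": part_vals[1],
                             "p_partial": part_vals[2]})
            try:
                comp = trends_mod.slope_difference_test(
                    fits[CAPERCAILLIE], fits[BLACK_GROUSE])
                t_val, p_val = comp.t, comp.p
            except ValueError:
                t_val, p_val = np.nan, np.nan
            for row in rows[-2:]:
                row["diff_beta_t"] = t_val
                row["diff_beta_p"] = p_val
    return pd.DataFrame(rows)


def monthly_temperature_trends(weather: pd.DataFrame,
                               months: tuple[int, ...] = (4, 5, 6),
                               span_years: int | None = None) -> pd.DataFrame:
    """Trend-table rows: per month and temperature kind, mean/Δ/β/s.e."""
    years = sorted(weather["year"].unique())
    span = span_years or len(years)
    month_col = weather["date"].dt.month.rename("month")
    rows = []
    for month in months:
        for which in ("min", "avg", "max"):
            col = {"min": "t_min", "avg": "t_avg", "max": "t_max"}[which]
            agg = weather.groupby(["year", month_col])[col].agg(
                ["mean", "count"])
            vals = []
            for year in years:
                start, end = weather_mod.month_window(year, month)
                try:
                    mean, count = agg.loc[(year, month)]
                except KeyError:
                    vals.append(np.nan)
                    continue
                vals.append(float(mean) if count == end - start + 1
                            else np.nan)
            vals = np.asarray(vals)
            fit = trends_mod.ols_trend(years, vals, span_years=span,
                                       variable=f"t_{which}_m{month:02d}")
            ok = np.isfinite(vals)
            rows.append({"month": month, "which": which,
                         "mean": float(np.nanmean(vals)),
                         "se_mean": float(np.nanstd(vals, ddof=1)
                                          / np.sqrt(ok.sum())),
                         "delta": fit.delta, "beta": fit.beta,
                         "se_beta": fit.se, "r": fit.r, "p": fit.p})
    return pd.DataFrame(rows)


def demographic_trends(indices: pd.DataFrame,
                       span_years: int | None = None) -> pd.DataFrame:
    """Year-trend of every demographic metric per species (+ normalized β)."""
    rows = []
    for species, sub in indices.groupby("species"):
        span = span_years or len(sub)
        for metric in METRICS:
            y = sub[metric].to_numpy(dtype=float)
            fit = trends_mod.ols_trend(sub["year"], y, span_years=span,
                                       variable=f"{species}:{metric}")
            try:
                norm = trends_mod.normalized_trend(sub["year"], y, span)
            except ValueError:
                norm = np.nan
            rows.append({"species": species, "metric": metric,
                         "beta": fit.beta, "se": fit.se, "r": fit.r,
                         "p": fit.p, "delta": fit.delta,
                         "normalized_beta": norm, "n": fit.n})
    return pd.DataFrame(rows)


def mismatch_analysis(tables: StudyTables) -> pd.DataFrame:
    """Per-species mismatch offsets and polynomial model selection."""
    points = mismatch_mod.compute_offsets(tables.breeding, tables.phenology,
                                          tables.indices)
    return mismatch_mod.mismatch_table(points)


def single_run_estimates(cfg, seed: int) -> dict:
    """One synthetic study realisation reduced to its headline estimates.

    Simulates a bundle, runs the full pipeline, and returns the estimates a
    replication study tracks: temperature-response slopes (and p-values) of
    brood frequency on pre-incubation minimum temperature and of brood size
    on post-hatch minimum temperature for both species, plus the
    breeding-success response over the 8-week pre-hatch window.
    """
    from .simulate import simulate_bundle

    tables = run_study(simulate_bundle(cfg, seed))
    out: dict[str, float] = {}
    specs = {
        "bf_pre_inc": ("brood_frequency", "pre_inc4"),
        "size_post": ("brood_size", "post4"),
        "bs_pre8": ("breeding_success", "pre8"),
    }
    for species, tag in ((CAPERCAILLIE, "cap"), (BLACK_GROUSE, "bg")):
        for key, (metric, window) in specs.items():
            sub = _metric_window_frame(tables, species, metric, window)
            fit = trends_mod.temp_response(sub["t_mean"], sub[metric])
            out[f"{tag}_{key}_beta"] = fit.beta
            out[f"{tag}_{key}_p"] = fit.p
    return out
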