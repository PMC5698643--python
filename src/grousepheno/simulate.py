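"""Synthetic study system: weather, covariates, breeding phenology, surveys.

Generates the four pipeline inputs of a boreal grouse climate–demography
study with the statistical structure the analysis assumes:

* a daily station temperature series (seasonal sinusoid + month-specific
  linear warming, strongest in April, + AR(1) day-to-day noise), with
  precipitation and an ordinal snow score that melts out in spring;
* annual small-rodent and red-fox indices — a 3–4-year rodent cycle coupled
  to same-year summer temperature, the fox following rodents with a one-year
  lag;
* capercaillie peak-mating dates advancing slowly (≈ −0.12 day/yr) and
  weakly coupled to the frost-free date;
* August pointing-dog survey records in which brood frequency responds to
  pre-incubation minimum temperature (capercaillie only) and to the rodent
  cycle, brood size responds to post-hatch minimum temperature (both
  species), and both channels carry a quadratic penalty for hatching away
  from the GDD₅ = 200 date.

Default effect sizes are the study system's published values where printed
(warming slopes, rodent/fox couplings, mating trend, temperature effects on
the demographic traits); noise levels are calibrated so annual window means
and demographic indices vary from year to year like the field series.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from . import breeding as breeding_mod
from . import weather as weather_mod
from .breeding import BLACK_GROUSE, CAPERCAILLIE, SpeciesOffsets

_DAYS_PER_YEAR = 365.25


def _species_dict(cap: float, bg: float) -> dict[str, float]:
    return {CAPERCAILLIE: cap, BLACK_GROUSE: bg}


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; defaults define the emulated study system.

    Temperature trend slopes are °C per year by calendar month (April, May,
    June from the study's trend table; a modest background slope elsewhere).
    Demographic effects act on link scales: brood frequency through a logit
    (slope 0.21 per °C for capercaillie ≈ 0.049 per °C on the probability
    scale at the baseline frequency), brood size through the success
    probability of a clutch-thinning binomial (slope 0.08 per °C ≈ 0.13
    chicks per °C at the baseline brood size).  The mismatch penalty is a
    quadratic in (hatch − GDD200) days applied on both link scales, sized so
    breeding success loses ≈ 0.3 % per squared day of mismatch.
    """

    n_years: int = 38
    start_year: int = 1979
    # --- daily temperature model ---
    site_mean: float = 4.0            # annual mean t_avg, °C
    seasonal_amplitude: float = 11.5  # °C, sinusoid amplitude
    peak_doy: int = 200               # warmest day of year
    ar_phi: float = 0.6               # AR(1) coefficient of daily noise
    ar_sd: float = 2.7                # innovation s.d., °C
    tavg_month_slopes: dict = field(
        default_factory=lambda: {4: 0.069, 5: 0.019, 6: 0.022})
    tmin_month_slopes: dict = field(
        default_factory=lambda: {4: 0.050, 5: 0.052, 6: 0.047})
    tmax_month_slopes: dict = field(
        default_factory=lambda: {4: 0.101, 5: 0.012, 6: 0.024})
    background_slope: float = 0.03    # °C/yr in months without a stated slope
    tmin_spread: float = 5.0          # mean t_avg − t_min, °C
    tmax_spread: float = 5.6          # mean t_max − t_avg, °C
    spread_sd: float = 0.8
    min_spread: float = 0.5           # floor keeping t_min < t_avg < t_max
    # --- precipitation and snow ---
    wet_prob: float = 0.45
    precip_shape: float = 0.8
    precip_scale: float = 5.0
    snow_smooth_days: int = 15
    # smoothed t_avg thresholds mapping to snow scores 0..5
    snow_thresholds: tuple = ((4.0, 0), (2.5, 1), (1.0, 2), (-1.0, 3), (-3.0, 4))
    # --- annual covariates ---
    rodent_mean: float = 3.0
    rodent_amplitude: float = 2.5
    rodent_period: float = 3.5        # years
    rodent_phase: float = 0.0
    rodent_temp_beta: float = 0.22    # per °C of same-year summer mean
    rodent_sd: float = 0.8
    fox_base: float = 1.0
    fox_rodent_beta: float = 0.078    # per unit of last year's rodent index
    fox_sd: float = 0.25
    # --- breeding phenology ---
    mating_base_doy: float = 118.0    # capercaillie peak mating, first year
    mating_trend: float = -0.12       # day/yr
    mating_onset_coupling: float = 0.10  # days per day of frost-free anomaly
    mating_sd: float = 1.5
    offsets: SpeciesOffsets = field(default_factory=SpeciesOffsets)
    # --- survey / demographic model ---
    n_females_mean: float = 22.0
    n_females_min: int = 5
    n_other_birds_mean: float = 12.0
    n_blocks: int = 25
    effort_min: float = 8.0
    effort_max: float = 15.0
    bf_intercept: dict = field(default_factory=lambda: _species_dict(-0.53, 0.0))
    bf_temp_slope: dict = field(default_factory=lambda: _species_dict(0.21, 0.0))
    bf_rodent_slope: float = 0.25     # per centred sqrt-rodent unit, logit scale
    # mismatch penalties, logit units per squared mismatch day; the egg-stage
    # penalty is a capercaillie feature (black grouse shows none in the field),
    # the chick-stage penalty is mild in both species
    bf_mismatch_curv: dict = field(default_factory=lambda: _species_dict(0.003, 0.0))
    clutch_minus_one: int = 7         # brood size = 1 + Binomial(7, q)
    size_intercept: dict = field(
        default_factory=lambda: _species_dict(-0.405, -0.172))
    size_temp_slope: dict = field(default_factory=lambda: _species_dict(0.08, 0.08))
    size_mismatch_curv: dict = field(
        default_factory=lambda: _species_dict(0.001, 0.001))

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for name in ("ar_sd", "spread_sd", "rodent_sd", "fox_sd", "mating_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ar_phi < 1:
            raise ValueError("ar_phi must be in [0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def null(self) -> "SimulationConfig":
        """Variant with every demographic driver switched off.

        Brood frequency and brood size become pure sampling noise around
        their baselines: no temperature effects, no rodent effect, no
        mismatch penalty.  Weather, covariates and phenology are unchanged.
        """
        return dataclasses.replace(
            self,
            bf_temp_slope=_species_dict(0.0, 0.0),
            size_temp_slope=_species_dict(0.0, 0.0),
            bf_rodent_slope=0.0,
            bf_mismatch_curv=_species_dict(0.0, 0.0),
            size_mismatch_curv=_species_dict(0.0, 0.0))

    def mismatch_emphasis(self) -> "SimulationConfig":
        """Variant with a pronounced chick-survival peak at zero mismatch.

        The entire mismatch penalty is placed on the chick-survival channel
        (brood size) with a strong curvature, and the direct temperature and
        rodent channels are switched off, so breeding success responds to
        nothing but how far hatching sits from the GDD₅ = 200 date.  Used to
        study the polynomial mismatch machinery in isolation.
        """
        return dataclasses.replace(
            self.null(),
            size_mismatch_curv=_species_dict(0.01, 0.01))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "offsets" in data and isinstance(data["offsets"], dict):
            data["offsets"] = SpeciesOffsets(**data["offsets"])
        for key in ("tavg_month_slopes", "tmin_month_slopes",
                    "tmax_month_slopes"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        if "snow_thresholds" in data:
            data["snow_thresholds"] = tuple(
                (float(a), int(b)) for a, b in data["snow_thresholds"])
        return cls(**data)


@dataclass
class Bundle:
    """A complete, mutually consistent set of pipeline inputs."""

    weather: pd.DataFrame
    covariates: pd.DataFrame
    mating: pd.DataFrame
    survey: pd.DataFrame
    manifest: dict


def _month_slope_lookup(slopes: dict, background: float) -> np.ndarray:
    table = np.full(13, background)
    for month, slope in slopes.items():
        table[int(month)] = slope
    return table


def simulate_weather(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    """Daily station weather for the configured span (validated frame)."""
    start = pd.Timestamp(year=cfg.start_year, month=1, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.n_years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    yi = dates.year.to_numpy() - cfg.start_year
    n = dates.size

    seasonal = cfg.site_mean + cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - cfg.peak_doy) / _DAYS_PER_YEAR)
    slope_avg = _month_slope_lookup(cfg.tavg_month_slopes, cfg.background_slope)
    slope_min = _month_slope_lookup(cfg.tmin_month_slopes, cfg.background_slope)
    slope_max = _month_slope_lookup(cfg.tmax_month_slopes, cfg.background_slope)

    eps = rng.normal(0.0, cfg.ar_sd, n) if cfg.ar_sd > 0 else np.zeros(n)
    noise = lfilter([1.0], [1.0, -cfg.ar_phi], eps)
    t_avg = seasonal + slope_avg[month] * yi + noise

    def spread(base: float, slope_self: np.ndarray) -> np.ndarray:
        trend = (slope_avg - slope_self)[month] * yi
        jitter = (rng.normal(0.0, cfg.spread_sd, n)
                  if cfg.spread_sd > 0 else np.zeros(n))
        return np.maximum(cfg.min_spread, base + trend + jitter)

    t_min = t_avg - spread(cfg.tmin_spread, slope_min)
    t_max = t_avg + np.maximum(cfg.min_spread,
                               cfg.tmax_spread
                               + (slope_max - slope_avg)[month] * yi
                               + (rng.normal(0.0, cfg.spread_sd, n)
                                  if cfg.spread_sd > 0 else np.zeros(n)))

    wet = rng.random(n) < cfg.wet_prob
    precip = np.where(wet, rng.gamma(cfg.precip_shape, cfg.precip_scale, n), 0.0)
    precip = np.round(precip, 1)

    smoothed = (pd.Series(t_avg)
                .rolling(cfg.snow_smooth_days, center=True, min_periods=1)
                .mean().to_numpy())
    score = np.full(n, 5, dtype=int)
    for threshold, value in sorted(cfg.snow_thresholds):
        score[smoothed >= threshold] = value

    df = pd.DataFrame({"date": dates, "t_min": t_min, "t_avg": t_avg,
                       "t_max": t_max, "precip": precip,
                       "snow_score": score})
    return weather_mod.validate_weather(df)


def _summer_means(weather: pd.DataFrame) -> pd.Series:
    """Mean daily average temperature June–August per year."""
    summer = weather.loc[weather["date"].dt.month.isin((6, 7, 8))]
    return summer.groupby("year")["t_avg"].mean()


def simulate_covariates(cfg: SimulationConfig, rng: np.random.Generator,
                        weather: pd.DataFrame) -> pd.DataFrame:
    """Annual rodent and fox indices (cycle + summer coupling; lagged fox)."""
    years = cfg.years
    yi = years - cfg.start_year
    summer = _summer_means(weather).reindex(years).to_numpy()
    summer_anom = summer - np.nanmean(summer)
    cycle = cfg.rodent_amplitude * np.sin(
        2 * np.pi * yi / cfg.rodent_period + cfg.rodent_phase)
    noise = (rng.normal(0.0, cfg.rodent_sd, cfg.n_years)
             if cfg.rodent_sd > 0 else np.zeros(cfg.n_years))
    rodent = np.maximum(0.05, cfg.rodent_mean + cycle
                        + cfg.rodent_temp_beta * summer_anom + noise)
    lagged = np.concatenate([[cfg.rodent_mean], rodent[:-1]])
    fox_noise = (rng.normal(0.0, cfg.fox_sd, cfg.n_years)
                 if cfg.fox_sd > 0 else np.zeros(cfg.n_years))
    fox = np.maximum(0.05, cfg.fox_base + cfg.fox_rodent_beta * lagged
                     + fox_noise)
    return pd.DataFrame({"year": years, "rodent_index": rodent,
                         "fox_index": fox})


def _frost_free_by_year(cfg: SimulationConfig,
                        weather: pd.DataFrame) -> pd.Series:
    vals = {}
    for year, sub in weather.groupby("year"):
        t_min = sub["t_min"].to_numpy(dtype=float)
        scan_end = pd.Timestamp(year=int(year), month=6, day=30).dayofyear
        d = weather_mod._frost_free_from_values(t_min, int(sub["doy"].iloc[0]),
                                                7, scan_end)
        vals[int(year)] = np.nan if d is None else float(d)
    return pd.Series(vals).reindex(cfg.years)


def simulate_mating_dates(cfg: SimulationConfig, rng: np.random.Generator,
                          weather: pd.DataFrame) -> pd.DataFrame:
    """Observed capercaillie peak-mating dates (slow advance + spring coupling)."""
    yi = cfg.years - cfg.start_year
    frost = _frost_free_by_year(cfg, weather)
    anom = frost.to_numpy() - np.nanmean(frost.to_numpy())
    anom = np.where(np.isfinite(anom), anom, 0.0)
    noise = (rng.normal(0.0, cfg.mating_sd, cfg.n_years)
             if cfg.mating_sd > 0 else np.zeros(cfg.n_years))
    mating = (cfg.mating_base_doy + cfg.mating_trend * yi
              + cfg.mating_onset_coupling * anom + noise)
    return pd.DataFrame({"year": cfg.years,
                         "species": CAPERCAILLIE,
                         "mating_doy": np.round(mating).astype(int)})


def _gdd200_by_year(cfg: SimulationConfig, weather: pd.DataFrame) -> pd.Series:
    vals = {}
    for year, sub in weather.groupby("year"):
        cum = np.cumsum(np.maximum(sub["t_avg"].to_numpy(dtype=float) - 5.0, 0.0))
        hit = np.nonzero(cum >= 200.0)[0]
        doy = sub["doy"].to_numpy()
        vals[int(year)] = np.nan if hit.size == 0 else float(doy[hit[0]])
    return pd.Series(vals).reindex(cfg.years)


def simulate_breeding(cfg: SimulationConfig, rng: np.random.Generator,
                      weather: pd.DataFrame, covariates: pd.DataFrame,
                      mating: pd.DataFrame) -> pd.DataFrame:
    """August survey records implied by weather, covariates and phenology.

    Per species-year the number of observed females is Poisson, each female
    broods with a logit-linear probability (pre-incubation minimum
    temperature, centred sqrt-rodent index, mismatch penalty) and each brood
    holds ``1 + Binomial(clutch-1, q)`` chicks with logit-linear ``q``
    (post-hatch minimum temperature, mismatch penalty).  Observations are
    scattered over survey blocks with uniform effort.
    """
    from .pipeline import _doy_arrays, _window_mean_from_array

    table = breeding_mod.phenology_table(mating, cfg.offsets)
    gdd200 = _gdd200_by_year(cfg, weather)
    tmin_by_year = _doy_arrays(weather, "t_min")
    rodent = covariates.set_index("year")["rodent_index"]
    sqrt_rod = np.sqrt(rodent.reindex(cfg.years).to_numpy())
    sqrt_rod_c = sqrt_rod - np.nanmean(sqrt_rod)

    rows = []
    for species in (CAPERCAILLIE, BLACK_GROUSE):
        sub = table.loc[table["species"] == species].set_index("year")
        t_pre, t_post, off2 = {}, {}, {}
        for year in cfg.years:
            ph = breeding_mod.BreedingPhenology(
                year=int(year), species=species,
                mating_doy=float(sub.loc[year, "mating_doy"]),
                incubation_start_doy=float(sub.loc[year, "incubation_start_doy"]),
                hatch_doy=float(sub.loc[year, "hatch_doy"]))
            win = breeding_mod.build_windows(ph)
            tm = tmin_by_year[int(year)]
            t_pre[year] = _window_mean_from_array(tm, *win["pre_inc4"])
            t_post[year] = _window_mean_from_array(tm, *win["post4"])
            g = gdd200.loc[year]
            off2[year] = (ph.hatch_doy - g) ** 2 if np.isfinite(g) else 0.0
        pre = np.array([t_pre[y] for y in cfg.years])
        post = np.array([t_post[y] for y in cfg.years])
        pre_c = pre - pre.mean()
        post_c = post - post.mean()
        off2_arr = np.array([off2[y] for y in cfg.years])

        p_brood = expit(cfg.bf_intercept[species]
                        + cfg.bf_temp_slope[species] * pre_c
                        + cfg.bf_rodent_slope * sqrt_rod_c
                        - cfg.bf_mismatch_curv[species] * off2_arr)
        q_chick = expit(cfg.size_intercept[species]
                        + cfg.size_temp_slope[species] * post_c
                        - cfg.size_mismatch_curv[species] * off2_arr)

        for k, year in enumerate(cfg.years):
            n_f = max(cfg.n_females_min, int(rng.poisson(cfg.n_females_mean)))
            n_broods = int(rng.binomial(n_f, p_brood[k]))
            sizes = 1 + rng.binomial(cfg.clutch_minus_one, q_chick[k], n_broods)
            lone = n_f - n_broods
            other = int(rng.poisson(cfg.n_other_birds_mean))
            hours = rng.uniform(cfg.effort_min, cfg.effort_max, cfg.n_blocks)
            lone_split = rng.multinomial(lone, np.full(cfg.n_blocks,
                                                       1.0 / cfg.n_blocks))
            other_split = rng.multinomial(other, np.full(cfg.n_blocks,
                                                         1.0 / cfg.n_blocks))
            brood_block = rng.integers(0, cfg.n_blocks, n_broods)
            for b in range(cfg.n_blocks):
                chicks = sizes[brood_block == b]
                rows.append({
                    "year": int(year), "species": species,
                    "block": f"B{b + 1:02d}",
                    "hours": round(float(hours[b]), 1),
                    "females_no_brood": int(lone_split[b]),
                    "brood_chicks": ";".join(str(int(c)) for c in chicks),
                    "other_birds": int(other_split[b]),
                })
    return pd.DataFrame(rows)


def simulate_bundle(cfg: SimulationConfig, seed: int) -> Bundle:
    """Generate the full, mutually consistent input bundle from one seed."""
    rng = np.random.default_rng(seed)
    weather = simulate_weather(cfg, rng)
    covariates = simulate_covariates(cfg, rng, weather)
    mating = simulate_mating_dates(cfg, rng, weather)
    survey = simulate_breeding(cfg, rng, weather, covariates, mating)
    manifest = {"generator": "grousepheno.simulate", "seed": int(seed),
                "config": cfg.to_dict()}
    return Bundle(weather=weather, covariates=covariates, mating=mating,
                  survey=survey, manifest=manifest)


def make_fixture(cfg: SimulationConfig, seed: int, outdir) -> Path:
    """Write weather/covariates/mating/survey CSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(cfg, seed)
    weather_out = bundle.weather.drop(columns=["year", "doy"]).copy()
    weather_out["date"] = weather_out["date"].dt.strftime("%Y-%m-%d")
    weather_out.to_csv(outdir / "weather.csv", index=False)
    bundle.covariates.to_csv(outdir / "covariates.csv", index=False)
    bundle.mating.to_csv(outdir / "mating.csv", index=False)
    bundle.survey.to_csv(outdir / "survey.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    return outdir


def load_bundle(indir) -> Bundle:
    """Read back a fixture directory written by :func:`make_fixture`."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    from .surveys import load_survey
    return Bundle(
        weather=weather_mod.load_weather(indir / "weather.csv"),
        covariates=pd.read_csv(indir / "covariates.csv"),
        mating=pd.read_csv(indir / "mating.csv"),
        survey=load_survey(indir / "survey.csv"),
        manifest=manifest)
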