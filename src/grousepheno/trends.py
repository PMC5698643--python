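"""Trend and regression battery for annual ecological series.

Implements the statistical toolkit the study design calls for: OLS trends
on calendar year with total-change conversion (Δ = β × span), an AIC
comparison of the year-trend model under independent vs AR(1) vs AR(2)
errors, normalized (relative) trends, log-ratio trends and slope-difference
tests for interspecific comparisons, temperature-response regressions,
partial regressions controlling for rodent and fox abundances, and
lagged summer-temperature checks.

Right-skewed covariates follow the conventional transforms (square-root
rodents, natural-log fox); p-values are two-sided throughout and no
multiple-testing correction is applied — the battery reports each test as
the field convention prints it, so treat marginal p-values accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: full study-period length in years used for total-change conversion
DEFAULT_SPAN_YEARS = 38

ALPHA = 0.05
NEAR_SIGNIFICANT_BAND = (0.05, 0.10)


def significance_label(p: float) -> str:
    """'significant' (p < 0.05), 'near_significant' (0.05–0.10), or 'ns'."""
    if not np.isfinite(p):
        return "undefined"
    if p < ALPHA:
        return "significant"
    if p <= NEAR_SIGNIFICANT_BAND[1]:
        return "near_significant"
    return "ns"


@dataclass
class TrendResult:
    """Slope, uncertainty and derived total change of one OLS regression."""

    variable: str
    beta: float
    se: float
    r: float
    p: float
    delta: float
    n: int
    df_resid: int
    intercept: float
    aic_ols: float | None = None
    aic_ar1: float | None = None
    aic_ar2: float | None = None


@dataclass
class PartialRegressionResult:
    """Temperature effect after adjusting for rodent and fox covariates."""

    response: str
    predictor: str
    controls: tuple[str, ...]
    beta_p: float
    beta_resid: float  # residual-on-residual slope (Frisch–Waugh route)
    r_p: float
    p: float
    n: int
    collinear: bool
    fox_log_shift: float


@dataclass
class SlopeComparison:
    """Two-slope comparison by direct difference test or log-ratio trend."""

    method: str
    t: float
    p: float
    df: float
    beta1: float | None = None
    se1: float | None = None
    beta2: float | None = None
    se2: float | None = None
    beta: float | None = None  # log-ratio slope, for that method
    se: float | None = None
    n: int | None = None
    dropped_years: list[int] = field(default_factory=list)


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def ols_trend(years, y, span_years: int = DEFAULT_SPAN_YEARS,
              variable: str = "y") -> TrendResult:
    """OLS regression of an annual series on calendar year.

    Missing years are dropped pairwise.  A zero-variance response yields
    beta = 0 with undefined (NaN) correlation and p-value rather than an
    error, mirroring how a flat series is reported.
    """
    x, yy = _clean_pairs(years, y)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 non-missing years")
    if np.ptp(yy) == 0.0:
        return TrendResult(variable=variable, beta=0.0, se=0.0,
                           r=np.nan, p=np.nan, delta=0.0, n=n,
                           df_resid=n - 2, intercept=float(yy[0]))
    fit = stats.linregress(x, yy)
    beta = float(fit.slope)
    return TrendResult(variable=variable, beta=beta, se=float(fit.stderr),
                       r=float(fit.rvalue), p=float(fit.pvalue),
                       delta=total_change(beta, span_years), n=n,
                       df_resid=n - 2, intercept=float(fit.intercept))


def total_change(beta: float, span_years: int = DEFAULT_SPAN_YEARS) -> float:
    """Total change over the study span: Δ = β × span_years.

    Reported rounded to one decimal in the output tables, full precision
    here.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return beta * span_years


@dataclass
class ARComparison:
    """AICs of the year-trend model under iid, AR(1) and AR(2) errors."""

    aic_ols: float
    aic_ar1: float
    aic_ar2: float
    selected: str
    failures: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[float, float, float]:
        return self.aic_ols, self.aic_ar1, self.aic_ar2


def gls_ar_compare(years, y) -> ARComparison:
    """Fit the linear year trend with iid, AR(1) and AR(2) errors by ML.

    All three fits use exact maximum likelihood (ARIMA(p,0,0) with the year
    as exogenous regressor) so their AICs are directly comparable; the
    minimum-AIC error structure is labelled ``selected``.  Non-convergence
    of a single structure is reported in ``failures`` rather than raised.
    """
    from statsmodels.tsa.arima.model import ARIMA

    x, yy = _clean_pairs(years, y)
    if x.size < 6:
        raise ValueError("need >= 6 non-missing years")
    exog = x - x.mean()
    labels = ("ols", "ar1", "ar2")
    aics: dict[str, float] = {}
    failures: list[str] = []
    for p, label in zip((0, 1, 2), labels):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ARIMA(yy, exog=exog, order=(p, 0, 0),
                            trend="c").fit()
            aic = float(res.aic)
            if not np.isfinite(aic):
                raise ValueError("non-finite AIC")
        except Exception:  # noqa: BLE001 - any fit failure is non-fatal
            aic = np.nan
            failures.append(label)
        aics[label] = aic
    finite = {k: v for k, v in aics.items() if np.isfinite(v)}
    if not finite:
        raise RuntimeError("all error structures failed to fit")
    selected = min(finite, key=finite.get)
    return ARComparison(aic_ols=aics["ols"], aic_ar1=aics["ar1"],
                        aic_ar2=aics["ar2"], selected=selected,
                        failures=tuple(failures))


def normalized_trend(years, y, span_years: int = DEFAULT_SPAN_YEARS) -> float:
    """Relative trend per year: the OLS slope divided by the series mean.

    Makes trends of series on different scales (e.g. brood frequency vs
    brood size) directly comparable; requires a positive mean.
    """
    x, yy = _clean_pairs(years, y)
    mean = yy.mean()
    if mean <= 0:
        raise ValueError("normalized trend needs a positive series mean")
    return ols_trend(x, yy, span_years).beta / float(mean)


def log_ratio_trend(years, y_a, y_b) -> SlopeComparison:
    """Trend in log(y_a / y_b): tests whether two series diverge in relative terms.

    Years where either series is non-positive are dropped with a warning.
    The t statistic tests the log-ratio slope against zero.
    """
    years = np.asarray(years, dtype=float)
    a = np.asarray(y_a, dtype=float)
    b = np.asarray(y_b, dtype=float)
    finite = np.isfinite(years) & np.isfinite(a) & np.isfinite(b)
    positive = finite & (a > 0) & (b > 0)
    dropped = [int(v) for v in years[finite & ~positive]]
    if dropped:
        warnings.warn(f"log_ratio_trend dropped non-positive years: {dropped}",
                      stacklevel=2)
    x, ratio = years[positive], np.log(a[positive] / b[positive])
    if x.size < 3:
        raise ValueError("need >= 3 overlapping positive years")
    if np.ptp(ratio) == 0.0:
        return SlopeComparison(method="log_ratio_trend", t=0.0, p=1.0,
                               df=x.size - 2, beta=0.0, se=0.0,
                               n=x.size, dropped_years=dropped)
    fit = stats.linregress(x, ratio)
    t = float(fit.slope / fit.stderr) if fit.stderr > 0 else 0.0
    return SlopeComparison(method="log_ratio_trend", t=t, p=float(fit.pvalue),
                           df=x.size - 2, beta=float(fit.slope),
                           se=float(fit.stderr), n=x.size,
                           dropped_years=dropped)


def slope_difference_test(fit1: TrendResult, fit2: TrendResult) -> SlopeComparison:
    """Two-sample test of β₁ = β₂ from two independent OLS fits.

    t = (β₁ − β₂) / sqrt(se₁² + se₂²) with Welch–Satterthwaite degrees of
    freedom built from the two residual dfs.
    """
    v1, v2 = fit1.se ** 2, fit2.se ** 2
    pooled = v1 + v2
    if pooled <= 0:
        raise ValueError("zero pooled standard error")
    t = (fit1.beta - fit2.beta) / np.sqrt(pooled)
    df = pooled ** 2 / (v1 ** 2 / fit1.df_resid + v2 ** 2 / fit2.df_resid)
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeComparison(method="difference_test", t=float(t), p=float(p),
                           df=float(df), beta1=fit1.beta, se1=fit1.se,
                           beta2=fit2.beta, se2=fit2.se)


def temp_response(temp, metric, variable: str = "metric~temp") -> TrendResult:
    """OLS of an annual demographic metric on an annual window temperature.

    Same shape of result as :func:`ols_trend` but the regressor is the
    temperature, not the year, so the total-change field is not meaningful
    and is NaN.
    """
    x, yy = _clean_pairs(temp, metric)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired years")
    if np.ptp(yy) == 0.0 or np.ptp(x) == 0.0:
        return TrendResult(variable=variable, beta=0.0, se=0.0, r=np.nan,
                           p=np.nan, delta=np.nan, n=n, df_resid=n - 2,
                           intercept=float(yy.mean()))
    fit = stats.linregress(x, yy)
    return TrendResult(variable=variable, beta=float(fit.slope),
                       se=float(fit.stderr), r=float(fit.rvalue),
                       p=float(fit.pvalue), delta=np.nan, n=n,
                       df_resid=n - 2, intercept=float(fit.intercept))


def transform_covariates(rodents, fox) -> tuple[np.ndarray, np.ndarray, float]:
    """Square-root rodents and natural-log fox.

    Zero fox indices are handled by adding half the smallest positive value
    before the log; the applied shift is returned so callers can flag it.
    """
    rod = np.asarray(rodents, dtype=float)
    fx = np.asarray(fox, dtype=float)
    if np.nanmin(rod) < 0 or np.nanmin(fx) < 0:
        raise ValueError("covariate indices must be non-negative")
    shift = 0.0
    if np.nanmin(fx) == 0:
        positive = fx[np.isfinite(fx) & (fx > 0)]
        if positive.size == 0:
            raise ValueError("fox index is all zero; log undefined")
        shift = 0.5 * float(positive.min())
    return np.sqrt(rod), np.log(fx + shift), shift


def partial_regression(metric, temp, rodents, fox,
                       response: str = "metric",
                       predictor: str = "temp") -> PartialRegressionResult:
    """Temperature effect on a metric after controlling for rodents and fox.

    β_p is the temperature coefficient of the multiple regression of the
    metric on temperature + sqrt(rodents) + log(fox); r_p is the partial
    correlation obtained from the residual-on-residual regression, whose
    slope (also returned) equals β_p by the Frisch–Waugh theorem.  A design
    condition number above 1e8 sets the ``collinear`` flag.
    """
    import statsmodels.api as sm

    metric = np.asarray(metric, dtype=float)
    temp = np.asarray(temp, dtype=float)
    sqrt_rod, log_fox, shift = transform_covariates(rodents, fox)
    keep = (np.isfinite(metric) & np.isfinite(temp)
            & np.isfinite(sqrt_rod) & np.isfinite(log_fox))
    n = int(keep.sum())
    if n < 6:  # k + 3 complete cases with k = 3 regressors
        raise ValueError("need >= 6 complete cases")
    y = metric[keep]
    X = np.column_stack([temp[keep], sqrt_rod[keep], log_fox[keep]])
    Xc = sm.add_constant(X)
    collinear = bool(np.linalg.cond(Xc) > 1e8)
    full = sm.OLS(y, Xc).fit()
    beta_p = float(full.params[1])
    p = float(full.pvalues[1])

    # Frisch–Waugh route: residualise temp and metric on the controls
    Z = sm.add_constant(X[:, 1:])
    resid_t = temp[keep] - Z @ np.linalg.lstsq(Z, temp[keep], rcond=None)[0]
    resid_y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = float(resid_t @ resid_t)
    beta_resid = float(resid_t @ resid_y) / denom if denom > 0 else np.nan
    norm = np.sqrt(float(resid_t @ resid_t) * float(resid_y @ resid_y))
    r_p = float(resid_t @ resid_y) / norm if norm > 0 else np.nan

    return PartialRegressionResult(
        response=response, predictor=predictor,
        controls=("sqrt_rodents", "log_fox"),
        beta_p=beta_p, beta_resid=beta_resid, r_p=r_p, p=p, n=n,
        collinear=collinear, fox_log_shift=shift)


@dataclass
class LagResult:
    """Fit of a metric on summer temperature ``lag`` years earlier."""

    lag: int
    r2: float
    p: float
    n: int


def lagged_response(years, metric, temp_years, summer_temp,
                    lags: tuple[int, ...] = (1, 2)) -> list[LagResult]:
    """Regress a metric on mean summer (Jun–Aug) temperature 1–2 years back.

    Alignment drops boundary years without a matching lagged temperature.
    """
    years = np.asarray(years, dtype=int)
    metric = np.asarray(metric, dtype=float)
    temp_map = {int(ty): float(tv)
                for ty, tv in zip(np.asarray(temp_years, dtype=int),
                                  np.asarray(summer_temp, dtype=float))}
    out = []
    for lag in lags:
        if lag < 1:
            raise ValueError("lag must be >= 1")
        xs, ys = [], []
        for yr, m in zip(years, metric):
            t = temp_map.get(yr - lag)
            if t is not None and np.isfinite(t) and np.isfinite(m):
                xs.append(t)
                ys.append(m)
        if len(xs) < 3:
            raise ValueError(f"insufficient overlap for lag {lag}")
        fit = temp_response(xs, ys, variable=f"metric~summer_temp_lag{lag}")
        r2 = fit.r ** 2 if np.isfinite(fit.r) else np.nan
        out.append(LagResult(lag=lag, r2=float(r2), p=fit.p, n=fit.n))
    return out
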