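"""Hatch-date mismatch analysis.

The mismatch offset of a species-year is the signed number of days between
hatching and the GDD₅ = 200 date (onset of summer, i.e. completed bilberry
shoot growth): negative offsets mean the chicks hatched before summer
arrived, positive offsets after.  Breeding success is then regressed on the
offset with first- and second-order polynomials; the better model is chosen
by small-sample AIC (AICc), and a concave quadratic yields the estimated
optimal offset −b₁/(2 b₂).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MismatchPoint:
    """One species-year: hatch-vs-summer offset and its breeding success."""

    year: int
    species: str
    offset_days: float
    breeding_success: float


@dataclass
class MismatchFit:
    """Polynomial fit of breeding success on the mismatch offset."""

    species: str
    order: int
    coefficients: tuple[float, ...]  # (intercept, linear[, quadratic])
    r2: float
    p: float
    aicc: float
    n: int
    selected: bool = False
    optimum_offset: float | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x ** k for k, c in enumerate(self.coefficients))


def compute_offsets(breeding_table: pd.DataFrame,
                    phenology_dates: pd.DataFrame,
                    indices: pd.DataFrame) -> pd.DataFrame:
    """Join hatch dates, GDD₅=200 dates and breeding success per species-year.

    Returns columns ``year, species, offset_days, breeding_success`` where
    ``offset_days = hatch_doy − gdd200_doy``.  Years missing either date or
    the success index are dropped and logged.
    """
    hatch = breeding_table[["year", "species", "hatch_doy"]]
    gdd = phenology_dates[["year", "gdd200_doy"]]
    bs = indices[["year", "species", "breeding_success"]]
    merged = hatch.merge(gdd, on="year", how="left").merge(
        bs, on=["year", "species"], how="left")
    merged["offset_days"] = merged["hatch_doy"] - merged["gdd200_doy"]
    complete = merged.dropna(subset=["offset_days", "breeding_success"])
    n_dropped = len(merged) - len(complete)
    if n_dropped:
        log.info("compute_offsets dropped %d species-year(s) with missing "
                 "dates or success", n_dropped)
    return complete[["year", "species", "offset_days",
                     "breeding_success"]].reset_index(drop=True)


def _aicc(rss: float, n: int, n_params: int) -> float:
    # Gaussian log-likelihood based AIC with small-sample correction;
    # n_params counts the polynomial coefficients plus the error variance.
    if n <= n_params + 1:
        return np.inf
    aic = n * np.log(rss / n) + 2 * n_params
    return aic + 2 * n_params * (n_params + 1) / (n - n_params - 1)


def fit_mismatch(offsets, success, order: int,
                 species: str = "pooled") -> MismatchFit:
    """Least-squares polynomial of breeding success on the mismatch offset.

    ``order`` is 1 (line) or 2 (parabola).  The overall p-value is the
    F-test of the fitted polynomial against the intercept-only model.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(success, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < order + 2:
        raise ValueError(f"need >= {order + 2} points for order {order}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all offsets identical")
    X = np.vander(x, N=order + 1, increasing=True)
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    df_model, df_resid = order, n - order - 1
    if not np.isfinite(r2):
        p = np.nan
    elif 1.0 - r2 <= 1e-14:  # numerically exact fit
        p = 0.0
    else:
        f = (r2 / df_model) / ((1.0 - r2) / df_resid)
        p = float(stats.f.sf(f, df_model, df_resid))
    optimum = None
    if order == 2 and coefs[2] < 0:
        optimum = float(-coefs[1] / (2.0 * coefs[2]))
    return MismatchFit(species=species, order=order,
                       coefficients=tuple(float(c) for c in coefs),
                       r2=float(r2), p=p,
                       aicc=_aicc(max(rss, 1e-300), n, order + 2),
                       n=n, optimum_offset=optimum)


def select_mismatch_model(offsets, success,
                          species: str = "pooled"
                          ) -> tuple[MismatchFit, MismatchFit]:
    """Fit order 1 and order 2 and mark the AICc-preferred fit as selected.

    Returns ``(linear_fit, quadratic_fit)``; exactly one has
    ``selected=True``.  Requires at least 4 points.
    """
    x = np.asarray(offsets, dtype=float)
    if np.isfinite(x).sum() < 4:
        raise ValueError("need >= 4 points for model selection")
    f1 = fit_mismatch(offsets, success, order=1, species=species)
    f2 = fit_mismatch(offsets, success, order=2, species=species)
    if f2.aicc < f1.aicc:
        f2.selected = True
    else:
        f1.selected = True
    return f1, f2


def mismatch_table(points: pd.DataFrame) -> pd.DataFrame:
    """Per-species model-selection summary of the mismatch response.

    ``points`` holds ``species, offset_days, breeding_success`` rows; the
    output has one row per species and order with columns ``species, order,
    b0, b1, b2, r2, p, selected, optimum_offset``.
    """
    rows = []
    for species, sub in points.groupby("species"):
        fits = select_mismatch_model(sub["offset_days"],
                                     sub["breeding_success"], species=species)
        for fit in fits:
            b = list(fit.coefficients) + [np.nan] * (3 - len(fit.coefficients))
            rows.append({"species": species, "order": fit.order,
                         "b0": b[0], "b1": b[1], "b2": b[2],
                         "r2": fit.r2, "p": fit.p, "selected": fit.selected,
                         "optimum_offset": (np.nan if fit.optimum_offset is None
                                            else fit.optimum_offset)})
    return pd.DataFrame(rows)
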