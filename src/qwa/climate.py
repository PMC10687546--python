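"""Climatic water balance, SPEI and the drought-year calendar.

The Standardized Precipitation Evapotranspiration Index (SPEI) at scale k
is the standard-normal quantile of the fitted cumulative probability of
the k-month rolling climatic water balance D = P - PET.  Fitting is per
calendar month with a three-parameter log-logistic distribution estimated
by unbiased probability-weighted moments, the reference-implementation
convention for this index.  Potential evapotranspiration defaults to the
Thornthwaite temperature-based method with day-length correction, the
usual choice when only monthly temperature is available.

Severe drought years are flagged when the 3-month SPEI drops below -1.5 in
any month of the March-October growing-season window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma
from scipy.stats import norm

__all__ = [
    "thornthwaite_pet",
    "water_balance",
    "spei",
    "SpeiSeries",
    "DroughtCalendar",
    "flag_drought_years",
    "detrend_climate",
    "monthly_climate_matrix",
]

_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _day_length_hours(latitude: float, month: np.ndarray) -> np.ndarray:
    """Mean day length (h) at mid-month from the standard solar geometry."""
    doy = _MID_MONTH_DOY[month - 1]
    decl = 0.4093 * np.sin(2 * np.pi * doy / 365.25 - 1.405)
    lat = np.radians(latitude)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def thornthwaite_pet(climate: pd.DataFrame, latitude: float) -> pd.Series:
    """Monthly Thornthwaite potential evapotranspiration (mm).

    PET = 16 K (10 T / I)^a for T > 0 degC (0 otherwise), with the annual
    heat index I summed over that year's months, the cubic exponent a(I),
    and the day-length/month-length correction K.
    """
    if abs(latitude) > 66.5:
        raise ValueError("latitude beyond the polar circle: day-length formula undefined")
    if climate["tmean_c"].isna().any():
        raise ValueError("tmean missing for some months")
    t = climate["tmean_c"].to_numpy(dtype=float)
    month = climate["month"].to_numpy(dtype=int)
    year = climate["year"].to_numpy(dtype=int)

    tpos = np.maximum(t, 0.0)
    i_month = (tpos / 5.0) ** 1.514
    heat_index = pd.Series(i_month).groupby(year).transform("sum").to_numpy()
    a = 6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2 + 1.792e-2 * heat_index + 0.49239

    with np.errstate(divide="ignore", invalid="ignore"):
        pet_unadj = np.where(
            (tpos > 0) & (heat_index > 0),
            16.0 * (10.0 * tpos / np.where(heat_index > 0, heat_index, 1.0)) ** a,
            0.0,
        )
    k = (_day_length_hours(latitude, month) / 12.0) * (_DAYS_IN_MONTH[month - 1] / 30.0)
    return pd.Series(pet_unadj * k, index=climate.index, name="pet_mm")


def water_balance(climate: pd.DataFrame, latitude: float | None = None) -> pd.DataFrame:
    """Monthly climatic water balance D = precipitation - PET (mm).

    Uses a ``pet_mm`` column when present, otherwise computes Thornthwaite
    PET (``latitude`` then required).  Months must be contiguous.
    """
    _check_contiguous(climate)
    out = climate.copy()
    if "pet_mm" not in out.columns:
        if latitude is None:
            raise ValueError("latitude required to compute PET")
        out["pet_mm"] = thornthwaite_pet(out, latitude)
    out["balance_mm"] = out["prec_mm"] - out["pet_mm"]
    return out


def _check_contiguous(climate: pd.DataFrame) -> None:
    idx = climate["year"].to_numpy() * 12 + (climate["month"].to_numpy() - 1)
    if len(idx) == 0:
        raise ValueError("empty climate table")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate year-month rows")
    if not np.array_equal(np.sort(idx), np.arange(idx.min(), idx.min() + len(idx))):
        raise ValueError("climate months are not contiguous")


class _InadmissibleShape(ValueError):
    """PWM shape estimate outside the log-logistic domain (L-skew <= 0)."""


def _unbiased_pwm(x_sorted: np.ndarray, r: int) -> float:
    """Unbiased probability-weighted moment b_r of an ascending sample."""
    n = x_sorted.size
    i = np.arange(1, n + 1)
    w = np.ones(n)
    for j in range(r):
        w *= (i - 1 - j) / (n - 1 - j)
    return float(np.mean(w * x_sorted))


def _fit_loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Three-parameter log-logistic (alpha scale, beta shape, gamma origin)
    via unbiased PWMs; raises on degenerate or inadmissible samples."""
    xs = np.sort(x)
    if xs[-1] - xs[0] <= 0:
        raise ValueError("degenerate (zero-variance) sample for this calendar month")
    b0 = _unbiased_pwm(xs, 0)
    b1 = _unbiased_pwm(xs, 1)
    b2 = _unbiased_pwm(xs, 2)
    # complementary-weight PWMs w_s = E[X (1-F(X))^s] as used by the
    # log-logistic parameterization of the SPEI standardization
    w0, w1, w2 = b0, b0 - b1, b0 - 2 * b1 + b2
    beta = (2 * w1 - w0) / (6 * w1 - w0 - 6 * w2)
    if not np.isfinite(beta) or beta <= 1.0:
        raise _InadmissibleShape(
            f"log-logistic shape parameter {beta:.3f} inadmissible (<= 1)"
        )
    g1g2 = _gamma(1 + 1 / beta) * _gamma(1 - 1 / beta)
    alpha = (w0 - 2 * w1) * beta / g1g2
    gamma0 = w0 - alpha * g1g2
    return alpha, beta, gamma0


def _loglogistic_cdf(x: np.ndarray, alpha: float, beta: float, gamma0: float) -> np.ndarray:
    z = np.maximum(x - gamma0, 1e-12)
    return 1.0 / (1.0 + (alpha / z) ** beta)


@dataclass
class SpeiSeries:
    """Standardized index per year-month at one aggregation scale."""

    scale: int
    values: pd.DataFrame  # columns: year, month, spei
    calibration_period: tuple[int, int]

    def series(self) -> pd.Series:
        return self.values.set_index(["year", "month"])["spei"]


def spei(
    balance: pd.DataFrame,
    scale: int = 3,
    calibration: tuple[int, int] | None = None,
) -> SpeiSeries:
    """SPEI at a k-month scale from a monthly water-balance table.

    The k-month rolling sum of D is standardized per calendar month via a
    PWM-fitted three-parameter log-logistic distribution over the
    calibration years (default: the full record), then mapped through the
    standard-normal quantile function.  The first k-1 months are undefined.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    _check_contiguous(balance)
    df = balance.sort_values(["year", "month"]).reset_index(drop=True)
    agg = df["balance_mm"].rolling(scale, min_periods=scale).sum()
    out = df[["year", "month"]].copy()
    out["agg_mm"] = agg

    if calibration is None:
        calibration = (int(df["year"].min()), int(df["year"].max()))
    lo, hi = calibration
    n_cal = hi - lo + 1
    if n_cal < 30:
        raise ValueError(f"calibration period {calibration} shorter than 30 years")

    spei_vals = np.full(len(out), np.nan)
    for month in range(1, 13):
        sel = (out["month"] == month) & out["agg_mm"].notna()
        cal_sel = sel & out["year"].between(lo, hi)
        xcal = out.loc[cal_sel, "agg_mm"].to_numpy(dtype=float)
        if xcal.size == 0:
            continue
        x_all = out.loc[sel, "agg_mm"].to_numpy(dtype=float)
        try:
            alpha, beta, gamma0 = _fit_loglogistic_pwm(xcal)
            p = _loglogistic_cdf(x_all, alpha, beta, gamma0)
        except _InadmissibleShape:
            # left-skewed sample: the log-logistic (always right-skewed)
            # cannot fit it directly; fit the mirrored sample and use
            # F_X(x) = 1 - F_{-X}(-x), which preserves standardization
            alpha, beta, gamma0 = _fit_loglogistic_pwm(-xcal)
            p = 1.0 - _loglogistic_cdf(-x_all, alpha, beta, gamma0)
        spei_vals[sel.to_numpy()] = norm.ppf(np.clip(p, 1e-6, 1 - 1e-6))

    out = out.drop(columns="agg_mm")
    out["spei"] = spei_vals
    return SpeiSeries(scale=scale, values=out, calibration_period=calibration)


@dataclass
class DroughtCalendar:
    """Years whose 3-month SPEI fell below the threshold within the window."""

    drought_years: frozenset[int]
    threshold: float = -1.5
    window_months: tuple[int, int] = (3, 10)
    scale: int = 3

    def __contains__(self, year: int) -> bool:
        return year in self.drought_years

    def sorted(self) -> list[int]:
        return sorted(self.drought_years)


def flag_drought_years(
    spei3: SpeiSeries,
    threshold: float = -1.5,
    window_months: tuple[int, int] = (3, 10),
) -> DroughtCalendar:
    """Flag a year as a severe drought iff any month of the March-October
    window has SPEI below the threshold."""
    df = spei3.values
    lo, hi = window_months
    hit = df[(df["month"] >= lo) & (df["month"] <= hi) & (df["spei"] < threshold)]
    return DroughtCalendar(
        drought_years=frozenset(int(y) for y in hit["year"].unique()),
        threshold=threshold,
        window_months=window_months,
        scale=spei3.scale,
    )


def detrend_climate(
    climate: pd.DataFrame, column: str, cutoff: int = 30
) -> pd.DataFrame:
    """Detrend one monthly climate variable the same way the tree-ring
    series are detrended: each calendar month's interannual series is
    divided by its 30-year smoothing-spline fit, giving ratio indices.

    Returns a (year, month, index) table.
    """
    from .chronology import detrend_series  # deferred: avoids a cycle

    frames = []
    for month, grp in climate.groupby("month"):
        grp = grp.sort_values("year")
        idx = detrend_series(grp[column].to_numpy(dtype=float), cutoff=cutoff)
        frames.append(pd.DataFrame({"year": grp["year"].to_numpy(), "month": month, "index": idx}))
    out = pd.concat(frames, ignore_index=True).sort_values(["year", "month"])
    return out.reset_index(drop=True)


def monthly_climate_matrix(climate: pd.DataFrame, column: str = "index") -> pd.DataFrame:
    """Pivot a (year, month, value) table to a year x month matrix."""
    return climate.pivot(index="year", columns="month", values=column)
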