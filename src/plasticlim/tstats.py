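"""Descriptive statistics of annual climate series.

All correlation estimators here are "cropped Pearson": the lag-k
autocorrelation is the plain Pearson correlation between the first n-k
and last n-k observations, i.e. between year X and year X+k.  Partial
autocorrelations are obtained by Durbin-Levinson applied to that sample
ACF, which is exactly the partial correlation (shorter lags regressed
out) implied by the sample correlation sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DomainError, InsufficientDataError
from .series import AnnualSeries, SeasonalSeries

DEFAULT_MAX_LAG = 12

#: relative tolerance below which a series is treated as constant
_REL_SD_TOL = 1e-9


def _is_degenerate(x: np.ndarray) -> bool:
    x = np.asarray(x, float)
    return float(x.std()) <= _REL_SD_TOL * (1.0 + float(np.max(np.abs(x))))


@dataclass(frozen=True)
class SiteClimateSummary:
    """Per-site, per-variable descriptive statistics.

    ``acf``/``pacf`` are indexed by lag 1..max_lag; entries that cannot
    be computed (short or degenerate series) are NaN.  The five seasonal
    cross-correlation fields are populated only for seasonal pairs.
    """

    site_id: str
    variable: str
    mean: float
    iasd: float
    trend_slope: float
    acf: np.ndarray
    pacf: np.ndarray
    res_acf1: float
    n_years: int
    ee_acf: float = np.nan
    el_acf: float = np.nan
    le_acf: float = np.nan
    ll_acf: float = np.nan
    within_acf: float = np.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "acf", np.asarray(self.acf, dtype=float))
        object.__setattr__(self, "pacf", np.asarray(self.pacf, dtype=float))
        for name in ("acf", "pacf"):
            arr = getattr(self, name)
            finite = arr[np.isfinite(arr)]
            if np.any(np.abs(finite) > 1 + 1e-9):
                raise DomainError(f"{name} values must lie in [-1, 1]")
        if np.isfinite(self.iasd) and self.iasd < 0:
            raise DomainError("iasd must be non-negative")

    def acf_at(self, lag: int) -> float:
        return float(self.acf[lag - 1])

    def pacf_at(self, lag: int) -> float:
        return float(self.pacf[lag - 1])


def detrend_linear(series: AnnualSeries) -> tuple[AnnualSeries, float]:
    """Remove the OLS linear trend in year, preserving the series mean.

    Returns the residual-plus-mean series and the fitted slope
    (units/year).
    """
    if series.n_years < 3:
        raise InsufficientDataError("detrending needs at least 3 years")
    x = series.years.astype(float)
    y = series.values
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    detrended = residuals + y.mean()
    return series.with_values(detrended), float(slope)


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, AnnualSeries) else np.asarray(series, float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if _is_degenerate(a) or _is_degenerate(b):
        raise DegenerateInputError("zero variance in correlation window")
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def acf(series, max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """Cropped-Pearson autocorrelations at lags 1..max_lag."""
    x = _values(series)
    n = len(x)
    if n <= max_lag + 2:
        raise InsufficientDataError(f"need length > max_lag + 2 ({max_lag + 2}), got {n}")
    if _is_degenerate(x):
        raise DegenerateInputError("zero-variance series has no autocorrelation")
    return np.array([_pearson(x[:-k], x[k:]) for k in range(1, max_lag + 1)])


def pacf(series, max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """Partial autocorrelations at lags 1..max_lag via Durbin-Levinson.

    Applied to the cropped-Pearson sample ACF; lag 1 equals the lag-1
    ACF by construction.
    """
    rho = acf(series, max_lag)
    return pacf_from_acf(rho)


def pacf_from_acf(rho: np.ndarray) -> np.ndarray:
    """Durbin-Levinson reflection coefficients from an ACF sequence (lags 1..p)."""
    rho = np.asarray(rho, dtype=float)
    p = len(rho)
    out = np.empty(p)
    a = np.zeros(0)
    for k in range(1, p + 1):
        if k == 1:
            phi = rho[0]
        else:
            num = rho[k - 1] - a @ rho[k - 2 :: -1][:k - 1]
            den = 1.0 - a @ rho[: k - 1]
            if abs(den) < 1e-12:
                out[k - 1 :] = np.nan
                return out
            phi = num / den
        if not np.isfinite(phi) or abs(phi) > 1 + 1e-9:
            # sample ACF is not a valid (positive-definite) correlation
            # sequence at this order; higher lags are unidentifiable
            out[k - 1 :] = np.nan
            return out
        out[k - 1] = phi
        prev = a
        a = np.empty(k)
        a[k - 1] = phi
        if k > 1:
            a[: k - 1] = prev - phi * prev[::-1]
    return out


def cross_corr(a: AnnualSeries, b: AnnualSeries, lag: int = 0) -> float:
    """Pearson correlation of a_{t-lag} with b_t over shared years."""
    if not np.array_equal(a.years, b.years):
        raise DomainError("series must share identical year labels")
    if lag < 0:
        raise DomainError("lag must be >= 0")
    n = a.n_years
    if n - lag < 3:
        raise InsufficientDataError("need at least 3 overlapping years")
    xa = a.values[: n - lag] if lag else a.values
    xb = b.values[lag:] if lag else b.values
    return _pearson(xa, xb)


def _safe(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (DegenerateInputError, InsufficientDataError):
        return np.nan


def _annual_summary(series: AnnualSeries, max_lag: int) -> dict:
    x = series.values
    lag_cap = min(max_lag, series.n_years - 3)
    acf_vals = np.full(max_lag, np.nan)
    pacf_vals = np.full(max_lag, np.nan)
    if lag_cap >= 1:
        got = _safe(acf, series, lag_cap)
        if got is not np.nan:
            acf_vals[:lag_cap] = got
            pacf_vals[:lag_cap] = pacf_from_acf(got)
    detrended, slope = detrend_linear(series)
    res_acf1 = _safe(acf, detrended, 1)
    if isinstance(res_acf1, np.ndarray):
        res_acf1 = float(res_acf1[0])
    return {
        "site_id": series.site_id,
        "variable": series.variable,
        "mean": float(x.mean()),
        "iasd": float(x.std(ddof=1)),
        "trend_slope": slope,
        "acf": acf_vals,
        "pacf": pacf_vals,
        "res_acf1": res_acf1,
        "n_years": series.n_years,
    }


def site_summary(data, max_lag: int = DEFAULT_MAX_LAG):
    """Summarize one site's series.

    For an :class:`AnnualSeries`, returns one :class:`SiteClimateSummary`.
    For a :class:`SeasonalSeries`, returns an (early, late) pair, each
    carrying the five seasonal cross-correlations.  Degenerate statistics
    are recorded as NaN rather than raised, so batch runs stay alive.
    """
    if isinstance(data, AnnualSeries):
        return SiteClimateSummary(**_annual_summary(data, max_lag))
    if isinstance(data, SeasonalSeries):
        e, l = data.early, data.late
        n = data.n_years
        e_prev = e.values[:-1]
        l_prev = l.values[:-1]
        cross = {
            "ee_acf": _safe(_pearson, e_prev, e.values[1:]),
            "el_acf": _safe(_pearson, e_prev, l.values[1:]),
            "le_acf": _safe(_pearson, l_prev, e.values[1:]),
            "ll_acf": _safe(_pearson, l_prev, l.values[1:]),
            "within_acf": _safe(_pearson, e.values, l.values),
        } if n >= 4 else {}
        early = SiteClimateSummary(**_annual_summary(e, max_lag), **cross)
        late = SiteClimateSummary(**_annual_summary(l, max_lag), **cross)
        return early, late
    raise TypeError(f"unsupported input type {type(data).__name__}")
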