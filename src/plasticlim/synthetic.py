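"""Seeded synthetic climate generators.

Annual series are stationary AR(p) processes parameterized directly by
their partial autocorrelations (the Durbin-Levinson reflection
coefficients), rescaled to a requested marginal SD, shifted by a
long-term mean, and optionally given a mean-preserving linear trend.
Seasonal pairs are a first-order vector autoregression on standardized
(early, late) deviations with correlated Gaussian innovations.

The monthly disaggregator turns annual series back into the long CSV
dialect consumed by :mod:`plasticlim.climate_io`, conserving the annual
aggregate exactly; it exists so that round trips through the reader can
be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.signal import lfilter

from .climate_io import HYDRO_WINDOW, MonthlyClimateTable, SEASON_MONTHS
from .errors import DomainError
from .series import AnnualSeries, SeasonalSeries

#: steps discarded before recording, to remove the initialization transient
BURN_IN = 200


@dataclass(frozen=True)
class AnnualSimSpec:
    """Parameters of one simulated annual series."""

    n_years: int
    mean: float
    sd: float
    pacf_targets: tuple[float, ...] = ()
    trend: float = 0.0
    seed: int = 0
    site_id: str = "sim"
    variable: str = "precip"
    start_year: int = 1896
    clip_at_zero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pacf_targets", tuple(float(p) for p in self.pacf_targets))
        p = len(self.pacf_targets)
        if self.n_years < p + 5:
            raise DomainError(f"n_years must be >= order + 5 ({p + 5})")
        if not self.sd > 0:
            raise DomainError("sd must be positive")
        if any(abs(phi) >= 1 for phi in self.pacf_targets):
            raise DomainError("all partial autocorrelations must satisfy |phi| < 1")


@dataclass(frozen=True)
class SeasonalSimSpec:
    """Parameters of one simulated (early, late) seasonal pair.

    ``var1_matrix`` is the lag-1 coefficient matrix of a VAR(1) on the
    *standardized* (E, L) deviations, row = target component, column =
    source component: entry (1, 0) couples last year's E into this
    year's L.  ``within_year_corr`` is the innovation correlation.
    """

    n_years: int
    mean_early: float
    mean_late: float
    sd_early: float
    sd_late: float
    var1_matrix: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))
    within_year_corr: float = 0.0
    trend_early: float = 0.0
    trend_late: float = 0.0
    seed: int = 0
    site_id: str = "sim"
    start_year: int = 1896

    def __post_init__(self) -> None:
        A = np.asarray(self.var1_matrix, dtype=float)
        if A.shape != (2, 2):
            raise DomainError("var1_matrix must be 2x2")
        object.__setattr__(self, "var1_matrix", tuple(tuple(row) for row in A))
        if self.n_years < 6:
            raise DomainError("n_years must be >= 6")
        if not (self.sd_early > 0 and self.sd_late > 0):
            raise DomainError("seasonal SDs must be positive")
        if np.max(np.abs(np.linalg.eigvals(A))) >= 1:
            raise DomainError("var1_matrix must have spectral radius < 1")
        if abs(self.within_year_corr) >= 1:
            raise DomainError("|within_year_corr| must be < 1")


def ar_coeffs_from_pacf(pacf_targets) -> np.ndarray:
    """AR(p) coefficients whose theoretical PACF equals ``pacf_targets``.

    Durbin-Levinson recursion run forward with the targets as reflection
    coefficients: a_k^(k) = phi_kk and
    a_j^(k) = a_j^(k-1) - phi_kk * a_{k-j}^(k-1).
    """
    phis = [float(p) for p in pacf_targets]
    if any(abs(p) >= 1 for p in phis):
        raise DomainError("all partial autocorrelations must satisfy |phi| < 1")
    a = np.zeros(0)
    for k, phi in enumerate(phis, start=1):
        prev = a
        a = np.empty(k)
        a[k - 1] = phi
        if k > 1:
            a[: k - 1] = prev - phi * prev[::-1]
    return a


def _stationary_gain(pacf_targets) -> float:
    """SD of the stationary AR process per unit innovation SD."""
    prod = 1.0
    for phi in pacf_targets:
        prod *= 1.0 - float(phi) ** 2
    return prod ** -0.5


def centered_trend(n_years: int, slope: float) -> np.ndarray:
    """Linear ramp with the given per-year slope and zero mean."""
    idx = np.arange(n_years, dtype=float)
    return slope * (idx - (n_years - 1) / 2.0)


def simulate_annual_series(spec: AnnualSimSpec) -> AnnualSeries:
    """Deterministic (per seed) stationary AR(p) series per the spec."""
    rng = np.random.default_rng(spec.seed)
    coeffs = ar_coeffs_from_pacf(spec.pacf_targets)
    sigma_eps = spec.sd / _stationary_gain(spec.pacf_targets)
    n_total = spec.n_years + BURN_IN
    eps = rng.standard_normal(n_total) * sigma_eps
    # x_t - sum a_i x_{t-i} = eps_t  <=>  AR filter with denominator [1, -a]
    dev = lfilter([1.0], np.concatenate(([1.0], -coeffs)), eps)[BURN_IN:]
    values = spec.mean + dev + centered_trend(spec.n_years, spec.trend)
    if spec.clip_at_zero:
        values = np.clip(values, 0.0, None)
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    return AnnualSeries(spec.site_id, spec.variable, years, values)


def simulate_seasonal_pair(spec: SeasonalSimSpec) -> SeasonalSeries:
    """Deterministic (per seed) VAR(1) seasonal pair per the spec.

    Standardized deviations z follow z_t = A z_{t-1} + e_t with
    corr(e_E, e_L) = within_year_corr; each component is rescaled by its
    theoretical stationary SD so the output hits the requested marginal SDs.
    """
    rng = np.random.default_rng(spec.seed)
    A = np.asarray(spec.var1_matrix, dtype=float)
    r = spec.within_year_corr
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov)
    n_total = spec.n_years + BURN_IN
    eps = rng.standard_normal((n_total, 2)) @ chol.T
    z = np.zeros((n_total, 2))
    state = np.zeros(2)
    for t in range(n_total):
        state = A @ state + eps[t]
        z[t] = state
    z = z[BURN_IN:]
    gamma0 = solve_discrete_lyapunov(A, cov)
    scale = np.sqrt(np.diag(gamma0))
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    e_vals = spec.mean_early + spec.sd_early * z[:, 0] / scale[0] + centered_trend(
        spec.n_years, spec.trend_early
    )
    l_vals = spec.mean_late + spec.sd_late * z[:, 1] / scale[1] + centered_trend(
        spec.n_years, spec.trend_late
    )
    early = AnnualSeries(spec.site_id, "tmax_early", years, e_vals)
    late = AnnualSeries(spec.site_id, "tmax_late", years, l_vals)
    return SeasonalSeries(spec.site_id, early, late)


def disaggregate_to_monthly(
    annual: AnnualSeries,
    seed: int = 0,
    lat: float = 0.0,
    lon: float = 0.0,
) -> MonthlyClimateTable:
    """Spread annual values over months so the window aggregate is exact.

    Precipitation totals are split over the 12 hydrologic-year months with
    random positive weights; seasonal temperatures get three monthly values
    whose mean equals the annual value.  Feeding the result back through
    :mod:`plasticlim.climate_io` recovers the source series.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    if annual.variable == "precip":
        if np.any(annual.values < 0):
            raise DomainError("cannot disaggregate negative precipitation totals")
        for year, total in zip(annual.years, annual.values):
            w = rng.uniform(0.5, 1.5, size=12)
            w /= w.sum()
            monthly = total * w
            # force exact conservation of the window sum
            monthly[-1] = total - monthly[:-1].sum()
            for (dy, month), val in zip(HYDRO_WINDOW, monthly):
                records.append(
                    {
                        "site_id": annual.site_id,
                        "lat": lat,
                        "lon": lon,
                        "year": int(year) + dy,
                        "month": month,
                        "ppt_mm": max(val, 0.0),
                        "tmax_c": np.nan,
                    }
                )
    elif annual.variable in ("tmax_early", "tmax_late"):
        season = "early" if annual.variable == "tmax_early" else "late"
        months = SEASON_MONTHS[season]
        for year, mean_val in zip(annual.years, annual.values):
            d = rng.uniform(-1.0, 1.0, size=2)
            vals = [mean_val + d[0], mean_val + d[1]]
            vals.append(3.0 * mean_val - vals[0] - vals[1])
            for month, val in zip(months, vals):
                records.append(
                    {
                        "site_id": annual.site_id,
                        "lat": lat,
                        "lon": lon,
                        "year": int(year),
                        "month": month,
                        "ppt_mm": np.nan,
                        "tmax_c": val,
                    }
                )
    else:  # pragma: no cover - series type already validates the variable
        raise DomainError(f"cannot disaggregate variable {annual.variable!r}")
    return MonthlyClimateTable(pd.DataFrame.from_records(records))
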