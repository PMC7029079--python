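"""Core in-memory series types shared by every stage of the pipeline.

An :class:`AnnualSeries` holds one site's per-year values for a single
variable (hydrologic-year precipitation totals or seasonal mean daily
maximum temperature).  A :class:`SeasonalSeries` pairs the early
(Mar-May) and late (Jul-Sep) temperature series of one site on a shared
year axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError

VARIABLES = ("precip", "tmax_early", "tmax_late")

#: minimum number of years for a series to be usable at all
MIN_YEARS = 5


@dataclass(frozen=True)
class AnnualSeries:
    """One site's annual climate values with integer year labels.

    Years must be strictly increasing.  Gaps are tolerated (years with
    missing months are dropped upstream); lag-based consumers restrict
    themselves to runs of consecutive years.  The long-term baseline is
    always the arithmetic mean of the stored values and is recomputed,
    never stored.
    """

    site_id: str
    variable: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.variable not in VARIABLES:
            raise DomainError(f"unknown variable {self.variable!r}")
        if years.ndim != 1 or values.ndim != 1 or years.shape != values.shape:
            raise DomainError("years and values must be 1-D arrays of equal length")
        if len(years) < MIN_YEARS:
            raise InsufficientDataError(
                f"series needs at least {MIN_YEARS} years, got {len(years)}"
            )
        if np.any(np.diff(years) <= 0):
            raise DomainError("years must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise DomainError("values must be finite")

    @property
    def baseline(self) -> float:
        """Long-term mean of the stored values."""
        return float(self.values.mean())

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def is_contiguous(self) -> bool:
        return bool(np.all(np.diff(self.years) == 1))

    def with_values(self, values: np.ndarray) -> "AnnualSeries":
        """Copy of this series with replaced values (same years)."""
        return AnnualSeries(self.site_id, self.variable, self.years, values)


@dataclass(frozen=True)
class SeasonalSeries:
    """Paired early/late growing-season temperature series for one site."""

    site_id: str
    early: AnnualSeries
    late: AnnualSeries
    years: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.early.variable != "tmax_early" or self.late.variable != "tmax_late":
            raise DomainError("seasonal pair must be (tmax_early, tmax_late)")
        if not np.array_equal(self.early.years, self.late.years):
            raise DomainError("early and late series must share identical year labels")
        object.__setattr__(self, "years", self.early.years)

    @property
    def n_years(self) -> int:
        return len(self.years)
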