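"""Reading long-format monthly climate tables and aggregating to annual series.

The canonical input is a flat CSV with header
``site_id,lat,lon,year,month,ppt_mm,tmax_c`` ("." decimal, empty cell =
missing).  Precipitation is totalled over the hydrologic year (October
of the previous calendar year through September, labelled by the ending
year); temperature is averaged over the early (Mar-May) or late
(Jul-Sep) growing season of a single calendar year.  Years with any
missing month in the relevant window are dropped, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientDataError,
    IntegrityError,
    SiteNotFoundError,
)
from .series import AnnualSeries

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site_id", "lat", "lon", "year", "month", "ppt_mm", "tmax_c")

SEASON_MONTHS = {"early": (3, 4, 5), "late": (7, 8, 9)}

#: hydrologic year Y = Oct(Y-1) .. Sep(Y), as (year offset, month) pairs
HYDRO_WINDOW = tuple((-1, m) for m in (10, 11, 12)) + tuple((0, m) for m in range(1, 10))

MIN_COMPLETE_YEARS = 5


@dataclass
class MonthlyClimateTable:
    """Validated long-format monthly climate records.

    ``data`` columns follow :data:`REQUIRED_COLUMNS`; ``n_flagged`` counts
    cells that failed numeric parsing on read and were demoted to missing.
    """

    data: pd.DataFrame
    n_flagged: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = self.data.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["site_id"] = df["site_id"].astype(str)
        for col in ("lat", "lon", "ppt_mm", "tmax_c"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df["year"] = df["year"].astype(np.int64)
        df["month"] = df["month"].astype(np.int64)
        if ((df["month"] < 1) | (df["month"] > 12)).any():
            raise IntegrityError("month values must lie in [1, 12]")
        if df.duplicated(subset=["site_id", "year", "month"]).any():
            raise IntegrityError("duplicate (site_id, year, month) records")
        if (df["ppt_mm"].dropna() < 0).any():
            raise IntegrityError("negative precipitation values")
        self.data = df

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site_id"].unique())

    def site(self, site_id: str) -> pd.DataFrame:
        sub = self.data[self.data["site_id"] == site_id]
        if sub.empty:
            raise SiteNotFoundError(site_id)
        return sub


def read_monthly_climate(path: str | Path) -> MonthlyClimateTable:
    """Read and validate a monthly climate CSV.

    Unparseable numeric cells are demoted to missing and counted in
    ``n_flagged`` (one log line); rows whose site/year/month key cannot be
    parsed are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = raw.loc[:, list(REQUIRED_COLUMNS)].copy()
    n_flagged = 0
    for col in ("lat", "lon", "year", "month", "ppt_mm", "tmax_c"):
        cell = df[col].str.strip()
        parsed = pd.to_numeric(cell, errors="coerce")
        bad = parsed.isna() & (cell != "")
        n_flagged += int(bad.sum())
        df[col] = parsed
    if n_flagged:
        log.warning("%s: %d unparseable numeric cells treated as missing", path, n_flagged)
    # key columns must parse; drop rows where they did not
    key_ok = df[["year", "month"]].notna().all(axis=1) & (df["site_id"].str.strip() != "")
    n_dropped = int((~key_ok).sum())
    if n_dropped:
        log.warning("%s: %d rows dropped (unusable site/year/month key)", path, n_dropped)
    df = df[key_ok].reset_index(drop=True)
    return MonthlyClimateTable(df, n_flagged=n_flagged)


def _monthly_lookup(sub: pd.DataFrame, value_col: str) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    for year, month, val in zip(sub["year"], sub["month"], sub[value_col]):
        if pd.notna(val):
            out[(int(year), int(month))] = float(val)
    return out


def hydrologic_year_precip(
    table: MonthlyClimateTable,
    site_id: str,
    min_years: int = MIN_COMPLETE_YEARS,
) -> AnnualSeries:
    """Total precipitation over each complete hydrologic year at one site.

    Hydrologic year Y spans Oct(Y-1)..Sep(Y) and is labelled by its ending
    calendar year.  Years with any of the 12 months missing are dropped.
    """
    sub = table.site(site_id)
    ppt = _monthly_lookup(sub, "ppt_mm")
    if not ppt:
        raise InsufficientDataError(f"{site_id}: no precipitation records")
    years_present = {y for (y, _m) in ppt}
    labels, totals = [], []
    for y in range(min(years_present), max(years_present) + 2):
        window = [(y + dy, m) for dy, m in HYDRO_WINDOW]
        if all(k in ppt for k in window):
            labels.append(y)
            totals.append(sum(ppt[k] for k in window))
        else:
            if any(k in ppt for k in window):
                log.debug("%s: hydrologic year %d incomplete, dropped", site_id, y)
    if len(labels) < min_years:
        raise InsufficientDataError(
            f"{site_id}: only {len(labels)} complete hydrologic years (need {min_years})"
        )
    return AnnualSeries(site_id, "precip", np.array(labels), np.array(totals))


def season_tmax_series(
    table: MonthlyClimateTable,
    site_id: str,
    season: str,
    min_years: int = MIN_COMPLETE_YEARS,
) -> AnnualSeries:
    """Mean daily maximum temperature over one growing season per calendar year."""
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be 'early' or 'late', got {season!r}")
    months = SEASON_MONTHS[season]
    sub = table.site(site_id)
    tmax = _monthly_lookup(sub, "tmax_c")
    if not tmax:
        raise InsufficientDataError(f"{site_id}: no temperature records")
    years_present = sorted({y for (y, _m) in tmax})
    labels, means = [], []
    for y in years_present:
        vals = [tmax.get((y, m)) for m in months]
        if all(v is not None for v in vals):
            labels.append(y)
            means.append(float(np.mean(vals)))
        else:
            log.debug("%s: %s season %d incomplete, dropped", site_id, season, y)
    if len(labels) < min_years:
        raise InsufficientDataError(
            f"{site_id}: only {len(labels)} complete {season}-season years (need {min_years})"
        )
    variable = "tmax_early" if season == "early" else "tmax_late"
    return AnnualSeries(site_id, variable, np.array(labels), np.array(means))


def write_annual_series_csv(series: Iterable[AnnualSeries], path: str | Path) -> None:
    """Write annual series as long CSV ``site_id,variable,year,value``."""
    frames = [
        pd.DataFrame(
            {
                "site_id": s.site_id,
                "variable": s.variable,
                "year": s.years,
                "value": s.values,
            }
        )
        for s in series
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["site_id", "variable", "year", "value"]
    )
    out.to_csv(path, index=False)


def write_monthly_climate(table: MonthlyClimateTable, path: str | Path) -> None:
    """Write a monthly table in the canonical CSV dialect (empty = missing)."""
    table.data.to_csv(path, index=False, na_rep="")


def concat_tables(tables: Iterable[MonthlyClimateTable]) -> MonthlyClimateTable:
    """Merge several monthly tables.

    Records sharing a (site_id, year, month) key are collapsed: each value
    column takes its unique non-missing value; two conflicting non-missing
    values raise IntegrityError.
    """
    frames = [t.data for t in tables]
    if not frames:
        raise ValueError("no tables to concatenate")
    df = pd.concat(frames, ignore_index=True)
    key = ["site_id", "year", "month"]
    grouped = df.groupby(key, sort=True)
    for col in ("lat", "lon", "ppt_mm", "tmax_c"):
        conflicts = grouped[col].nunique(dropna=True) > 1
        if conflicts.any():
            first_key = conflicts[conflicts].index[0]
            raise IntegrityError(f"conflicting {col} values for key {first_key}")
    merged = grouped[["lat", "lon", "ppt_mm", "tmax_c"]].first().reset_index()
    return MonthlyClimateTable(merged[list(REQUIRED_COLUMNS)])
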