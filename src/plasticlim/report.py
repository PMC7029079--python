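"""Batch pipeline over many sites plus cross-site summaries.

One row per site x variant; degenerate sites yield an in-band skip row
with a reason code instead of crashing the batch.  Cross-site helpers
cover optimum histograms over the strategy grid, an OLS regression of
temperature optima on the five seasonal autocorrelation classes, and a
sign x persistence classification of precipitation strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_io, tstats
from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    PlasticlimError,
)
from .precip import ModelConfig, bimodality_condition, evaluate_precip_landscape
from .series import AnnualSeries, SeasonalSeries
from .temp import PARAM_NAMES, TempModelConfig, evaluate_temp_landscape

log = logging.getLogger(__name__)

MODELS = ("precip", "temp")

ACF_PREDICTORS = ("ee_acf", "el_acf", "le_acf", "ll_acf", "within_acf")
TEMP_RESPONSES = ("m_ee", "m_el", "m_le", "m_ll")

_SKIPPABLE = (InsufficientDataError, DegenerateInputError, DomainError)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one deterministic batch run."""

    input_path: str | Path
    model: str = "precip"
    variants: tuple[str, ...] = ("raw", "residual")
    precip_config: ModelConfig = field(default_factory=ModelConfig)
    temp_config: TempModelConfig = field(default_factory=TempModelConfig)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise DomainError(f"model must be one of {MODELS}")
        object.__setattr__(self, "variants", tuple(self.variants))
        if not self.variants:
            raise DomainError("at least one variant required")


def _summary_fields(summary: tstats.SiteClimateSummary, prefix: str = "") -> dict:
    out = {
        f"{prefix}mean": summary.mean,
        f"{prefix}iasd": summary.iasd,
        f"{prefix}trend_slope": summary.trend_slope,
        f"{prefix}acf1": summary.acf_at(1),
        f"{prefix}pacf2": summary.pacf_at(2),
        f"{prefix}pacf3": summary.pacf_at(3),
        f"{prefix}res_acf1": summary.res_acf1,
    }
    return out


def _degenerate(values: np.ndarray) -> bool:
    return float(values.std()) <= 1e-12 * (1.0 + abs(float(values.mean())))


def _precip_site_rows(table, site_id: str, config: RunConfig) -> list[dict]:
    series = climate_io.hydrologic_year_precip(table, site_id)
    if _degenerate(series.values):
        raise DegenerateInputError("constant precipitation series")
    summary = tstats.site_summary(series)
    rows = []
    for variant in config.variants:
        cfg = ModelConfig(
            fitness_floor=config.precip_config.fitness_floor,
            m_grid=config.precip_config.m_grid,
            g_grid=config.precip_config.g_grid,
            variant=variant,
        )
        land = evaluate_precip_landscape(series, cfg)
        try:
            bimodal = bimodality_condition(summary)
        except DomainError:
            bimodal = np.nan
        row = {
            "site_id": site_id,
            "model": "precip",
            "variant": variant,
            "m_opt": land.optimum.strategy.m,
            "g_opt": land.optimum.strategy.g,
            "gm_fitness": land.optimum.gm_fitness,
            "n_years": land.n_years_used,
            "n_local_maxima": land.n_local_maxima,
            "bimodal_condition": bimodal,
            "skip_reason": "",
        }
        row.update(_summary_fields(summary))
        log.info(
            "site=%s model=precip variant=%s optimum=(m=%.2f, g=%.2f) W=%.6f",
            site_id, variant, row["m_opt"], row["g_opt"], row["gm_fitness"],
        )
        rows.append(row)
    _add_deltas(rows, ("m_opt", "g_opt"))
    return rows


def _temp_site_rows(table, site_id: str, config: RunConfig) -> list[dict]:
    early = climate_io.season_tmax_series(table, site_id, "early")
    late = climate_io.season_tmax_series(table, site_id, "late")
    shared = np.intersect1d(early.years, late.years)
    e_mask = np.isin(early.years, shared)
    l_mask = np.isin(late.years, shared)
    seasonal = SeasonalSeries(
        site_id,
        AnnualSeries(site_id, "tmax_early", early.years[e_mask], early.values[e_mask]),
        AnnualSeries(site_id, "tmax_late", late.years[l_mask], late.values[l_mask]),
    )
    if _degenerate(seasonal.early.values) or _degenerate(seasonal.late.values):
        raise DegenerateInputError("constant seasonal temperature series")
    early_summary, _late_summary = tstats.site_summary(seasonal)
    rows = []
    for variant in config.variants:
        cfg = TempModelConfig(
            values=config.temp_config.values,
            fitness_floor=config.temp_config.fitness_floor,
            scale=config.temp_config.scale,
            variant=variant,
        )
        land = evaluate_temp_landscape(seasonal, cfg)
        opt = land.optimum.strategy
        row = {
            "site_id": site_id,
            "model": "temp",
            "variant": variant,
            "m_ee": opt.m_ee,
            "m_el": opt.m_el,
            "m_le": opt.m_le,
            "m_ll": opt.m_ll,
            "w": opt.w,
            "gm_fitness": land.optimum.gm_fitness,
            "total_tgp": land.total_tgp,
            "max_tgp": land.max_tgp,
            "min_tgp": land.min_tgp,
            "n_obs": land.n_obs,
            "skip_reason": "",
        }
        for name in ACF_PREDICTORS:
            row[name] = getattr(early_summary, name)
        log.info(
            "site=%s model=temp variant=%s optimum=%s W=%.6f",
            site_id, variant, opt.as_tuple(), row["gm_fitness"],
        )
        rows.append(row)
    _add_deltas(rows, ("m_ee", "m_el", "m_le", "m_ll", "w"))
    return rows


def _add_deltas(rows: list[dict], params: tuple[str, ...]) -> None:
    """Populate raw-minus-residual deltas when both variants are present."""
    by_variant = {r["variant"]: r for r in rows}
    if "raw" in by_variant and "residual" in by_variant:
        for p in params:
            delta = by_variant["raw"][p] - by_variant["residual"][p]
            for r in rows:
                r[f"delta_{p}"] = delta


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Aggregate, summarize and optimize every site in the input table.

    Returns one row per site x variant, sorted by (site_id, variant);
    sites whose series are degenerate or too short get a single skip row
    with the reason recorded in ``skip_reason``.
    """
    table = climate_io.read_monthly_climate(config.input_path)
    sites = table.sites
    if not sites:
        raise DomainError("input table contains no sites")
    rows: list[dict] = []
    for site_id in sites:
        try:
            if config.model == "precip":
                rows.extend(_precip_site_rows(table, site_id, config))
            else:
                rows.extend(_temp_site_rows(table, site_id, config))
        except _SKIPPABLE as exc:
            log.warning("site=%s skipped: %s", site_id, exc)
            rows.append(
                {
                    "site_id": site_id,
                    "model": config.model,
                    "variant": "",
                    "skip_reason": f"{type(exc).__name__}: {exc}",
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["site_id", "variant"], kind="stable").reset_index(drop=True)


def optima_histogram(
    results: pd.DataFrame, parameter: str, grid: tuple[float, ...] | None = None
) -> pd.DataFrame:
    """Counts of the optimum's ``parameter`` over its grid values.

    Counts are per site (the raw variant row is used when both variants
    are present) and sum to the number of non-skipped sites.
    """
    if results.empty:
        raise DomainError("no results to histogram")
    if parameter not in results.columns:
        raise DomainError(f"unknown parameter {parameter!r}")
    ok = results[results["skip_reason"] == ""]
    variants = [v for v in ("raw", "residual") if (ok["variant"] == v).any()]
    if not variants:
        raise DomainError("no non-skipped results")
    ok = ok[ok["variant"] == variants[0]]
    vals = ok[parameter].astype(float)
    if grid is None:
        grid = tuple(sorted(vals.unique()))
    counts = []
    for v in grid:
        counts.append(int(np.sum(np.isclose(vals, v, atol=1e-9))))
    if sum(counts) != len(vals):
        raise DomainError(f"some optima lie outside the provided grid for {parameter!r}")
    return pd.DataFrame({"value": list(grid), "count": counts})


def regress_optima_on_acf(results: pd.DataFrame) -> pd.DataFrame:
    """OLS (with intercept) of temperature optima on autocorrelation classes.

    Returns the 5 x 4 slope table: rows ee/el/le/ll/within autocorrelation,
    columns the four transgenerational parameters.  Rank deficiency yields
    NaN coefficients and a warning instead of an error.
    """
    ok = results[(results["skip_reason"] == "") & (results["model"] == "temp")]
    if "variant" in ok.columns and (ok["variant"] == "raw").any():
        ok = ok[ok["variant"] == "raw"]
    needed = list(ACF_PREDICTORS) + list(TEMP_RESPONSES)
    missing = [c for c in needed if c not in ok.columns]
    if missing:
        raise DomainError(f"results lack required columns: {missing}")
    ok = ok.dropna(subset=needed)
    if len(ok) < 10:
        raise InsufficientDataError(
            f"need >= 10 sites with temperature results, got {len(ok)}"
        )
    X = np.column_stack([np.ones(len(ok))] + [ok[c].to_numpy(float) for c in ACF_PREDICTORS])
    coef = pd.DataFrame(
        index=list(ACF_PREDICTORS), columns=list(TEMP_RESPONSES), dtype=float
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning("rank-deficient design (rank %d < %d); coefficients set to NaN",
                    rank, X.shape[1])
        return coef
    for resp in TEMP_RESPONSES:
        beta, *_ = np.linalg.lstsq(X, ok[resp].to_numpy(float), rcond=None)
        coef[resp] = beta[1:]
    return coef


_PRECIP_M_GRID = tuple(np.round(np.arange(-10, 11) * 0.1, 10))
_PRECIP_G_GRID = tuple(np.round(np.arange(0, 11) * 0.1, 10))


def classify_strategy(m: float, g: float) -> str:
    """Sign x persistence label of a precipitation strategy (7 classes)."""
    if not any(np.isclose(m, v, atol=1e-9) for v in _PRECIP_M_GRID):
        raise DomainError(f"m={m} is not on the strategy grid")
    if not any(np.isclose(g, v, atol=1e-9) for v in _PRECIP_G_GRID):
        raise DomainError(f"g={g} is not on the strategy grid")
    if np.isclose(m, 0.0, atol=1e-9):
        return "none"
    sign = "positive" if m > 0 else "negative"
    if np.isclose(g, 0.0, atol=1e-9):
        persistence = "single-generation"
    elif np.isclose(g, 1.0, atol=1e-9):
        persistence = "full-persistence"
    else:
        persistence = "intermediate"
    return f"{sign}/{persistence}"
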