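"""Temperature optimality model.

A strategy carries four transgenerational slopes (parent season ->
offspring season: m_ee, m_el, m_le, m_ll) plus one within-generation
slope w mapping the current early-season deviation onto the late-season
phenotype.  Phenotypes are linear in last year's (and, for w, this
year's early) seasonal deviations:

    E_hat_t = Ebar + m_ee*(E_{t-1}-Ebar) + m_le*(L_{t-1}-Lbar)
    L_hat_t = Lbar + m_el*(E_{t-1}-Ebar) + m_ll*(L_{t-1}-Lbar) + w*(E_t-Ebar)

Per-season fitness decays linearly with |phenotype - actual| scaled by
the season's long-term mean (switchable to interannual-SD scaling,
since Celsius has an arbitrary zero); the strategy score is the
geometric mean over all usable season observations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError
from .series import SeasonalSeries
from .tstats import detrend_linear

DEFAULT_VALUES = (-0.2, 0.0, 0.1, 0.3, 0.5)

PARAM_NAMES = ("m_ee", "m_el", "m_le", "m_ll", "w")

SCALES = ("mean", "iasd")

VARIANTS = ("raw", "residual")


@dataclass(frozen=True, order=True)
class TempStrategy:
    """One temperature genotype: four transgenerational slopes plus w."""

    m_ee: float = 0.0
    m_el: float = 0.0
    m_le: float = 0.0
    m_ll: float = 0.0
    w: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.m_ee, self.m_el, self.m_le, self.m_ll, self.w)

    @property
    def total_tgp(self) -> float:
        """Summed transgenerational plasticity, (m_ee+m_el+m_le+m_ll)/2."""
        return (self.m_ee + self.m_el + self.m_le + self.m_ll) / 2.0

    @property
    def max_tgp(self) -> float:
        return max(self.m_ee, self.m_el, self.m_le, self.m_ll)

    @property
    def min_tgp(self) -> float:
        return min(self.m_ee, self.m_el, self.m_le, self.m_ll)


@dataclass(frozen=True)
class TempStrategyFitness:
    strategy: TempStrategy
    gm_fitness: float
    n_obs: int


@dataclass(frozen=True)
class TempModelConfig:
    """Value grid, floor, fitness scale and variant for the temperature model."""

    values: tuple[float, ...] = DEFAULT_VALUES
    fitness_floor: float = 1e-6
    scale: str = "mean"
    variant: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not self.values:
            raise DomainError("value grid must be nonempty")
        if len(set(self.values)) != len(self.values):
            raise DomainError("value grid must not contain duplicates")
        if not 0.0 < self.fitness_floor < 0.1:
            raise DomainError("fitness_floor must lie in (0, 0.1)")
        if self.scale not in SCALES:
            raise DomainError(f"scale must be one of {SCALES}")
        if self.variant not in VARIANTS:
            raise DomainError(f"variant must be one of {VARIANTS}")


def temp_strategy_grid(values=DEFAULT_VALUES) -> list[TempStrategy]:
    """Full Cartesian product over the five parameters."""
    values = tuple(float(v) for v in values)
    if not values:
        raise DomainError("value grid must be nonempty")
    return [TempStrategy(*combo) for combo in itertools.product(sorted(values), repeat=5)]


def predict_season_phenotypes(
    seasonal: SeasonalSeries, strategy: TempStrategy, t: int
) -> tuple[float, float]:
    """(early, late) phenotypes for year index ``t`` (0-based)."""
    if t < 1 or t >= seasonal.n_years:
        raise IndexError(f"year index {t} lacks a prior year")
    if seasonal.years[t] - seasonal.years[t - 1] != 1:
        raise IndexError(f"year index {t} has a gap before it")
    ebar = seasonal.early.baseline
    lbar = seasonal.late.baseline
    de_prev = seasonal.early.values[t - 1] - ebar
    dl_prev = seasonal.late.values[t - 1] - lbar
    de_cur = seasonal.early.values[t] - ebar
    e_hat = ebar + strategy.m_ee * de_prev + strategy.m_le * dl_prev
    l_hat = lbar + strategy.m_el * de_prev + strategy.m_ll * dl_prev + strategy.w * de_cur
    return float(e_hat), float(l_hat)


def _usable_indices(seasonal: SeasonalSeries) -> np.ndarray:
    years = seasonal.years
    idx = np.arange(1, len(years))
    return idx[(years[idx] - years[idx - 1]) == 1]


def _fitness_scales(seasonal: SeasonalSeries, config: TempModelConfig) -> tuple[float, float]:
    if config.scale == "mean":
        s_e = seasonal.early.baseline
        s_l = seasonal.late.baseline
    else:
        s_e = float(seasonal.early.values.std(ddof=1))
        s_l = float(seasonal.late.values.std(ddof=1))
    if s_e <= 0 or s_l <= 0:
        raise DomainError(
            f"non-positive fitness scale ({config.scale}); use the iasd scale for "
            "series whose mean is not positive"
        )
    return s_e, s_l


def temp_geometric_mean_fitness(
    seasonal: SeasonalSeries,
    strategy: TempStrategy,
    config: TempModelConfig | None = None,
) -> TempStrategyFitness:
    """Geometric-mean fitness over all usable season observations."""
    config = config or TempModelConfig()
    if seasonal.n_years < 6:
        raise InsufficientDataError("need at least 6 shared years for the temperature model")
    usable = _usable_indices(seasonal)
    if len(usable) == 0:
        raise InsufficientDataError("no year has a consecutive prior year")
    s_e, s_l = _fitness_scales(seasonal, config)
    eps = config.fitness_floor
    logs = []
    for t in usable:
        e_hat, l_hat = predict_season_phenotypes(seasonal, strategy, int(t))
        w_e = max(eps, 1.0 - abs(e_hat - seasonal.early.values[t]) / s_e)
        w_l = max(eps, 1.0 - abs(l_hat - seasonal.late.values[t]) / s_l)
        logs.extend((math.log(w_e), math.log(w_l)))
    return TempStrategyFitness(strategy, math.exp(float(np.mean(logs))), 2 * len(usable))


@dataclass(frozen=True)
class TempLandscape:
    """Grid evaluation of the temperature model at one site."""

    site_id: str
    variant: str
    strategies: tuple[TempStrategy, ...]
    gm_fitness: np.ndarray  # aligned with strategies
    optimum: TempStrategyFitness
    n_obs: int

    @property
    def total_tgp(self) -> float:
        return self.optimum.strategy.total_tgp

    @property
    def max_tgp(self) -> float:
        return self.optimum.strategy.max_tgp

    @property
    def min_tgp(self) -> float:
        return self.optimum.strategy.min_tgp


def evaluate_temp_landscape(
    seasonal: SeasonalSeries, config: TempModelConfig | None = None
) -> TempLandscape:
    """Evaluate every strategy on the grid and pick the optimum.

    Residual variant detrends the early and late series independently
    (mean preserved).  Ties are broken by minimal total |plasticity|,
    then lexicographically over the parameter tuple.
    """
    config = config or TempModelConfig()
    work = seasonal
    if config.variant == "residual":
        e_dt, _ = detrend_linear(seasonal.early)
        l_dt, _ = detrend_linear(seasonal.late)
        work = SeasonalSeries(seasonal.site_id, e_dt, l_dt)
    if work.n_years < 6:
        raise InsufficientDataError("need at least 6 shared years for the temperature model")
    usable = _usable_indices(work)
    if len(usable) == 0:
        raise InsufficientDataError("no year has a consecutive prior year")
    s_e, s_l = _fitness_scales(work, config)
    eps = config.fitness_floor

    strategies = temp_strategy_grid(config.values)
    ebar, lbar = work.early.baseline, work.late.baseline
    de = work.early.values - ebar
    dl = work.late.values - lbar
    de_prev, dl_prev, de_cur = de[usable - 1], dl[usable - 1], de[usable]
    de_t, dl_t = de[usable], dl[usable]
    vals = np.array(sorted(set(config.values)))
    k = len(vals)

    # the early phenotype depends only on (m_ee, m_le) and the late one on
    # (m_el, m_ll, w), so per-season log-fitness sums factorize: compute
    # k^2 + k^3 sums instead of k^5 and combine by broadcasting
    e_dev = vals[:, None, None] * de_prev + vals[None, :, None] * dl_prev  # (ee, le, t)
    e_ls = np.log(np.maximum(eps, 1.0 - np.abs(e_dev - de_t) / s_e)).sum(axis=-1)
    l_dev = (
        vals[:, None, None, None] * de_prev
        + vals[None, :, None, None] * dl_prev
        + vals[None, None, :, None] * de_cur
    )  # (el, ll, w, t)
    l_ls = np.log(np.maximum(eps, 1.0 - np.abs(l_dev - dl_t) / s_l)).sum(axis=-1)
    # combined axes ordered (ee, el, le, ll, w) to match temp_strategy_grid
    total = (
        e_ls[:, None, :, None, None] + l_ls[None, :, None, :, :]
    )  # (ee, el, le, ll, w)
    n_obs_total = 2 * len(usable)
    gm = np.exp(total / n_obs_total).ravel()

    params = np.array([s.as_tuple() for s in strategies])  # (S, 5)
    best = gm.max()
    tied = np.flatnonzero(gm == best)
    key = lambda i: (np.abs(params[i]).sum(), strategies[i].as_tuple())
    winner = min(tied, key=key)
    n_obs = 2 * len(usable)
    optimum = TempStrategyFitness(strategies[winner], float(gm[winner]), n_obs)
    return TempLandscape(
        site_id=seasonal.site_id,
        variant=config.variant,
        strategies=tuple(strategies),
        gm_fitness=gm,
        optimum=optimum,
        n_obs=n_obs,
    )
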