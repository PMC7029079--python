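"""Precipitation optimality model.

A strategy (m, g) predicts the year-t phenotype from the long-term mean
plus a weighted combination of the previous three years' deviations:

    P_hat_t = Pbar + m * (d_{t-1} + g*d_{t-2} + g^2*d_{t-3}) / (1 + g + g^2)

with d_k = P_k - Pbar.  Yearly fitness decays linearly with the scaled
distance between phenotype and the realized value, floored at a small
epsilon so the geometric mean stays defined; strategies are ranked by
geometric-mean fitness over all usable years.  With m = 0 the phenotype
map is identical for every g, so (0, g) is canonicalized to (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError
from .series import AnnualSeries
from .tstats import SiteClimateSummary, detrend_linear

_GRID_TOL = 1e-9

VARIANTS = ("raw", "residual")


def _default_m_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(-10, 11) * 0.1, 10))


def _default_g_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0, 11) * 0.1, 10))


@dataclass(frozen=True)
class PrecipStrategy:
    """One plasticity genotype: parental-effect slope m and persistence g.

    Constructed in canonical form: m = 0 forces g = 0.
    """

    m: float
    g: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.m <= 1.0:
            raise DomainError(f"m must lie in [-1, 1], got {self.m}")
        if not 0.0 <= self.g <= 1.0:
            raise DomainError(f"g must lie in [0, 1], got {self.g}")
        if self.m == 0.0 and self.g != 0.0:
            object.__setattr__(self, "g", 0.0)

    @property
    def lag_weights(self) -> np.ndarray:
        """Normalized weights of the previous three years' deviations."""
        w = np.array([1.0, self.g, self.g**2])
        return w / w.sum()


@dataclass(frozen=True)
class StrategyFitness:
    strategy: PrecipStrategy
    gm_fitness: float
    n_years_used: int


@dataclass(frozen=True)
class ModelConfig:
    """Grid, floor and variant switches for the precipitation model."""

    fitness_floor: float = 1e-6
    m_grid: tuple[float, ...] = field(default_factory=_default_m_grid)
    g_grid: tuple[float, ...] = field(default_factory=_default_g_grid)
    variant: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_grid", tuple(float(v) for v in self.m_grid))
        object.__setattr__(self, "g_grid", tuple(float(v) for v in self.g_grid))
        if not 0.0 < self.fitness_floor < 0.1:
            raise DomainError("fitness_floor must lie in (0, 0.1)")
        for name, grid in (("m_grid", self.m_grid), ("g_grid", self.g_grid)):
            if not grid or list(grid) != sorted(grid):
                raise DomainError(f"{name} must be nonempty and sorted")
        if self.variant not in VARIANTS:
            raise DomainError(f"variant must be one of {VARIANTS}")


def _usable_indices(series: AnnualSeries) -> np.ndarray:
    """Indices t with three consecutive prior years available."""
    years = series.years
    idx = np.arange(3, len(years))
    ok = (years[idx] - years[idx - 3]) == 3
    return idx[ok]


def predict_precip_phenotype(
    series: AnnualSeries, strategy: PrecipStrategy, t: int
) -> float:
    """Phenotype for year index ``t`` (0-based position in the series)."""
    if t < 3 or t >= series.n_years:
        raise IndexError(f"year index {t} lacks three prior years")
    if series.years[t] - series.years[t - 3] != 3:
        raise IndexError(f"year index {t} has a gap in its three prior years")
    pbar = series.baseline
    d = series.values[t - 3 : t] - pbar  # [d_{t-3}, d_{t-2}, d_{t-1}]
    w = strategy.lag_weights  # [w1 (parent), w2, w3]
    return float(pbar + strategy.m * (d[::-1] @ w))


def fitness_year(
    phenotype: float, actual: float, baseline: float, eps: float = 1e-6
) -> float:
    """Linear-cost fitness, floored: max(eps, 1 - |phenotype - actual| / baseline)."""
    if baseline <= 0:
        raise DomainError("baseline must be positive")
    return max(eps, 1.0 - abs(phenotype - actual) / baseline)


def geometric_mean_fitness(
    series: AnnualSeries, strategy: PrecipStrategy, config: ModelConfig | None = None
) -> StrategyFitness:
    """Geometric-mean fitness of one strategy over all usable years.

    Computed as exp(mean(log w_t)) to avoid underflow over long series.
    """
    config = config or ModelConfig()
    if series.n_years < 8:
        raise InsufficientDataError("need at least 8 years for the precipitation model")
    usable = _usable_indices(series)
    if len(usable) == 0:
        raise InsufficientDataError("no year has three consecutive prior years")
    pbar = series.baseline
    logs = [
        math.log(
            fitness_year(
                predict_precip_phenotype(series, strategy, t),
                series.values[t],
                pbar,
                config.fitness_floor,
            )
        )
        for t in usable
    ]
    return StrategyFitness(strategy, math.exp(float(np.mean(logs))), len(usable))


@dataclass(frozen=True)
class FitnessLandscape:
    """Geometric-mean fitness over the full (m, g) lattice at one site."""

    site_id: str
    variant: str
    m_grid: tuple[float, ...]
    g_grid: tuple[float, ...]
    fitness: np.ndarray  # shape (len(m_grid), len(g_grid)), m=0 column constant
    grid: tuple[StrategyFitness, ...]  # canonical lattice points only
    optimum: StrategyFitness
    local_maxima: tuple[StrategyFitness, ...]
    n_years_used: int

    @property
    def n_local_maxima(self) -> int:
        return len(self.local_maxima)


def _fitness_matrix(
    series: AnnualSeries, config: ModelConfig
) -> tuple[np.ndarray, int]:
    """Vectorized W over the full m x g lattice (m=0 column filled constant)."""
    usable = _usable_indices(series)
    if len(usable) == 0:
        raise InsufficientDataError("no year has three consecutive prior years")
    pbar = series.baseline
    if pbar <= 0:
        raise DomainError("series baseline must be positive for the fitness scale")
    d = series.values - pbar
    d1, d2, d3 = d[usable - 1], d[usable - 2], d[usable - 3]
    dt = d[usable]
    m = np.asarray(config.m_grid)
    g = np.asarray(config.g_grid)
    # weighted deviation per g: (n_g, T)
    denom = 1.0 + g + g**2
    D = (d1[None, :] + g[:, None] * d2[None, :] + (g**2)[:, None] * d3[None, :]) / denom[:, None]
    # phenotype deviation per (m, g, t): m * D; fitness vs actual deviation dt
    diff = np.abs(m[:, None, None] * D[None, :, :] - dt[None, None, :])
    w = np.maximum(config.fitness_floor, 1.0 - diff / pbar)
    W = np.exp(np.log(w).mean(axis=2))
    # m = 0 rows are analytically identical for all g; enforce exactly
    zero_rows = np.isclose(m, 0.0, atol=_GRID_TOL)
    if zero_rows.any():
        w0 = np.maximum(config.fitness_floor, 1.0 - np.abs(dt) / pbar)
        W[zero_rows, :] = np.exp(np.log(w0).mean())
    return W, len(usable)


def _local_maxima_components(W: np.ndarray) -> list[list[tuple[int, int]]]:
    """Connected components of cells >= all their 8 lattice neighbors.

    Adjacent local maxima are necessarily equal-valued, so merging
    plateaus reduces to taking 8-connected components of the maxima mask.
    """
    pad = np.full((W.shape[0] + 2, W.shape[1] + 2), -np.inf)
    pad[1:-1, 1:-1] = W
    neigh = np.full_like(W, -np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh = np.maximum(neigh, pad[1 + di : 1 + di + W.shape[0], 1 + dj : 1 + dj + W.shape[1]])
    mask = W >= neigh
    # connected components (8-connectivity) of the mask
    cells = {(int(i), int(j)) for i, j in np.argwhere(mask)}
    components: list[list[tuple[int, int]]] = []
    while cells:
        seed = cells.pop()
        comp = [seed]
        frontier = [seed]
        while frontier:
            i, j = frontier.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (i + di, j + dj)
                    if nb in cells:
                        cells.remove(nb)
                        comp.append(nb)
                        frontier.append(nb)
        components.append(comp)
    return components


def _tie_break_key(m: float, g: float) -> tuple:
    """Parsimony ordering: smallest |m|, then smallest g, then lexicographic."""
    return (abs(m), g, m, g)


def evaluate_precip_landscape(
    series: AnnualSeries, config: ModelConfig | None = None
) -> FitnessLandscape:
    """Full-lattice landscape with optimum and merged local maxima.

    In the residual variant the series is linearly detrended (mean
    preserved) before evaluation.
    """
    config = config or ModelConfig()
    work = series
    if config.variant == "residual":
        work, _ = detrend_linear(series)
    if work.n_years < 8:
        raise InsufficientDataError("need at least 8 years for the precipitation model")
    W, n_used = _fitness_matrix(work, config)
    m_grid, g_grid = config.m_grid, config.g_grid

    def strat(i: int, j: int) -> PrecipStrategy:
        return PrecipStrategy(m_grid[i], g_grid[j])

    # canonical lattice points: one entry for m = 0, all g for m != 0
    entries: list[StrategyFitness] = []
    for i, m in enumerate(m_grid):
        if abs(m) < _GRID_TOL:
            entries.append(StrategyFitness(strat(i, 0), float(W[i, 0]), n_used))
        else:
            for j in range(len(g_grid)):
                entries.append(StrategyFitness(strat(i, j), float(W[i, j]), n_used))

    # local maxima on the full lattice, plateau components merged to one
    # representative each (parsimony tie-break inside a component)
    maxima: list[StrategyFitness] = []
    for comp in _local_maxima_components(W):
        i, j = min(comp, key=lambda c: _tie_break_key(m_grid[c[0]], g_grid[c[1]]))
        maxima.append(StrategyFitness(strat(i, j), float(W[i, j]), n_used))
    maxima.sort(key=lambda sf: _tie_break_key(sf.strategy.m, sf.strategy.g))

    best_w = max(sf.gm_fitness for sf in entries)
    candidates = [sf for sf in entries if sf.gm_fitness == best_w]
    optimum = min(candidates, key=lambda sf: _tie_break_key(sf.strategy.m, sf.strategy.g))
    # the optimum is by construction one of the maxima components
    if not any(
        sf.strategy == optimum.strategy for sf in maxima
    ):  # pragma: no cover - defensive
        maxima.append(optimum)
        maxima.sort(key=lambda sf: _tie_break_key(sf.strategy.m, sf.strategy.g))
    return FitnessLandscape(
        site_id=series.site_id,
        variant=config.variant,
        m_grid=m_grid,
        g_grid=g_grid,
        fitness=W,
        grid=tuple(entries),
        optimum=optimum,
        local_maxima=tuple(maxima),
        n_years_used=n_used,
    )


def bimodality_condition(summary: SiteClimateSummary) -> bool:
    """Flag autocorrelation structures prone to bimodal landscapes.

    True iff the lag-1 autocorrelation points the opposite way from the
    mean of the lag-2 and lag-3 partial autocorrelations and is smaller
    in magnitude than that mean.
    """
    acf1 = summary.acf_at(1)
    pacf2 = summary.pacf_at(2)
    pacf3 = summary.pacf_at(3)
    if not (np.isfinite(acf1) and np.isfinite(pacf2) and np.isfinite(pacf3)):
        raise DomainError("bimodality condition needs acf1, pacf2 and pacf3")
    tail = (pacf2 + pacf3) / 2.0
    return bool(np.sign(acf1) != np.sign(tail) and abs(acf1) < abs(tail))
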