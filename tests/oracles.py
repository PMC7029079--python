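"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized/recursive code paths:
geometric means are plain per-year products, partial autocorrelations
come from explicit regression algebra on the correlation matrix, and
aggregation oracles loop over raw monthly records.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz


def cropped_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Plain Pearson correlation of overlapping windows, lags 1..max_lag."""
    x = np.asarray(x, float)
    return np.array(
        [np.corrcoef(x[:-k], x[k:])[0, 1] for k in range(1, max_lag + 1)]
    )


def pacf_by_regression(rho: np.ndarray) -> np.ndarray:
    """Partial autocorrelations by explicit regression on shorter lags.

    For each lag k, build the (k+1)x(k+1) Toeplitz correlation matrix of
    (x_t, x_{t-1}, ..., x_{t-k}) from the ACF sequence, regress both
    endpoints on the intermediate lags (normal-equation solve), and
    correlate the regression residuals.
    """
    rho = np.asarray(rho, float)
    p = len(rho)
    out = np.empty(p)
    full = np.concatenate(([1.0], rho))
    for k in range(1, p + 1):
        R = toeplitz(full[: k + 1])
        if k == 1:
            out[0] = R[0, 1]
            continue
        mid = list(range(1, k))
        Rmm = R[np.ix_(mid, mid)]
        beta_a = np.linalg.solve(Rmm, R[mid, 0])
        beta_b = np.linalg.solve(Rmm, R[mid, k])
        var_a = R[0, 0] - R[0, mid] @ beta_a
        var_b = R[k, k] - R[k, mid] @ beta_b
        cov_ab = R[0, k] - R[0, mid] @ beta_b
        out[k - 1] = cov_ab / np.sqrt(var_a * var_b)
    return out


def precip_gm_direct(series, m: float, g: float, eps: float = 1e-6) -> float:
    """Naive per-year product geometric mean for the precipitation model."""
    pbar = float(np.mean(series.values))
    years = series.years
    ws = []
    for t in range(3, len(years)):
        if years[t] - years[t - 3] != 3:
            continue
        d1 = series.values[t - 1] - pbar
        d2 = series.values[t - 2] - pbar
        d3 = series.values[t - 3] - pbar
        phen = pbar + m * (d1 + g * d2 + g * g * d3) / (1 + g + g * g)
        w = 1.0 - abs(phen - series.values[t]) / pbar
        ws.append(max(eps, w))
    prod = 1.0
    for w in ws:
        prod *= w
    return prod ** (1.0 / len(ws))


def temp_gm_direct(pair, params, eps: float = 1e-6, scale: str = "mean") -> float:
    """Naive per-season product geometric mean for the temperature model."""
    m_ee, m_el, m_le, m_ll, w = params
    e, l = pair.early.values, pair.late.values
    ebar, lbar = float(np.mean(e)), float(np.mean(l))
    if scale == "mean":
        s_e, s_l = ebar, lbar
    else:
        s_e, s_l = float(np.std(e, ddof=1)), float(np.std(l, ddof=1))
    years = pair.years
    ws = []
    for t in range(1, len(years)):
        if years[t] - years[t - 1] != 1:
            continue
        e_hat = ebar + m_ee * (e[t - 1] - ebar) + m_le * (l[t - 1] - lbar)
        l_hat = (
            lbar + m_el * (e[t - 1] - ebar) + m_ll * (l[t - 1] - lbar) + w * (e[t] - ebar)
        )
        ws.append(max(eps, 1.0 - abs(e_hat - e[t]) / s_e))
        ws.append(max(eps, 1.0 - abs(l_hat - l[t]) / s_l))
    prod = 1.0
    for wv in ws:
        prod *= wv
    return prod ** (1.0 / len(ws))


def hydro_total_direct(records: dict, year: int) -> float | None:
    """Brute-force hydrologic-year sum from a {(year, month): ppt} mapping."""
    months = [(year - 1, m) for m in (10, 11, 12)] + [(year, m) for m in range(1, 10)]
    vals = [records.get(k) for k in months]
    if any(v is None for v in vals):
        return None
    return float(sum(vals))
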