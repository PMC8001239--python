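"""Screening and transformation steps applied ahead of estimation: deflation
to real per-capita terms, Phillips-Perron stationarity screening, differencing,
Hodrick-Prescott trend/cycle extraction and weekly-to-monthly averaging."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from statsmodels.tsa.adfvalues import mackinnoncrit

from .synthetic_data import Calendar

__all__ = [
    "PPResult",
    "TrendCycle",
    "deflate_per_capita",
    "hp_filter",
    "pp_test",
    "difference",
    "aggregate_weekly_to_monthly",
    "newey_west_bandwidth",
    "apply_recipe",
]

MONTHLY_HP_LAMBDA = 14400.0


def deflate_per_capita(expenditure, population, price_index, base_period: int):
    """Real per-capita series: (expenditure / population) scaled to base prices.

    ``base_period`` is a positional index into ``price_index``; the output at t
    is (expenditure_t / population_t) * price_base / price_t.
    """
    expenditure = np.asarray(expenditure, dtype=float)
    population = np.asarray(population, dtype=float)
    price_index = np.asarray(price_index, dtype=float)
    if not (expenditure.shape == population.shape == price_index.shape):
        raise ValueError("expenditure, population and price_index must be aligned")
    bad_pop = np.flatnonzero(population <= 0)
    if bad_pop.size:
        raise ValueError(f"non-positive population at period {bad_pop[0]}")
    bad_price = np.flatnonzero(price_index <= 0)
    if bad_price.size:
        raise ValueError(f"non-positive price index at period {bad_price[0]}")
    if not 0 <= base_period < len(price_index):
        raise ValueError(f"base_period {base_period} outside the sample")
    return expenditure / population * (price_index[base_period] / price_index)


@dataclass(frozen=True)
class TrendCycle:
    """HP decomposition; trend + cycle reproduces the input exactly."""

    trend: np.ndarray
    cycle: np.ndarray
    smoothing: float


def hp_filter(series, smoothing: float) -> TrendCycle:
    """Hodrick-Prescott filter via the sparse pentadiagonal normal equations.

    The trend solves (I + lambda K'K) tau = y with K the second-difference
    operator; lambda = 14400 is the monthly-frequency convention used for the
    regression variables.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    t = y.shape[0]
    if t < 4:
        raise ValueError("series must have at least 4 observations")
    if smoothing <= 0:
        raise ValueError("smoothing parameter must be positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains missing or non-finite values")
    k = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(t - 2, t), format="csc")
    a = sp.eye(t, format="csc") + smoothing * (k.T @ k)
    trend = spla.spsolve(a, y)
    return TrendCycle(trend=trend, cycle=y - trend, smoothing=float(smoothing))


def difference(series, order: int = 1) -> np.ndarray:
    """Repeated first differences; output is shorter by ``order``."""
    y = np.asarray(series, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= y.shape[0]:
        raise ValueError(f"order {order} must be smaller than the series length {y.shape[0]}")
    return np.diff(y, n=order)


def newey_west_bandwidth(nobs: int) -> int:
    """Automatic lag truncation floor(4 * (T/100)^(2/9))."""
    return int(math.floor(4.0 * (nobs / 100.0) ** (2.0 / 9.0)))


@dataclass(frozen=True)
class PPResult:
    """Phillips-Perron statistics for one series.

    ``z_tau`` is the studentized statistic compared against Dickey-Fuller
    critical values; ``z_rho`` is the normalized-bias form T(rho - 1) with the
    same serial-correlation correction.
    """

    z_tau: float
    z_rho: float
    bandwidth: int
    deterministic_spec: str
    crit_5pct: float
    reject_5pct: bool


_SPEC_TO_REGRESSION = {"none": "n", "constant": "c", "constant+trend": "ct"}


def pp_test(series, deterministic_spec: str = "constant", bandwidth: int | None = None) -> PPResult:
    """Phillips-Perron unit-root test.

    Fits y_t on [deterministics, y_{t-1}] by OLS and corrects the rho-based
    statistics with a Bartlett-kernel (Newey-West) long-run variance estimate;
    ``bandwidth=None`` selects the automatic rule.  At bandwidth zero the
    correction vanishes and z_tau equals the plain Dickey-Fuller t-statistic.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if y.shape[0] < 20:
        raise ValueError("series must have at least 20 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains missing or non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("constant series: the unit-root regression is degenerate")
    if deterministic_spec not in _SPEC_TO_REGRESSION:
        raise ValueError(f"deterministic_spec must be one of {sorted(_SPEC_TO_REGRESSION)}")

    y_lag = y[:-1]
    y_now = y[1:]
    t = y_now.shape[0]
    cols = [y_lag]
    if deterministic_spec in ("constant", "constant+trend"):
        cols.append(np.ones(t))
    if deterministic_spec == "constant+trend":
        cols.append(np.arange(1, t + 1, dtype=float))
    x = np.column_stack(cols)
    k = x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y_now)
    resid = y_now - x @ beta
    rho = beta[0]
    s2 = resid @ resid / (t - k)
    se_rho = math.sqrt(s2 * xtx_inv[0, 0])
    t_rho = (rho - 1.0) / se_rho

    if bandwidth is None:
        bandwidth = newey_west_bandwidth(t)
    if bandwidth < 0:
        raise ValueError("bandwidth must be non-negative")
    gamma0 = resid @ resid / t
    lam = gamma0
    for j in range(1, bandwidth + 1):
        w = 1.0 - j / (bandwidth + 1.0)
        lam += 2.0 * w * (resid[j:] @ resid[:-j]) / t
    lam = max(lam, 1e-300)

    s = math.sqrt(s2)
    z_tau = math.sqrt(gamma0 / lam) * t_rho - (lam - gamma0) * t * se_rho / (2.0 * math.sqrt(lam) * s)
    z_rho = t * (rho - 1.0) - 0.5 * (lam - gamma0) * (t * se_rho / s) ** 2

    crit = float(mackinnoncrit(N=1, regression=_SPEC_TO_REGRESSION[deterministic_spec], nobs=t)[1])
    return PPResult(
        z_tau=float(z_tau),
        z_rho=float(z_rho),
        bandwidth=int(bandwidth),
        deterministic_spec=deterministic_spec,
        crit_5pct=crit,
        reject_5pct=bool(z_tau < crit),
    )


def aggregate_weekly_to_monthly(weekly_series, calendar: Calendar) -> pd.Series:
    """Monthly series of arithmetic means over the weeks starting in each month."""
    y = np.asarray(weekly_series, dtype=float)
    if y.shape[0] != calendar.n_weeks:
        raise ValueError(
            f"series length {y.shape[0]} does not match the calendar's {calendar.n_weeks} weekly bins"
        )
    months = calendar.week_months()
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for value, month in zip(y, months):
        sums[month] = sums.get(month, 0.0) + value
        counts[month] = counts.get(month, 0) + 1
    out = np.array([sums[m] / counts[m] for m in calendar.month_labels if m in sums])
    labels = [m for m in calendar.month_labels if m in sums]
    idx = pd.PeriodIndex([pd.Period(year=yy, month=mm, freq="M") for yy, mm in labels], name="month")
    return pd.Series(out, index=idx)


def apply_recipe(
    table: pd.DataFrame, recipe: dict[str, str], hp_lambda: float = MONTHLY_HP_LAMBDA
) -> pd.DataFrame:
    """Column-wise stationarity transform: {hp_cycle | difference | none}.

    Differenced columns lose their first observation; the output is the
    intersection of the transformed indexes with any all-NaN head rows dropped.
    """
    out = {}
    for col in table.columns:
        how = recipe.get(col, "none")
        values = table[col].to_numpy()
        if how == "hp_cycle":
            out[col] = pd.Series(hp_filter(values, hp_lambda).cycle, index=table.index)
        elif how == "difference":
            out[col] = pd.Series(np.diff(values), index=table.index[1:])
        elif how == "none":
            out[col] = table[col]
        else:
            raise ValueError(f"unknown transform {how!r} for column {col!r}")
    return pd.DataFrame(out).dropna()
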