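"""Seeded generators for weekly expenditure panels with known spillover
structure and monthly covariates with trend-plus-cycle anatomy.

Everything here is ground truth for the estimation stages: panels come from a
VAR whose coefficients (possibly drifting) and innovation covariance are known,
and ``true_connectedness`` pushes those true parameters through the same
decomposition code path used in estimation, giving recovery tests an oracle.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import connectedness as _conn
from .tvp_var import VARParams, spectral_radius

__all__ = [
    "InvalidConfigError",
    "Calendar",
    "make_calendar",
    "SimulationConfig",
    "ExpenditurePanel",
    "CovariateConfig",
    "generate_expenditure_panel",
    "generate_covariates",
    "true_connectedness",
    "random_stationary_coefficients",
    "random_innovation_cov",
    "drifting_coefficients",
    "two_regime_coefficients",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = (
    "young_dep",
    "old_dep",
    "leading_index",
    "medical_price",
    "primary_care_share",
    "baumol",
)


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class Calendar:
    """Weekly 7-day bins anchored at the study start plus the covered months.

    Bins are consecutive and non-overlapping; the final bin may cover fewer
    than 7 in-range days when the span is not a multiple of 7.  Each week
    belongs to the month containing its start date.
    """

    start_date: dt.date
    end_date: dt.date
    week_starts: tuple[dt.date, ...]
    month_labels: tuple[tuple[int, int], ...]

    @property
    def n_weeks(self) -> int:
        return len(self.week_starts)

    @property
    def n_months(self) -> int:
        return len(self.month_labels)

    def week_months(self) -> tuple[tuple[int, int], ...]:
        """Month label (year, month) owning each weekly bin."""
        return tuple((d.year, d.month) for d in self.week_starts)

    def week_index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([pd.Timestamp(d) for d in self.week_starts], name="week_start")

    def month_index(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(
            [pd.Period(year=y, month=m, freq="M") for y, m in self.month_labels], name="month"
        )


def make_calendar(start_date, end_date, keep_partial_week: bool = True) -> Calendar:
    """Build the weekly/monthly calendar for an inclusive date range.

    The bin count is ceil(inclusive day count / 7); ``keep_partial_week=False``
    drops a trailing bin shorter than 7 days.  Months run from the start month
    through the end month inclusive.
    """
    start = _as_date(start_date)
    end = _as_date(end_date)
    if start >= end:
        raise ValueError(f"start_date {start} must precede end_date {end}")
    n_days = (end - start).days + 1
    n_weeks = math.ceil(n_days / 7)
    if not keep_partial_week and n_days % 7 != 0:
        n_weeks -= 1
    week_starts = tuple(start + dt.timedelta(days=7 * i) for i in range(n_weeks))
    months = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        months.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return Calendar(start, end, week_starts, tuple(months))


# ---------------------------------------------------------------------------
# expenditure panel
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Truth for a weekly expenditure panel.

    ``coefficients`` is either a constant stack with shape (p, N, N) or a
    per-period path with shape (T, p, N, N), T the number of weekly bins.
    """

    calendar: Calendar
    coefficients: np.ndarray
    innovation_cov: np.ndarray
    n_series: int = 18
    intercept: np.ndarray | None = None
    seed: int = 0
    burn_in: int = 200
    level: float = 0.0
    series_prefix: str = "CCS"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        if self.intercept is not None:
            self.intercept = np.asarray(self.intercept, dtype=float)

    @property
    def var_order(self) -> int:
        return self.coefficients.shape[-3]

    def coefficient_path(self) -> np.ndarray:
        """Per-period stacks, shape (T, p, N, N)."""
        t = self.calendar.n_weeks
        if self.coefficients.ndim == 3:
            return np.broadcast_to(self.coefficients, (t,) + self.coefficients.shape)
        if self.coefficients.ndim == 4:
            if self.coefficients.shape[0] != t:
                raise InvalidConfigError(
                    f"coefficient path has {self.coefficients.shape[0]} periods, "
                    f"calendar has {t} weekly bins"
                )
            return self.coefficients
        raise InvalidConfigError("coefficients must have shape (p, N, N) or (T, p, N, N)")

    def validate(self) -> None:
        n = self.n_series
        path = self.coefficient_path()
        if path.shape[-1] != n or path.shape[-2] != n:
            raise InvalidConfigError(
                f"coefficient stacks are {path.shape[-2]}x{path.shape[-1]}, expected {n}x{n}"
            )
        if self.innovation_cov.shape != (n, n):
            raise InvalidConfigError("innovation_cov must be N x N")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T, atol=1e-10):
            raise InvalidConfigError("innovation_cov must be symmetric")
        try:
            np.linalg.cholesky(self.innovation_cov)
        except np.linalg.LinAlgError as exc:
            raise InvalidConfigError("innovation_cov must be positive definite") from exc
        if self.coefficients.ndim == 3:
            r = spectral_radius(self.coefficients)
            if r >= 1.0:
                raise InvalidConfigError(
                    f"non-stationary coefficient stack: spectral radius {r:.4f} >= 1"
                )
        else:
            for t in range(path.shape[0]):
                r = spectral_radius(path[t])
                if r >= 1.0:
                    raise InvalidConfigError(
                        f"non-stationary coefficient stack at period {t}: "
                        f"spectral radius {r:.4f} >= 1"
                    )
        if self.burn_in < 0:
            raise InvalidConfigError("burn_in must be non-negative")


@dataclass
class ExpenditurePanel:
    """Weekly panel of simulated (or loaded) expenditure series."""

    calendar: Calendar
    values: pd.DataFrame  # index = week starts, one column per series

    @property
    def series_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_series(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index = out.index.strftime("%Y-%m-%d")
        # full precision so a CSV round trip reproduces estimation bit-for-bit
        out.to_csv(path, index_label="week_start", float_format="%.17g")

    @classmethod
    def from_csv(cls, path, keep_partial_week: bool = True) -> "ExpenditurePanel":
        values = pd.read_csv(
            path, index_col="week_start", parse_dates=True, float_precision="round_trip"
        )
        if values.isna().any().any():
            raise ValueError("panel CSV contains missing values")
        start = values.index[0].date()
        last = values.index[-1].date()
        cal = make_calendar(start, last + dt.timedelta(days=6), keep_partial_week=keep_partial_week)
        if cal.n_weeks != len(values):
            raise ValueError("panel rows are not consecutive 7-day bins")
        return cls(calendar=cal, values=values)


def generate_expenditure_panel(config: SimulationConfig) -> ExpenditurePanel:
    """Simulate the panel from the VAR recursion with Gaussian innovations.

    A burn-in of ``config.burn_in`` periods (driven by the first coefficient
    stack) is discarded before the first retained week; the draw is fully
    determined by ``config.seed``.
    """
    config.validate()
    cal = config.calendar
    n = config.n_series
    path = config.coefficient_path()
    p = config.var_order
    t_keep = cal.n_weeks
    intercept = config.intercept if config.intercept is not None else np.zeros(n)
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(config.innovation_cov)
    total = config.burn_in + t_keep
    shocks = rng.standard_normal((total, n)) @ chol.T
    y = np.zeros((total + p, n))
    for t in range(total):
        stack = path[0] if t < config.burn_in else path[t - config.burn_in]
        acc = intercept + shocks[t]
        for j in range(p):
            acc = acc + stack[j] @ y[t + p - 1 - j]
        y[t + p] = acc
    kept = y[p + config.burn_in :] + config.level
    cols = [f"{config.series_prefix}{i + 1}" for i in range(n)]
    frame = pd.DataFrame(kept, index=cal.week_index(), columns=cols)
    return ExpenditurePanel(calendar=cal, values=frame)


def random_stationary_coefficients(
    n_series: int, order: int, rng: np.random.Generator, target_radius: float = 0.6
) -> np.ndarray:
    """Random (p, N, N) stack rescaled to the requested companion radius."""
    stack = rng.standard_normal((order, n_series, n_series)) / np.sqrt(n_series)
    return _shrink_to_radius(stack, target_radius)


def _shrink_to_radius(stack: np.ndarray, target: float, tol: float = 1e-10) -> np.ndarray:
    lo, hi = 0.0, 1.0
    base = stack / max(spectral_radius(stack), 1e-12)
    # scale lag j by s**j so the companion radius scales linearly in s
    p = stack.shape[0]
    def scaled(s):
        return np.stack([base[j] * s ** (j + 1) for j in range(p)])
    while spectral_radius(scaled(hi)) < target:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spectral_radius(scaled(mid)) < target:
            lo = mid
        else:
            hi = mid
    return scaled(lo)


def random_innovation_cov(
    n_series: int, rng: np.random.Generator, correlation: float = 0.3
) -> np.ndarray:
    """Random SPD covariance: equicorrelation backbone plus a Wishart tilt."""
    base = (1.0 - correlation) * np.eye(n_series) + correlation * np.ones((n_series, n_series))
    a = rng.standard_normal((n_series, 2 * n_series)) / np.sqrt(2 * n_series)
    tilt = a @ a.T
    cov = 0.7 * base + 0.3 * tilt
    return 0.5 * (cov + cov.T)


def drifting_coefficients(stack_a: np.ndarray, stack_b: np.ndarray, n_periods: int) -> np.ndarray:
    """Deterministic half-cosine drift from stack_a to stack_b over T periods."""
    stack_a = np.asarray(stack_a, dtype=float)
    stack_b = np.asarray(stack_b, dtype=float)
    w = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_periods) / max(n_periods - 1, 1)))
    return stack_a[None] + w[:, None, None, None] * (stack_b - stack_a)[None]


def two_regime_coefficients(
    stack_a: np.ndarray, stack_b: np.ndarray, n_periods: int, switch_at: int
) -> np.ndarray:
    """Abrupt regime switch from stack_a to stack_b at period ``switch_at``."""
    path = np.empty((n_periods,) + np.asarray(stack_a).shape)
    path[:switch_at] = stack_a
    path[switch_at:] = stack_b
    return path


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateConfig:
    """Monthly covariate generator: deterministic linear trends plus AR(1)
    cycles.  The Baumol variable is assembled from simulated wage growth,
    productivity growth and the healthcare labor share as
    (wage growth - productivity growth) / labor share."""

    seed: int = 0
    cycle_rho: float = 0.7
    cycle_sigma: float = 1.0  # global multiplier on the per-column scales
    young_dep_range: tuple[float, float] = (0.55, 0.34)  # declining by default
    old_dep_range: tuple[float, float] = (0.10, 0.30)  # rising by default
    leading_index_range: tuple[float, float] = (95.0, 105.0)
    medical_price_range: tuple[float, float] = (82.0, 101.0)  # approx base 2014 = 100
    primary_care_range: tuple[float, float] = (0.34, 0.28)
    wage_growth_mean: float = 0.030
    productivity_growth_mean: float = 0.022
    labor_share: float = 0.05
    cycle_scales: dict = field(
        default_factory=lambda: {
            "young_dep": 0.004,
            "old_dep": 0.003,
            "leading_index": 1.2,
            "medical_price": 0.6,
            "primary_care_share": 0.006,
            "wage_growth": 0.004,
            "productivity_growth": 0.004,
        }
    )


def _ar1_cycle(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(n)
    innov = rng.standard_normal(n) * sigma * np.sqrt(max(1.0 - rho**2, 1e-12))
    cycle = np.empty(n)
    cycle[0] = innov[0] / np.sqrt(max(1.0 - rho**2, 1e-12))  # stationary start, sd = sigma
    for t in range(1, n):
        cycle[t] = rho * cycle[t - 1] + innov[t]
    return cycle


def generate_covariates(config: CovariateConfig, calendar: Calendar) -> pd.DataFrame:
    """Monthly covariate table over the calendar's months.

    Columns: young_dep, old_dep, leading_index, medical_price,
    primary_care_share, baumol (plus the wage/productivity/labor-share
    components the Baumol variable is built from).  Deterministic given
    ``config.seed``.
    """
    if calendar.n_months == 0:
        raise InvalidConfigError("calendar has no months")
    if config.labor_share <= 0:
        raise InvalidConfigError(f"labor share must be positive, got {config.labor_share}")
    n = calendar.n_months
    rng = np.random.default_rng(config.seed)
    ramp = np.linspace(0.0, 1.0, n)

    def trended(lo_hi: tuple[float, float], col: str) -> np.ndarray:
        lo, hi = lo_hi
        scale = config.cycle_scales.get(col, 0.0) * config.cycle_sigma
        return lo + (hi - lo) * ramp + _ar1_cycle(rng, n, config.cycle_rho, scale)

    young = trended(config.young_dep_range, "young_dep")
    old = trended(config.old_dep_range, "old_dep")
    leading = trended(config.leading_index_range, "leading_index")
    price = trended(config.medical_price_range, "medical_price")
    primary = np.clip(trended(config.primary_care_range, "primary_care_share"), 0.0, 1.0)
    wage = config.wage_growth_mean + _ar1_cycle(
        rng, n, config.cycle_rho, config.cycle_scales.get("wage_growth", 0.0) * config.cycle_sigma
    )
    productivity = config.productivity_growth_mean + _ar1_cycle(
        rng,
        n,
        config.cycle_rho,
        config.cycle_scales.get("productivity_growth", 0.0) * config.cycle_sigma,
    )
    baumol = (wage - productivity) / config.labor_share
    frame = pd.DataFrame(
        {
            "young_dep": young,
            "old_dep": old,
            "leading_index": leading,
            "medical_price": price,
            "primary_care_share": primary,
            "baumol": baumol,
            "wage_growth": wage,
            "productivity_growth": productivity,
            "labor_share": np.full(n, config.labor_share),
        },
        index=calendar.month_index(),
    )
    if frame.isna().any().any():
        raise InvalidConfigError("generated covariates contain missing values")
    return frame


def true_connectedness(
    coefficients: np.ndarray,
    innovation_cov: np.ndarray,
    horizon: int = 10,
    labels: tuple[str, ...] | None = None,
    **index_kwargs,
):
    """Ground-truth connectedness table from known VAR parameters.

    Runs the true (stack, covariance) pair through the same decomposition code
    path as estimation, so recovery tests compare like with like.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if spectral_radius(coefficients) >= 1.0:
        raise InvalidConfigError("coefficient stack is non-stationary")
    n = coefficients.shape[-1]
    params = VARParams(np.zeros(n), coefficients, np.asarray(innovation_cov, dtype=float))
    fevd = _conn.gfevd(params, horizon, labels=labels)
    return _conn.connectedness_indices(fevd, label="true", **index_kwargs)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def write_covariates_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out.index = out.index.astype(str)
    out.to_csv(path, index_label="month", float_format="%.17g")


def read_covariates_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="month", float_precision="round_trip")
    frame.index = pd.PeriodIndex(frame.index, freq="M", name="month")
    return frame


def write_simulation_metadata(path, seed: int, extra: dict | None = None) -> None:
    payload = {"seed": int(seed)}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
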