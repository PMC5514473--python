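"""Covariate blocks for the admission-count regression.

The model's linear predictor combines a lagged-exposure basis (single-lag,
unconstrained distributed-lag, or lag-stratified constrained), a natural
cubic spline of calendar time for seasonality and long-term trend, natural
cubic splines of same-day temperature and humidity, and day-of-week terms.
All blocks are assembled on calendar dates, so panels with gaps (e.g.
complete-case filtered) are handled correctly: a row enters the analysis
only if its own and all lagged exposures exist on the calendar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import POLLUTANTS, WEATHER_COLS

YEAR_DAYS = 365.25

#: Day-of-week names indexed by pandas weekday (Monday=0).
_DOW_NAMES = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
_DOW_REFERENCE = 5  # Saturday, first day of the Iranian week


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline request: ``df`` basis columns, quantile knots.

    Interior knots sit at equally spaced quantiles of the observed values;
    boundary knots at the observed range.  ``df = 1`` degenerates to the
    linear term (the natural constraints leave nothing else).
    """

    variable: str
    df: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("spline df must be >= 1")


@dataclass(frozen=True)
class LagStructure:
    """Exposure lag basis definition over lags 0..max_lag.

    mode 'single'        one column, the exposure at ``lag``;
    mode 'unconstrained' one column per lag (max_lag + 1 columns);
    mode 'constrained'   one column per lag stratum, each the sum of the
                         exposure over the stratum's lags, so the stratum
                         coefficient is the shared per-unit log rate ratio
                         at every lag in the stratum.
    """

    mode: str = "unconstrained"
    max_lag: int = 7
    lag: int = 0
    strata: tuple[tuple[int, ...], ...] = ((0,), (1, 2), (3, 4, 5, 6, 7))

    def __post_init__(self) -> None:
        if self.mode not in ("single", "unconstrained", "constrained"):
            raise ValueError(f"unknown lag mode {self.mode!r}")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.mode == "single" and not (0 <= self.lag <= self.max_lag):
            raise ValueError("single-lag index must lie in [0, max_lag]")
        if self.mode == "constrained":
            flat = [l for s in self.strata for l in s]
            if sorted(flat) != list(range(self.max_lag + 1)):
                raise ValueError("strata must partition 0..max_lag without overlap")

    @property
    def width(self) -> int:
        if self.mode == "single":
            return 1
        if self.mode == "unconstrained":
            return self.max_lag + 1
        return len(self.strata)

    def column_lags(self) -> list[tuple[int, ...]]:
        """Lag set represented by each exposure column, in column order."""
        if self.mode == "single":
            return [(self.lag,)]
        if self.mode == "unconstrained":
            return [(l,) for l in range(self.max_lag + 1)]
        return [tuple(s) for s in self.strata]


@dataclass
class DesignMatrix:
    """Assembled covariate matrix with block bookkeeping.

    ``X`` has one row per analyzable day (all required lags present) and
    named columns; ``blocks`` maps block names to their column lists and
    ``lag_map`` maps every exposure column back to the lags it represents,
    which effect reporting relies on.
    """

    X: pd.DataFrame
    dates: pd.DatetimeIndex
    blocks: dict[str, list[str]] = field(default_factory=dict)
    lag_map: dict[str, tuple[int, ...]] = field(default_factory=dict)
    pollutant: str = ""
    structure: LagStructure | None = None
    dropped_dates: pd.DatetimeIndex | None = None
    knots: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def exposure_columns(self) -> list[str]:
        return self.blocks.get("exposure", [])


def natural_cubic_basis(
    x: np.ndarray, spec: SplineSpec, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis with exactly ``spec.df`` columns.

    The span of the columns plus an intercept is the natural cubic spline
    space on the knots: piecewise cubic between knots, linear beyond the
    boundary ones.  Built from the truncated-power representation

        N_1 = x,   N_{k+1} = d_k - d_{K-1},
        d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k),

    on K = df + 1 knots (boundary at the range of ``x``, interior at
    equally spaced quantiles).  ``x`` is affinely mapped to [0, 1] first
    for conditioning; the spanned space is unaffected.

    Returns the n x df basis and the knots on the original scale.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if knots is None:
        if len(uniq) < spec.df + 1:
            raise ValueError(
                f"{spec.variable}: df={spec.df} needs at least {spec.df + 1} distinct values"
            )
        if spec.df == 1:
            knots = np.array([uniq[0], uniq[-1]])
        else:
            probs = np.linspace(0.0, 1.0, spec.df + 1)
            knots = np.quantile(x, probs)
            knots[0], knots[-1] = uniq[0], uniq[-1]
            if len(np.unique(knots)) != len(knots):
                raise ValueError(f"{spec.variable}: tied quantile knots; lower df")
    lo, hi = knots[0], knots[-1]
    scale = hi - lo if hi > lo else 1.0
    u = (x - lo) / scale
    xi = (knots - lo) / scale

    if spec.df == 1:
        return u[:, None], knots

    def d(k: int) -> np.ndarray:
        return (np.maximum(u - xi[k], 0.0) ** 3 - np.maximum(u - xi[-1], 0.0) ** 3) / (
            xi[-1] - xi[k]
        )

    cols = [u]
    d_last = d(len(xi) - 2)
    for k in range(len(xi) - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols), knots


def time_spline(
    dates: pd.DatetimeIndex, df_per_year: int = 7, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Seasonality/long-term-trend spline of calendar time.

    The total basis dimension is ``round(df_per_year * n_days / 365.25)``
    where ``n_days`` is the calendar span, so six years at 7 df/year give
    42 columns.  Evaluated on the numeric day offset, hence invariant (as
    a fitted space) to shifting all dates by a constant.
    """
    if df_per_year < 1:
        raise ValueError("df_per_year must be >= 1")
    dates = pd.DatetimeIndex(dates)
    span_days = (dates.max() - dates.min()).days + 1
    total_df = max(int(round(df_per_year * span_days / YEAR_DAYS)), 1)
    if total_df > len(dates) // 2:
        raise ValueError("time spline df exceeds half the available days")
    x = (dates - dates.min()).days.to_numpy(float)
    basis, knots = natural_cubic_basis(x, SplineSpec("time", total_df), knots=knots)
    return basis, knots, total_df


def lag_basis(
    exposure: np.ndarray, structure: LagStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged-exposure design over a consecutive daily series.

    Returns the n x width matrix and a boolean validity mask: a row is
    valid only if every lag it needs exists (index >= max required lag)
    and is non-missing.  Invalid rows carry NaN and are meant for
    exclusion by the caller.
    """
    x = np.asarray(exposure, dtype=float)
    n = len(x)

    def lagged(l: int) -> np.ndarray:
        out = np.full(n, np.nan)
        if l == 0:
            return x.copy()
        out[l:] = x[:-l]
        return out

    cols = []
    for lags in structure.column_lags():
        col = np.zeros(n)
        for l in lags:
            col = col + lagged(l)
        cols.append(col)
    mat = np.column_stack(cols)
    valid = ~np.isnan(mat).any(axis=1)
    return mat, valid


def dow_terms(
    dates: pd.DatetimeIndex,
    mode: str = "indicator",
    holidays: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Day-of-week adjustment block.

    'indicator' (default): six 0/1 columns, Saturday as the reference
    level.  'days-since-holiday': a single integer column counting days
    elapsed since the most recent holiday in the supplied calendar (0 on a
    holiday itself; days before the first holiday count from the series
    start).
    """
    dates = pd.DatetimeIndex(dates)
    if mode == "indicator":
        wd = dates.weekday
        data = {}
        for day in range(7):
            if day == _DOW_REFERENCE:
                continue
            data[f"dow_{_DOW_NAMES[day]}"] = (wd == day).astype(float)
        return pd.DataFrame(data, index=dates)
    if mode == "days-since-holiday":
        if holidays is None:
            raise ValueError("days-since-holiday mode requires a holiday calendar")
        holidays = pd.DatetimeIndex(sorted(pd.DatetimeIndex(holidays)))
        values = []
        for date in dates:
            prior = holidays[holidays <= date]
            anchor = prior[-1] if len(prior) else dates[0]
            values.append((date - anchor).days)
        return pd.DataFrame({"days_since_holiday": np.asarray(values, float)}, index=dates)
    raise ValueError(f"unknown dow mode {mode!r}")


def _require_complete(panel: pd.DataFrame, columns: list[str]) -> None:
    for col in columns:
        bad = panel[col].isna()
        if bad.any():
            date = panel.loc[bad, "date"].iloc[0]
            raise ValueError(f"missing value in column {col!r} on {pd.Timestamp(date).date()}")


def assemble(
    panel: pd.DataFrame,
    pollutant: str,
    structure: LagStructure,
    time_df_per_year: int = 7,
    weather_df: int = 4,
    dow_mode: str = "indicator",
    holidays: pd.DatetimeIndex | None = None,
    second_pollutant: str | None = None,
) -> DesignMatrix:
    """Build the full covariate matrix for one pollutant's count model.

    Blocks, in order: intercept | exposure lag basis | time spline |
    temperature spline | humidity spline | day-of-week | optional
    co-pollutant lag-0 linear term.  The first ``max_lag`` burn-in days
    (and any day whose lagged exposures fall on calendar gaps) are dropped
    and recorded in ``dropped_dates``.
    """
    if pollutant not in POLLUTANTS:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    if second_pollutant is not None:
        if second_pollutant == pollutant:
            raise ValueError("co-pollutant must differ from the primary pollutant")
        if second_pollutant not in POLLUTANTS:
            raise ValueError(f"unknown co-pollutant {second_pollutant!r}")
    needed = [pollutant] + WEATHER_COLS + ([second_pollutant] if second_pollutant else [])
    _require_complete(panel, needed)

    dates = pd.DatetimeIndex(panel["date"])
    if dates.duplicated().any():
        raise ValueError("duplicate dates in panel")
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    on_calendar = panel.set_index("date").reindex(full)

    expo_mat, valid = lag_basis(on_calendar[pollutant].to_numpy(float), structure)
    if second_pollutant is not None:
        co_mat, co_valid = lag_basis(
            on_calendar[second_pollutant].to_numpy(float), LagStructure(mode="single", lag=0)
        )
        valid &= co_valid
    keep = valid & np.asarray(full.isin(dates))
    kept_dates = full[keep]
    dropped = dates.difference(kept_dates)

    blocks: dict[str, list[str]] = {}
    lag_map: dict[str, tuple[int, ...]] = {}
    knots: dict[str, np.ndarray] = {}
    parts: list[pd.DataFrame] = []

    parts.append(pd.DataFrame({"intercept": np.ones(keep.sum())}, index=kept_dates))
    blocks["intercept"] = ["intercept"]

    expo_cols = []
    for col_lags, colvec in zip(structure.column_lags(), expo_mat[keep].T):
        name = (
            f"{pollutant}_lag{col_lags[0]}"
            if len(col_lags) == 1
            else f"{pollutant}_lag{col_lags[0]}_{col_lags[-1]}"
        )
        expo_cols.append(name)
        lag_map[name] = col_lags
        parts.append(pd.DataFrame({name: colvec}, index=kept_dates))
    blocks["exposure"] = expo_cols

    tbasis, tknots, total_df = time_spline(kept_dates, time_df_per_year)
    tcols = [f"time_s{i+1}" for i in range(total_df)]
    parts.append(pd.DataFrame(tbasis, columns=tcols, index=kept_dates))
    blocks["time"] = tcols
    knots["time"] = tknots

    sub = on_calendar.loc[kept_dates]
    for var, prefix in (("temperature", "temp"), ("humidity", "hum")):
        basis, vknots = natural_cubic_basis(
            sub[var].to_numpy(float), SplineSpec(var, weather_df)
        )
        vcols = [f"{prefix}_s{i+1}" for i in range(weather_df)]
        parts.append(pd.DataFrame(basis, columns=vcols, index=kept_dates))
        blocks[var] = vcols
        knots[var] = vknots

    dow = dow_terms(kept_dates, mode=dow_mode, holidays=holidays)
    parts.append(dow)
    blocks["dow"] = list(dow.columns)

    if second_pollutant is not None:
        name = f"{second_pollutant}_lag0"
        parts.append(pd.DataFrame({name: co_mat[keep, 0]}, index=kept_dates))
        blocks["co_pollutant"] = [name]
        lag_map[name] = (0,)

    X = pd.concat(parts, axis=1)
    # generic rank check; collinearity here is a modelling problem worth flagging
    scaled = X.to_numpy() / np.maximum(np.abs(X.to_numpy()).max(axis=0), 1e-12)
    if np.linalg.matrix_rank(scaled) < X.shape[1]:
        warnings.warn(
            f"design matrix rank-deficient (blocks: {list(blocks)}); check for "
            "constant exposure or collinear splines"
        )
    return DesignMatrix(
        X=X,
        dates=kept_dates,
        blocks=blocks,
        lag_map=lag_map,
        pollutant=pollutant,
        structure=structure,
        dropped_dates=dropped,
        knots=knots,
    )
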