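"""Station averaging and EM imputation of missing pollutant values.

City-day values are the arithmetic mean of the non-missing station values.
Missing city-day pollutant entries are imputed under a joint multivariate
normal model for the six-pollutant daily vector, fitted by
expectation-maximization over the missingness patterns; each missing entry
is replaced by its conditional mean given the day's observed pollutants at
the converged parameters.  A complete-case filter provides the sensitivity
alternative, and per-pollutant mean imputation serves as the naive
comparator in accuracy checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import POLLUTANTS
from .simulate import YEAR_DAYS


@dataclass
class EmResult:
    """Outcome of an EM imputation run.

    ``loglik_trace`` holds the observed-data log-likelihood after every
    M-step; EM theory guarantees it is non-decreasing, which callers may
    assert.  ``floored`` flags cells whose conditional mean was negative
    and was clipped to zero (concentrations are physical quantities).
    """

    panel: pd.DataFrame
    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    floored: pd.DataFrame | None = None


def average_stations(stations: pd.DataFrame) -> pd.DataFrame:
    """Collapse a station-day panel to city-day means.

    The city value for a pollutant-day is the mean over the stations that
    observed it; it is missing only when every station is missing.
    """
    if stations.empty:
        raise ValueError("empty station panel")
    if stations.duplicated(subset=["date", "station"]).any():
        raise ValueError("duplicate (date, station) rows")
    present = [p for p in POLLUTANTS if p in stations.columns]
    neg = [p for p in present if (stations[p].dropna() < 0).any()]
    if neg:
        warnings.warn(f"negative station values for {neg}; kept, not dropped")
    city = stations.groupby("date", as_index=False)[present].mean()
    return city.sort_values("date").reset_index(drop=True)


def complete_case(panel: pd.DataFrame) -> pd.DataFrame:
    """Retain only days with all six pollutants observed.

    Downstream design assembly works on calendar dates, so the gaps this
    creates are handled there (a row is analyzable only if its own and all
    lagged exposures exist on the calendar).
    """
    keep = panel[POLLUTANTS].notna().all(axis=1)
    if not keep.any():
        raise ValueError("no complete days in panel")
    return panel.loc[keep].reset_index(drop=True)


def mean_impute(panel: pd.DataFrame) -> pd.DataFrame:
    """Replace missing pollutant entries by per-pollutant observed means."""
    out = panel.copy()
    for p in POLLUTANTS:
        out[p] = out[p].fillna(out[p].mean())
    return out


def _nearest_pd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to positive definiteness by eigenvalue clipping."""
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    vals = np.maximum(vals, floor * max(vals.max(), 1.0))
    return vecs @ np.diag(vals) @ vecs.T


def _initial_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Available-case means/variances, pairwise-complete correlations, PD-projected."""
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    k = x.shape[1]
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            if both.sum() > 2:
                c = np.corrcoef(x[both, i], x[both, j])[0, 1]
                if np.isfinite(c):
                    corr[i, j] = corr[j, i] = c
    cov = _nearest_pd(np.outer(sd, sd) * corr)
    return mean, cov


def _seasonal_design(n: int) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / YEAR_DAYS
    return np.column_stack([np.ones(n), np.sin(t), np.cos(t), np.sin(2 * t), np.cos(2 * t)])


def em_impute(
    panel: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    deseasonalize: bool = False,
    columns: list[str] | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> EmResult:
    """Fit a 6-variate normal to daily pollutant vectors by EM and impute.

    Days are treated as independent draws; per missingness pattern the
    E-step computes conditional means and covariances of the missing block
    given the observed one, the M-step updates the mean vector and
    covariance from the completed sufficient statistics.  Iteration stops
    when the observed-data log-likelihood improves by less than ``tol``.

    With ``deseasonalize=True`` each pollutant's harmonic seasonal mean
    (annual + semi-annual, fitted on observed days) is removed first and
    the residuals are imputed — an acknowledgement that the plain model
    assumes stationary means.

    Observed entries are never modified.  Negative conditional means are
    floored at zero after convergence and flagged in ``floored``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    columns = list(columns) if columns is not None else list(POLLUTANTS)
    x_raw = panel[columns].to_numpy(float)
    n, k = x_raw.shape
    miss = np.isnan(x_raw)
    if miss.all(axis=0).any():
        raise ValueError("a pollutant is missing on every day; covariance not identifiable")
    if (~miss).sum() <= k * (k + 3) / 2:
        raise ValueError("too few observed entries to identify mean and covariance")

    seasonal = np.zeros_like(x_raw)
    if deseasonalize:
        z = _seasonal_design(n)
        for j in range(k):
            obs = ~miss[:, j]
            coef, *_ = np.linalg.lstsq(z[obs], x_raw[obs, j], rcond=None)
            seasonal[:, j] = z @ coef
    x = x_raw - seasonal

    if init is not None:
        mean = np.asarray(init[0], float).copy()
        cov = _nearest_pd(np.asarray(init[1], float))
    else:
        mean, cov = _initial_moments(x)

    # group days by missingness pattern once; E-step work is per pattern
    pattern_keys = [tuple(row) for row in miss]
    groups: dict[tuple, np.ndarray] = {}
    for i, key in enumerate(pattern_keys):
        groups.setdefault(key, []).append(i)
    groups = {key: np.asarray(rows) for key, rows in groups.items()}

    trace: list[float] = []
    converged = False
    it = 0
    filled = x.copy()
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(k)
        sum_xx = np.zeros((k, k))
        loglik = 0.0
        for key, rows in groups.items():
            m = np.asarray(key)
            o = ~m
            xo = x[np.ix_(rows, np.flatnonzero(o))]
            mu_o = mean[o]
            sig_oo = cov[np.ix_(o, o)]
            if o.any():
                loglik += stats.multivariate_normal.logpdf(
                    xo, mean=mu_o, cov=sig_oo, allow_singular=True
                ).sum()
            comp = np.tile(mean, (len(rows), 1))
            comp[:, o] = xo
            cond_cov = np.zeros((k, k))
            if m.any() and o.any():
                sig_mo = cov[np.ix_(m, o)]
                gain = np.linalg.solve(sig_oo, sig_mo.T).T
                comp[:, m] = mean[m] + (xo - mu_o) @ gain.T
                cond_cov[np.ix_(m, m)] = cov[np.ix_(m, m)] - gain @ sig_mo.T
            elif m.any():
                cond_cov[np.ix_(m, m)] = cov[np.ix_(m, m)]
            sum_x += comp.sum(axis=0)
            sum_xx += comp.T @ comp + len(rows) * cond_cov
            filled[rows] = comp
        new_mean = sum_x / n
        new_cov = sum_xx / n - np.outer(new_mean, new_mean)
        if np.linalg.eigvalsh(0.5 * (new_cov + new_cov.T)).min() <= 0:
            raise np.linalg.LinAlgError(
                f"covariance update lost positive definiteness at iteration {it}"
            )
        mean, cov = new_mean, 0.5 * (new_cov + new_cov.T)
        trace.append(float(loglik))
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")

    # final E-step so imputations use the converged parameters
    for key, rows in groups.items():
        m = np.asarray(key)
        o = ~m
        if not m.any():
            continue
        comp = np.tile(mean, (len(rows), 1))
        if o.any():
            xo = x[np.ix_(rows, np.flatnonzero(o))]
            comp[:, o] = xo
            sig_oo = cov[np.ix_(o, o)]
            sig_mo = cov[np.ix_(m, o)]
            gain = np.linalg.solve(sig_oo, sig_mo.T).T
            comp[:, m] = mean[m] + (xo - mean[o]) @ gain.T
        filled[rows] = comp

    imputed = x_raw.copy()
    imputed[miss] = (filled + seasonal)[miss]
    floored = pd.DataFrame(miss & (imputed < 0), index=panel.index, columns=columns)
    imputed = np.maximum(imputed, 0.0)
    out = panel.copy()
    out[columns] = imputed
    return EmResult(
        panel=out,
        mean=mean + seasonal.mean(axis=0),
        cov=cov,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        floored=floored,
    )
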