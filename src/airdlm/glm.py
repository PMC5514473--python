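"""Quasi-Poisson log-link regression by iteratively reweighted least squares.

The point estimates are the Poisson maximum-likelihood solution; the
quasi-Poisson part is the Pearson dispersion phi = chi^2 / (n - p), which
rescales the coefficient covariance (and hence Wald intervals and
p-values) without moving the estimates.  Model-df selection uses the
quasi-likelihood analogue of AIC, QAIC = -2 * loglik / phi + 2p, which
reduces to ordinary AIC at phi = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .design import DesignMatrix, LagStructure, assemble

_MAX_ETA = 30.0  # exp overflow guard; counts this large never occur here


@dataclass
class GlmFit:
    """Converged quasi-Poisson fit.

    ``cov`` is the dispersion-scaled covariance phi * (X'WX)^-1; p-values
    are two-sided Wald against the standard normal.  ``loglik`` is the
    Poisson log-likelihood at the estimates (the quasi-model has no
    likelihood of its own).
    """

    coef: pd.Series
    cov: pd.DataFrame
    dispersion: float
    deviance: float
    loglik: float
    fitted: np.ndarray
    n_iter: int
    converged: bool
    n: int
    p: int

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.coef.index)

    @property
    def pvalues(self) -> pd.Series:
        se = self.se.replace(0.0, np.nan)
        z = self.coef / se
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.coef.index).fillna(1.0)

    def qaic(self) -> float:
        return qaic(self)


def _check_inputs(y: np.ndarray, X: np.ndarray, names: list[str]) -> None:
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} rows cannot identify p={p} coefficients")
    scaled = X / np.maximum(np.abs(X).max(axis=0), 1e-12)
    rank = np.linalg.matrix_rank(scaled)
    if rank < p:
        _, _, piv = linalg.qr(scaled, pivoting=True, mode="economic")
        culprits = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(f"design matrix rank deficient; columns {culprits}")


def fit(y, X: DesignMatrix | pd.DataFrame | np.ndarray, tol: float = 1e-9, max_iter: int = 100) -> GlmFit:
    """Fit the log-link count model by IRLS.

    Iterates weighted least squares on the working response
    ``eta + (y - mu) / mu`` with weights ``mu`` until the relative change
    in deviance falls below ``tol``.  Starting values: all coefficients 0
    except the intercept at ``log(mean(y) + 0.5/n)`` (deterministic).
    """
    if isinstance(X, DesignMatrix):
        Xdf = X.X
    elif isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        Xdf = pd.DataFrame(np.asarray(X, float))
        Xdf.columns = [f"x{j}" for j in range(Xdf.shape[1])]
    names = [str(c) for c in Xdf.columns]
    Xm = Xdf.to_numpy(float)
    y = np.asarray(y, dtype=float)
    if len(y) != Xm.shape[0]:
        raise ValueError("y and X row counts differ")
    _check_inputs(y, Xm, names)
    n, p = Xm.shape

    beta = np.zeros(p)
    const_cols = np.flatnonzero(np.ptp(Xm, axis=0) == 0)
    if const_cols.size:
        j = const_cols[0]
        beta[j] = np.log(y.mean() + 0.5 / n) / Xm[0, j]

    def deviance_of(mu: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * float(np.sum(term - (y - mu)))

    eta = np.clip(Xm @ beta, -_MAX_ETA, _MAX_ETA)
    mu = np.exp(eta)
    dev = deviance_of(mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        beta, *_ = np.linalg.lstsq(Xm * w[:, None], z * w, rcond=None)
        eta = np.clip(Xm @ beta, -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        new_dev = deviance_of(mu)
        if abs(new_dev - dev) / (abs(new_dev) + 0.1) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations (deviance {dev:.6g})"
        )

    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / (n - p)
    xtwx = (Xm * mu[:, None]).T @ Xm
    cov_unscaled = np.linalg.inv(xtwx)
    cov = dispersion * 0.5 * (cov_unscaled + cov_unscaled.T)
    loglik = float(np.sum(y * eta - mu - special.gammaln(y + 1.0)))
    return GlmFit(
        coef=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        dispersion=dispersion,
        deviance=dev,
        loglik=loglik,
        fitted=mu,
        n_iter=it,
        converged=converged,
        n=n,
        p=p,
    )


def qaic(fit_result: GlmFit, dispersion: float | None = None) -> float:
    """Quasi-AIC: ``-2 * loglik / phi + 2p``; ordinary AIC when phi = 1."""
    phi = fit_result.dispersion if dispersion is None else dispersion
    if phi <= 0:
        raise ValueError("dispersion must be positive")
    return -2.0 * fit_result.loglik / phi + 2.0 * fit_result.p


def select_df(
    panel: pd.DataFrame,
    pollutant: str,
    target: str,
    candidates=range(1, 11),
    structure: LagStructure | None = None,
    outcome: str = "all",
    time_df_per_year: int = 7,
    weather_df: int = 4,
    **assemble_kwargs,
) -> int:
    """Pick the QAIC-minimizing degrees of freedom for one spline.

    ``target`` is one of 'time' (df per year), 'temperature' or 'humidity'
    (total df); all other settings are held fixed while candidates are
    refitted.  Ties break toward the smaller df.  Candidates whose fit
    fails are skipped with a warning; if all fail an error is raised.
    """
    import warnings as _warnings

    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    if target not in ("time", "temperature", "humidity"):
        raise ValueError(f"unknown selection target {target!r}")
    structure = structure or LagStructure(mode="single", lag=0)
    y_full = panel.set_index("date")[outcome]

    best_df, best_q = None, np.inf
    for cand in candidates:
        kwargs = dict(time_df_per_year=time_df_per_year, weather_df=weather_df)
        if target == "time":
            kwargs["time_df_per_year"] = cand
        else:
            kwargs["weather_df"] = cand
        try:
            dm = assemble(panel, pollutant, structure, **kwargs, **assemble_kwargs)
            res = fit(y_full.loc[dm.dates].to_numpy(), dm)
            q = qaic(res)
        except Exception as exc:  # noqa: BLE001 - candidate skipped, not fatal
            _warnings.warn(f"df candidate {cand} for {target} failed: {exc}")
            continue
        if q < best_q - 1e-12:
            best_df, best_q = cand, q
    if best_df is None:
        raise RuntimeError(f"all df candidates failed for {target}")
    return best_df
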