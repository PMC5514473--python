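"""Synthetic daily panels with known ground-truth lag effects.

The generator emulates the structure of a single-city ecological
time-series study: six correlated pollutant series with annual and
semi-annual cycles, daily temperature and humidity, and overdispersed
admission counts driven by a log-linear distributed-lag model in one
pollutant.  Everything downstream (imputation, design assembly, GLM
fitting, effect reporting) can therefore be validated against a recorded
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AGE_STRATA,
    POLLUTANTS,
    SEX_STRATA,
    WEATHER_COLS,
    SimConfig,
)

YEAR_DAYS = 365.25
N_LAGS = 7  # exposures at lags 0..7 enter the count model
_POLLUTANT_FLOOR = 0.1  # truncation floor on measurement units

# Day-of-year (from Jan 1) at which each variable's annual cosine peaks:
# combustion pollutants and humidity peak mid-winter, O3 and temperature
# mid-summer; admissions peak in winter with the pollutants.
_PEAK_DAY = {
    "co": 15.0,
    "so2": 15.0,
    "no2": 15.0,
    "pm25": 15.0,
    "pm10": 15.0,
    "o3": 196.0,
    "temperature": 196.0,
    "humidity": 15.0,
    "admissions": 15.0,
}

_WEATHER_MEANS = {"temperature": 14.8, "humidity": 44.9}
_WEATHER_NOISE_SD = {"temperature": 3.5, "humidity": 12.0}


@dataclass
class TruthRecord:
    """Ground truth realized by one generator run.

    ``mu`` is the true expected count for every analysis day, i.e. the
    exponentiated log-linear predictor; recovery tests compare fitted
    models against ``lag_log_rr`` and coverage against these values.
    """

    panel: pd.DataFrame
    lag_log_rr: np.ndarray
    effect_pollutant: str
    weather_effect: dict[str, float]
    seasonal_log_amplitude: tuple[float, float]
    mu: np.ndarray
    linear_predictor: np.ndarray


def _seasonal_cycle(day_index: np.ndarray, variable: str, amplitudes: dict) -> np.ndarray:
    """Annual + semi-annual cosine cycle, zero-mean over a whole year."""
    a1, a2 = amplitudes.get(variable, (0.0, 0.0))
    phase = 2.0 * np.pi * (day_index - _PEAK_DAY[variable]) / YEAR_DAYS
    return a1 * np.cos(phase) + a2 * np.cos(2.0 * phase)


def _noise_sd(total_sd: float, a1: float, a2: float) -> float:
    """Day-to-day noise SD so total variance approximates the configured SD^2.

    A cosine of amplitude a contributes a^2/2 to the variance; the residual
    is floored at 30% of the configured SD so noise never vanishes.
    """
    resid = total_sd**2 - 0.5 * a1**2 - 0.5 * a2**2
    return float(np.sqrt(max(resid, (0.3 * total_sd) ** 2)))


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a complete daily panel and its ground-truth record.

    A 7-day pre-period is generated internally so the counts of the first
    analysis days see genuine lag-0..7 exposures; the returned panel holds
    exactly ``config.n_days`` rows and no missing values.

    Counts are Poisson when ``overdispersion == 1`` and gamma-mixed Poisson
    (negative binomial with variance ``mu * phi``) otherwise.  Sex and age
    stratum counts are multinomial splits of each day's total.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_days + N_LAGS

    start = pd.Timestamp(config.start_date) - pd.Timedelta(days=N_LAGS)
    dates = pd.date_range(start, periods=n_total, freq="D")
    day_index = np.arange(n_total, dtype=float) + float(dates[0].dayofyear) - 1.0

    # --- pollutants: seasonal mean + correlated noise, truncated at a floor
    sds = np.array([_noise_sd(config.pollutant_means_sds[p][1], *config.seasonal_amplitudes.get(p, (0, 0))) for p in POLLUTANTS])
    cov = np.outer(sds, sds) * config.pollutant_correlation
    noise = rng.multivariate_normal(np.zeros(6), cov, size=n_total, method="cholesky")
    pollutants = {}
    for j, p in enumerate(POLLUTANTS):
        mean = config.pollutant_means_sds[p][0]
        series = mean + _seasonal_cycle(day_index, p, config.seasonal_amplitudes) + noise[:, j]
        pollutants[p] = np.maximum(series, _POLLUTANT_FLOOR)

    # --- weather: seasonal cycle + independent noise
    weather = {}
    for w in WEATHER_COLS:
        series = (
            _WEATHER_MEANS[w]
            + _seasonal_cycle(day_index, w, config.seasonal_amplitudes)
            + rng.normal(0.0, _WEATHER_NOISE_SD[w], n_total)
        )
        if w == "humidity":
            series = np.clip(series, 5.0, 100.0)
        weather[w] = series

    # --- log-linear predictor on the analysis days
    keep = slice(N_LAGS, n_total)
    beta = np.asarray(config.lag_log_rr, dtype=float)
    exposure = pollutants[config.effect_pollutant]
    eta = np.full(config.n_days, config.baseline_log_rate)
    for lag in range(N_LAGS + 1):
        eta += beta[lag] * exposure[N_LAGS - lag : n_total - lag]
    for w in WEATHER_COLS:
        eta += config.weather_effect.get(w, 0.0) * (weather[w][keep] - _WEATHER_MEANS[w])
    eta += _seasonal_cycle(day_index[keep], "admissions", config.seasonal_amplitudes)
    mu = np.exp(eta)

    # --- counts: gamma-mixed Poisson with var = mu * phi (Poisson at phi=1)
    phi = config.overdispersion
    if phi == 1.0:
        total = rng.poisson(mu)
    else:
        shape = mu / (phi - 1.0)
        lam = rng.gamma(shape, scale=phi - 1.0)
        total = rng.poisson(lam)

    sex_p = [config.strata_shares["sex"][s] for s in SEX_STRATA]
    age_p = [config.strata_shares["age"][s] for s in AGE_STRATA]
    male = rng.binomial(total, sex_p[0])
    under60 = rng.binomial(total, age_p[0])

    panel = pd.DataFrame({"date": dates[keep]})
    for p in POLLUTANTS:
        panel[p] = pollutants[p][keep]
    for w in WEATHER_COLS:
        panel[w] = weather[w][keep]
    panel["all"] = total
    panel["male"] = male
    panel["female"] = total - male
    panel["under60"] = under60
    panel["over60"] = total - under60
    panel = panel.reset_index(drop=True)

    truth = TruthRecord(
        panel=panel.copy(),
        lag_log_rr=beta,
        effect_pollutant=config.effect_pollutant,
        weather_effect=dict(config.weather_effect),
        seasonal_log_amplitude=tuple(config.seasonal_amplitudes.get("admissions", (0.0, 0.0))),
        mu=mu,
        linear_predictor=eta,
    )
    return panel, truth


def degrade_missing(
    panel: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask pollutant values at the configured per-pollutant rates.

    Returns the degraded panel and a boolean mask frame (True = masked).
    Under ``mcar`` every day is masked independently with the pollutant's
    rate; under ``mar`` the daily masking probability is modulated by the
    annual cycle (winter days more likely missing) while keeping the same
    marginal rate, for robustness checks of MCAR-based imputation.
    """
    for p, rate in config.missing_rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missing rate for {p} must lie in [0, 1)")
    if panel[POLLUTANTS].isna().any().any():
        raise ValueError("degrade_missing expects a complete panel")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD16]))
    n = len(panel)
    day_index = np.arange(n, dtype=float)
    out = panel.copy()
    mask = pd.DataFrame(False, index=panel.index, columns=POLLUTANTS)
    for p in POLLUTANTS:
        rate = config.missing_rates.get(p, 0.0)
        if rate == 0.0:
            continue
        if config.missing_mechanism == "mar":
            mod = 1.0 + 0.5 * np.cos(2.0 * np.pi * day_index / YEAR_DAYS)
            prob = np.clip(rate * mod, 0.0, 0.999)
        else:
            prob = np.full(n, rate)
        hit = rng.random(n) < prob
        out.loc[hit, p] = np.nan
        mask[p] = hit
    return out, mask


def split_stations(panel: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Expand city-day pollutant values into station-day values.

    Each station observes the city value plus independent Gaussian noise
    with SD ``station_noise_frac`` times the pollutant's configured SD, so
    the station mean is an unbiased estimate of the city value.  Returns a
    long frame with columns date, station, and the six pollutants.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x57A]))
    frames = []
    for s in range(config.n_stations):
        block = pd.DataFrame({"date": panel["date"], "station": s + 1})
        for p in POLLUTANTS:
            sd = config.station_noise_frac * config.pollutant_means_sds[p][1]
            noise = rng.normal(0.0, sd, len(panel)) if sd > 0 else 0.0
            block[p] = panel[p].to_numpy() + noise
        frames.append(block)
    return pd.concat(frames, ignore_index=True).sort_values(["date", "station"]).reset_index(drop=True)
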