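"""Configuration objects and shared constants for the daily-panel pipeline.

Units follow ambient-air-quality convention: CO in mg/m3, all other
pollutants in ug/m3, temperature in degrees Celsius, relative humidity in
percent.  Rate ratios are reported per 10 ug/m3 for the ug/m3 pollutants and
per 1 mg/m3 for CO.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

#: Canonical pollutant column order used everywhere in the package.
POLLUTANTS = ["co", "so2", "no2", "o3", "pm25", "pm10"]

#: Reporting increment: 10 ug/m3 for ug/m3 pollutants, 1 mg/m3 for CO.
DEFAULT_INCREMENT = 10.0
CO_INCREMENT = 1.0

#: Meteorology and count columns of a daily panel.
WEATHER_COLS = ["temperature", "humidity"]
COUNT_COLS = ["all", "male", "female", "under60", "over60"]

SEX_STRATA = ["male", "female"]
AGE_STRATA = ["under60", "over60"]


def increment_for(pollutant: str) -> float:
    """Reporting increment on the pollutant's own measurement unit."""
    return CO_INCREMENT if pollutant == "co" else DEFAULT_INCREMENT


def _default_means_sds() -> dict[str, tuple[float, float]]:
    # Location/scale of the six daily series on their measurement units.
    return {
        "co": (2.89, 0.76),
        "so2": (54.83, 33.3),
        "no2": (53.45, 21.8),
        "o3": (59.58, 26.7),
        "pm25": (24.3, 20.9),
        "pm10": (86.6, 44.3),
    }


def _default_amplitudes() -> dict[str, tuple[float, float]]:
    # (annual, semi-annual) harmonic amplitudes per variable; combustion
    # pollutants peak in winter, O3 and temperature in summer (phases are
    # fixed in the generator, amplitudes configurable here).
    return {
        "co": (0.35, 0.08),
        "so2": (14.0, 3.0),
        "no2": (9.0, 2.0),
        "o3": (13.0, 3.0),
        "pm25": (8.0, 2.0),
        "pm10": (16.0, 4.0),
        "temperature": (12.0, 1.5),
        "humidity": (14.0, 3.0),
        "admissions": (0.20, 0.05),
    }


def _default_missing_rates() -> dict[str, float]:
    # Fractions of days with a missing city-level value, per pollutant.
    return {
        "co": 0.20,
        "pm10": 0.25,
        "pm25": 0.30,
        "no2": 0.32,
        "o3": 0.34,
        "so2": 0.35,
    }


def _default_strata_shares() -> dict[str, dict[str, float]]:
    return {
        "sex": {"male": 0.574, "female": 0.426},
        "age": {"under60": 0.69, "over60": 0.31},
    }


def exchangeable_correlation(rho: float = 0.4, k: int = 6) -> np.ndarray:
    """Exchangeable correlation matrix: unit diagonal, constant off-diagonal."""
    r = np.full((k, k), rho)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimConfig:
    """Parameters of the synthetic daily-panel generator.

    The defaults describe a six-year (2191-day) single-city study: six
    correlated pollutant series with seasonal cycles, daily meteorology, and
    overdispersed admission counts whose log-mean is a distributed-lag
    linear predictor in one driver pollutant plus weather and seasonal
    terms.

    Parameters
    ----------
    n_days
        Number of analysis days in the returned panel (a 7-day pre-period
        is generated internally so every day has lag-0..7 exposures).
    baseline_log_rate
        Intercept of the log-linear count model; ``exp`` of it is the
        expected daily count when all covariates sit at their centring
        values.
    lag_log_rr
        True log rate-ratio per unit of the driver pollutant at lags 0..7
        (exactly 8 entries).
    effect_pollutant
        Which pollutant series drives the admission counts.
    seasonal_amplitudes
        Per-variable (annual, semi-annual) cosine amplitudes; the
        ``"admissions"`` entry acts on the log-rate and induces seasonal
        confounding between exposure and outcome.
    pollutant_means_sds
        Per-pollutant (mean, total SD) on measurement units; the generator
        splits the SD between the seasonal cycle and day-to-day noise.
    pollutant_correlation
        6x6 correlation of the day-to-day pollutant noise, in the order of
        :data:`POLLUTANTS`.
    weather_effect
        Log-rate coefficients per degree C / per percent RH (applied to
        centred temperature and humidity).
    overdispersion
        Variance-to-mean ratio phi of daily counts (>= 1; 1 is Poisson,
        larger values use a gamma-mixed Poisson).
    missing_rates
        Per-pollutant MCAR missingness fraction in [0, 1).
    n_stations
        Number of monitoring stations the city value can be split into.
    station_noise_frac
        Station-level noise SD as a fraction of the pollutant's SD.
    strata_shares
        ``{"sex": {...}, "age": {...}}``; each inner dict sums to 1.
    seed
        Master RNG seed; identical configs with identical seeds reproduce
        identical panels.
    """

    n_days: int = 2191
    start_date: dt.date = dt.date(2010, 1, 1)
    baseline_log_rate: float = float(np.log(7.13))
    lag_log_rr: tuple[float, ...] = (0.0,) * 8
    effect_pollutant: str = "pm10"
    seasonal_amplitudes: dict[str, tuple[float, float]] = field(default_factory=_default_amplitudes)
    pollutant_means_sds: dict[str, tuple[float, float]] = field(default_factory=_default_means_sds)
    pollutant_correlation: np.ndarray = field(default_factory=exchangeable_correlation)
    weather_effect: dict[str, float] = field(
        default_factory=lambda: {"temperature": -0.008, "humidity": 0.0015}
    )
    overdispersion: float = 4.2
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    missing_mechanism: str = "mcar"  # or "mar" (season-dependent)
    n_stations: int = 4
    station_noise_frac: float = 0.15
    strata_shares: dict[str, dict[str, float]] = field(default_factory=_default_strata_shares)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be a positive integer")
        if len(self.lag_log_rr) != 8:
            raise ValueError("lag_log_rr must have exactly 8 entries (lags 0-7)")
        if self.effect_pollutant not in POLLUTANTS:
            raise ValueError(f"unknown effect_pollutant {self.effect_pollutant!r}")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {name} must lie in [0, 1)")
        for group, shares in self.strata_shares.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{group} strata shares sum to {total}, not 1")
            if any(s < 0 for s in shares.values()):
                raise ValueError(f"{group} strata shares must be non-negative")
        for name, (a1, a2) in self.seasonal_amplitudes.items():
            if a1 < 0 or a2 < 0:
                raise ValueError(f"negative seasonal amplitude for {name}")
        corr = np.asarray(self.pollutant_correlation, dtype=float)
        if corr.shape != (6, 6):
            raise ValueError("pollutant_correlation must be 6x6")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("pollutant_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("pollutant_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 1e-12:
            raise ValueError("pollutant_correlation must be positive definite")
        self.pollutant_correlation = corr
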