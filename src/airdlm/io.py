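"""Delimited-text readers and writers for panels and truth records.

Panels are plain CSV with ISO-8601 dates and empty fields for missing
values; truth records are JSON sidecars.  These are the only on-disk
formats the pipeline uses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COUNT_COLS, POLLUTANTS
from .simulate import TruthRecord


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def read_panel(path, require_consecutive: bool = False) -> pd.DataFrame:
    panel = pd.read_csv(path, parse_dates=["date"])
    if panel["date"].duplicated().any():
        raise ValueError(f"{path}: duplicate dates")
    panel = panel.sort_values("date").reset_index(drop=True)
    if require_consecutive:
        gaps = panel["date"].diff().dropna()
        if (gaps != pd.Timedelta(days=1)).any():
            raise ValueError(f"{path}: dates are not consecutive")
    for col in COUNT_COLS:
        if col in panel.columns:
            vals = panel[col].dropna()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{path}: column {col!r} must hold non-negative integers")
    if {"male", "female", "all"} <= set(panel.columns):
        if not (panel["male"] + panel["female"] == panel["all"]).all():
            raise ValueError(f"{path}: male + female != all")
    return panel


def write_stations(stations: pd.DataFrame, path) -> None:
    out = stations.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def read_stations(path) -> pd.DataFrame:
    stations = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "station"} - set(stations.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return stations


def write_truth(truth: TruthRecord, path) -> None:
    payload = {
        "lag_log_rr": truth.lag_log_rr.tolist(),
        "effect_pollutant": truth.effect_pollutant,
        "weather_effect": truth.weather_effect,
        "seasonal_log_amplitude": list(truth.seasonal_log_amplitude),
        "mu": truth.mu.tolist(),
        "linear_predictor": truth.linear_predictor.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["lag_log_rr"] = np.asarray(payload["lag_log_rr"])
    payload["mu"] = np.asarray(payload["mu"])
    payload["linear_predictor"] = np.asarray(payload["linear_predictor"])
    return payload


def panel_missing_fractions(panel: pd.DataFrame) -> dict[str, float]:
    return {p: float(panel[p].isna().mean()) for p in POLLUTANTS if p in panel.columns}
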