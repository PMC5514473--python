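"""Forest-style plots of lag-specific rate ratios."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .effects import EffectEstimate


def plot_forest(estimates: list[EffectEstimate], ax=None, title: str | None = None):
    """Rate ratios with 95% CI bars against lag, one marker per estimate.

    Estimates should share a pollutant/stratum/variant; the unit line at
    RR = 1 is drawn for reference.  Returns the matplotlib Axes.
    """
    if not estimates:
        raise ValueError("no estimates to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    lags = [e.lag for e in estimates]
    rrs = [e.rr for e in estimates]
    lo = [e.rr - e.ci_low for e in estimates]
    hi = [e.ci_high - e.rr for e in estimates]
    ax.errorbar(lags, rrs, yerr=[lo, hi], fmt="o", capsize=3, color="black")
    ax.axhline(1.0, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel("lag (days)")
    e = estimates[0]
    unit = "1 mg/m$^3$" if e.increment == 1.0 else f"{e.increment:g} $\\mu$g/m$^3$"
    ax.set_ylabel(f"RR per {unit}")
    ax.set_title(title or f"{e.pollutant} ({e.variant}, {e.stratum})")
    return ax


def save_forest(estimates: list[EffectEstimate], path, **kwargs) -> None:
    ax = plot_forest(estimates, **kwargs)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
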