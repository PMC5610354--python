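"""Diagnostic plots: binned series with segment fits and prediction
bands, and the two-curve annual-rate layout behind the savings
estimate."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .regression import SlopeComparison, prediction_interval
from .savings import AnnualRateCurve
from .timeseries import BinnedSeries

__all__ = ["plot_series_fit", "plot_rate_curves"]


def plot_series_fit(
    series: BinnedSeries, comparison: SlopeComparison, path: str | Path,
    title: str = "", level: float = 0.95,
) -> Path:
    """Series, before/after fit lines and prediction bands, one panel."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    obs = series.observed
    ax.plot(obs.index, obs.values, "o", ms=4, color="0.3", label="binned data")
    for fit, style in ((comparison.fit_before, "C0"), (comparison.fit_after, "C3")):
        ts = np.linspace(fit.x.min(), fit.x.max(), 50)
        ax.plot(ts, fit.predict(ts), "-", color=style)
        band = np.array([prediction_interval(fit, t, level) for t in ts])
        ax.fill_between(ts, band[:, 0], band[:, 1], color=style, alpha=0.15)
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"{series.bin_width}-day bin (0 = intervention)")
    ax.set_ylabel(f"{series.transform}({series.outcome_label})")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_rate_curves(
    before: AnnualRateCurve, after: AnnualRateCurve, path: str | Path,
    title: str = "",
) -> Path:
    """Projected before-curve vs actual after-curve over the after-year."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    days = np.linspace(0, 365, 200)
    t = days / before.bin_width
    ax.plot(days, before.rate(t), "C0-", label="projected (before fit)")
    ax.plot(days, after.rate(t), "C3-", label="actual (after fit)")
    ax.fill_between(days, after.rate(t), before.rate(t), color="C2", alpha=0.2,
                    label="estimated saving")
    ax.set_xlabel("days after start of intervention")
    ax.set_ylabel(f"annual rate ({before.unit}/yr)")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
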