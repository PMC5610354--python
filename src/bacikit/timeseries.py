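"""Intervention-synchronised binning, cross-patient averaging, transforms.

Events carry signed day offsets from each patient's intervention anchor.
Bin ``b`` of width ``w`` covers the half-open day interval
``[b*w, (b+1)*w)``; before-period bins have ``b < 0``, after-period bins
``b >= 0``. Costs use 30-day bins over 3 years before / 1 year after
(48 bins, -36..11); hospital outcomes use 100-day bins (15 bins,
-11..3), the wider interval avoiding a preponderance of zero counts.

A bin truncated by a patient's death is flagged unobserved rather than
zero-filled: zero-filling would fabricate an expenditure decline out of
mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIN_RANGES",
    "BinnedSeries",
    "DiscardLog",
    "bin_patients",
    "average_patients",
    "apply_transform",
    "select_transform",
    "difference_series",
]

#: Default signed bin-index ranges (half-open) per bin width in days.
BIN_RANGES: dict[int, tuple[int, int]] = {30: (-36, 12), 100: (-11, 4)}

TRANSFORMS = ("identity", "sqrt", "log")


@dataclass
class DiscardLog:
    """Events that entered no observed bin, for conservation accounting."""

    n_out_of_range: int = 0
    total_out_of_range: float = 0.0
    n_truncated: int = 0
    total_truncated: float = 0.0

    @property
    def discarded_total(self) -> float:
        return self.total_out_of_range + self.total_truncated


@dataclass
class BinnedSeries:
    """Per-bin cross-patient mean outcome on a stated transform scale.

    ``values`` is indexed by signed bin number; unobserved bins hold
    NaN. ``n_observed`` counts the patients contributing to each bin.
    """

    bin_width: int
    values: pd.Series
    n_observed: pd.Series
    transform: str = "identity"
    outcome_label: str = ""

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")

    @property
    def bins(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def observed(self) -> pd.Series:
        """Observed bins only (NaN bins dropped)."""
        return self.values.dropna()

    def period(self, which: str) -> pd.Series:
        """Observed values in the 'before', 'after' or 'pooled' period."""
        obs = self.observed
        if which == "before":
            return obs[obs.index < 0]
        if which == "after":
            return obs[obs.index >= 0]
        if which == "pooled":
            return obs
        raise ValueError("period must be 'before', 'after' or 'pooled'")


def default_bin_range(width: int) -> tuple[int, int]:
    try:
        return BIN_RANGES[width]
    except KeyError:
        raise ValueError(f"no default bin range for width {width}; pass bin_range")


def bin_patients(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    width: int,
    bin_range: tuple[int, int] | None = None,
    value_col: str = "cost",
    day_col: str = "day",
) -> tuple[pd.DataFrame, DiscardLog]:
    """Total ``value_col`` per patient per bin.

    Returns a (patients x bins) DataFrame whose cells are bin totals,
    with NaN marking bins unobserved because the patient died before
    the bin's final day, plus a :class:`DiscardLog` tallying events
    outside the bin range or inside unobserved bins, so that
    ``totals.sum() + log.discarded_total == events[value_col].sum()``.
    """
    lo, hi = bin_range if bin_range is not None else default_bin_range(width)
    ids = patients["patient_id"].to_numpy()
    order = {pid: i for i, pid in enumerate(ids)}
    death = patients["death_day"].to_numpy(dtype=float) if "death_day" in patients else np.full(ids.size, np.nan)

    all_bins = np.arange(lo, hi)
    totals = np.zeros((ids.size, all_bins.size))
    log = DiscardLog()

    if len(events):
        pat = events["patient_id"].map(order)
        if pat.isna().any():
            unknown = events.loc[pat.isna(), "patient_id"].unique()[:5]
            raise ValueError(f"events reference unknown patients: {list(unknown)}")
        pat = pat.to_numpy(dtype=int)
        day = events[day_col].to_numpy()
        val = events[value_col].to_numpy(dtype=float)
        b = np.floor_divide(day, width)
        in_range = (b >= lo) & (b < hi)
        log.n_out_of_range = int((~in_range).sum())
        log.total_out_of_range = float(val[~in_range].sum())
        pat, day, val, b = pat[in_range], day[in_range], val[in_range], b[in_range]
        # A bin is observed only if the patient was alive through its
        # final day ((b+1)*width - 1).
        d = death[pat]
        observed_ev = np.isnan(d) | (d >= (b + 1) * width - 1)
        log.n_truncated = int((~observed_ev).sum())
        log.total_truncated = float(val[~observed_ev].sum())
        pat, b, val = pat[observed_ev], b[observed_ev], val[observed_ev]
        np.add.at(totals, (pat, b - lo), val)

    # Unobserved mask from deaths, independent of whether events exist.
    d = death[:, None]
    unobserved = ~np.isnan(d) & (d < (all_bins + 1)[None, :] * width - 1)
    totals[unobserved] = np.nan
    return pd.DataFrame(totals, index=pd.Index(ids, name="patient_id"), columns=all_bins), log


def average_patients(
    totals: pd.DataFrame,
    outcome_label: str = "",
    bin_width: int | None = None,
) -> BinnedSeries:
    """Per-bin mean over observed patients, recording per-bin n.

    Bins with zero observed patients come out NaN and are skipped by
    downstream fits.
    """
    if totals.shape[0] < 1:
        raise ValueError("need at least one patient")
    values = totals.mean(axis=0, skipna=True)
    n_obs = totals.notna().sum(axis=0)
    values[n_obs == 0] = np.nan
    width = bin_width if bin_width is not None else _infer_width(totals.columns)
    return BinnedSeries(
        bin_width=width,
        values=values.astype(float),
        n_observed=n_obs.astype(int),
        transform="identity",
        outcome_label=outcome_label,
    )


def _infer_width(bins) -> int:
    b = np.asarray(bins)
    for width, (lo, hi) in BIN_RANGES.items():
        if b.min() >= lo and b.max() < hi and b.size > (hi - lo) // 2:
            return width
    raise ValueError("cannot infer bin width; pass bin_width explicitly")


def apply_transform(series: BinnedSeries, transform: str) -> BinnedSeries:
    """Return the series on the requested transform scale."""
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    if series.transform != "identity":
        raise ValueError("can only transform an identity-scale series")
    if transform == "identity":
        return replace(series)
    obs = series.observed
    if transform == "sqrt":
        if (obs < 0).any():
            raise ValueError("sqrt transform requires nonnegative values")
        vals = np.sqrt(series.values)
    else:
        if (obs <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        vals = np.log(series.values)
    return replace(series, values=vals, transform=transform)


def _segmented_residuals(series: BinnedSeries) -> np.ndarray:
    """Residuals of the before/after segmented line (the analysis model)."""
    obs = series.observed
    t = obs.index.to_numpy(dtype=float)
    y = obs.to_numpy(dtype=float)
    after = (t >= 0).astype(float)
    cols = [np.ones_like(t), t]
    if 0 < after.sum() < t.size:  # both periods present -> full segmented design
        cols += [after, t * after]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def select_transform(
    series: BinnedSeries, alpha: float = 0.05
) -> tuple[str, dict[str, float]]:
    """Choose the normalising transform by residual normality.

    Applies Shapiro-Wilk to the residuals of the segmented linear fit
    under each candidate transform and returns the first of (identity,
    sqrt, log) whose residual p-value is >= ``alpha``, else the
    candidate with the largest p. The normality assumption of the model
    concerns residuals, so residuals — not raw values — are tested.
    Candidates whose domain the data violates (negatives under sqrt,
    nonpositives under log) are excluded.
    """
    if series.transform != "identity":
        raise ValueError("select_transform expects an identity-scale series")
    if series.observed.size < 8:
        raise ValueError("need at least 8 observed bins to select a transform")
    report: dict[str, float] = {}
    for cand in TRANSFORMS:
        try:
            transformed = apply_transform(series, cand)
        except ValueError:
            continue
        resid = _segmented_residuals(transformed)
        if np.ptp(resid) < 1e-10 * max(1.0, float(np.abs(resid).max()), 1e-8):
            report[cand] = 1.0  # degenerate (perfect) fit: nothing to reject
        else:
            report[cand] = float(stats.shapiro(resid).pvalue)
    for cand in TRANSFORMS:
        if report.get(cand, -1.0) >= alpha:
            return cand, report
    return max(report, key=report.get), report


def difference_series(control: BinnedSeries, test: BinnedSeries) -> BinnedSeries:
    """Per-bin control-minus-test series on natural (identity) units."""
    if control.bin_width != test.bin_width:
        raise ValueError("bin widths differ")
    if control.transform != "identity" or test.transform != "identity":
        raise ValueError("differences are taken on the identity scale")
    if not control.values.index.equals(test.values.index):
        raise ValueError("bin ranges differ")
    values = control.values - test.values
    n_obs = pd.concat([control.n_observed, test.n_observed], axis=1).min(axis=1).astype(int)
    label = control.outcome_label or test.outcome_label
    return BinnedSeries(
        bin_width=control.bin_width,
        values=values,
        n_observed=n_obs,
        transform="identity",
        outcome_label=label,
    )
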