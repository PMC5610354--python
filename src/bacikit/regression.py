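"""Before/after segmented regression and ANCOVA slope comparison.

The working model on the transform scale is

    y_t = b0 + b1*t + b2*I(t >= 0) + b3*t*I(t >= 0) + e_t,

where ``t`` is the signed bin number and the after-indicator flips at
the intervention (bin 0). ``b3`` is the change in slope at
intervention; its two-tailed t-test is the ANCOVA slope comparison, and
equals the partial F-test obtained by dropping the interaction term.
Fitting the two periods separately reproduces the same segment
coefficients, so ``interaction = slope_after - slope_before`` exactly.

Outliers are screened iteratively by externally studentized residual
(|r| > 3), removing at most 10% of bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .timeseries import BinnedSeries

__all__ = [
    "SegmentFit",
    "SlopeComparison",
    "fit_segment",
    "compare_slopes",
    "prediction_interval",
    "exclude_outliers",
]

OUTLIER_Z = 3.0
OUTLIER_MAX_FRAC = 0.10


@dataclass
class SegmentFit:
    """OLS fit of one period: value ~ bin index."""

    intercept: float
    slope: float
    sse: float
    r2: float
    adj_r2: float
    rmse: float
    residuals: pd.Series
    n: int
    excluded_outliers: tuple[int, ...] = ()
    se_slope: float = float("nan")
    x: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class SlopeComparison:
    """ANCOVA contrast of before vs after slopes on one series."""

    fit_before: SegmentFit
    fit_after: SegmentFit
    interaction_estimate: float
    p_interaction: float
    p_partial_f: float
    common_fit: SegmentFit
    p_common_vs_before: float
    excluded_outliers: tuple[int, ...] = ()
    n: int = 0


def _ols_stats(x: np.ndarray, y: np.ndarray, bins: np.ndarray,
               excluded: tuple[int, ...] = ()) -> SegmentFit:
    X = sm.add_constant(x.astype(float), has_constant="add")
    res = sm.OLS(y.astype(float), X).fit()
    n = x.size
    sse = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        r2 = adj_r2 = 0.0
    else:
        r2 = 1.0 - sse / tss
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    rmse = float(np.sqrt(sse / (n - 2))) if n > 2 else 0.0
    return SegmentFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        sse=sse,
        r2=r2,
        adj_r2=adj_r2,
        rmse=rmse,
        residuals=pd.Series(res.resid, index=bins),
        n=n,
        excluded_outliers=tuple(excluded),
        se_slope=float(res.bse[1]),
        x=x.astype(float),
        y=y.astype(float),
    )


def _screen_outliers(
    x: np.ndarray,
    y: np.ndarray,
    design,
    min_keep: int = 3,
    z: float = OUTLIER_Z,
    max_frac: float = OUTLIER_MAX_FRAC,
    guard=None,
) -> np.ndarray:
    """Boolean keep-mask after iterative externally-studentized screening.

    ``design(x)`` builds the model matrix; ``guard(keep)`` may veto a
    proposed removal (used to keep >= 3 bins per period).
    """
    n = x.size
    cap = int(np.floor(max_frac * n))
    keep = np.ones(n, dtype=bool)
    removed = 0
    while removed < cap and keep.sum() > min_keep:
        X = design(x[keep])
        res = sm.OLS(y[keep], X).fit()
        if res.ssr <= 1e-12 * max(1.0, float(np.abs(y[keep]).max()) ** 2):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = OLSInfluence(res).resid_studentized_external
        r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
        worst = int(np.argmax(np.abs(r)))
        if np.abs(r[worst]) <= z:
            break
        candidate = keep.copy()
        candidate[np.flatnonzero(keep)[worst]] = False
        if guard is not None and not guard(candidate):
            warnings.warn("outlier removal stopped: would leave too few bins in a period")
            break
        keep = candidate
        removed += 1
    return keep


def _period_xy(series: BinnedSeries, period: str) -> tuple[np.ndarray, np.ndarray]:
    obs = series.period(period)
    return obs.index.to_numpy(dtype=float), obs.to_numpy(dtype=float)


def fit_segment(
    series: BinnedSeries, period: str = "before", outlier_exclusion: bool = True
) -> SegmentFit:
    """OLS of the series on bin index over one period.

    With ``outlier_exclusion`` the |externally studentized residual| > 3
    rule is applied (at most 10% of bins) before the final fit.
    """
    x, y = _period_xy(series, period)
    if x.size < 3:
        raise ValueError(f"need >= 3 observed bins in period '{period}', got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in bin index")
    excluded: tuple[int, ...] = ()
    if outlier_exclusion:
        design = lambda xs: sm.add_constant(xs, has_constant="add")
        keep = _screen_outliers(x, y, design)
        excluded = tuple(int(b) for b in x[~keep])
        x, y = x[keep], y[keep]
    return _ols_stats(x, y, bins=x.astype(int), excluded=excluded)


def exclude_outliers(
    series: BinnedSeries, period: str = "pooled"
) -> tuple[BinnedSeries, list[int]]:
    """Return the series with outlier bins masked, plus the removed bins."""
    x, y = _period_xy(series, period)
    if x.size < 3:
        raise ValueError("need >= 3 observed bins")
    design = lambda xs: sm.add_constant(xs, has_constant="add")
    keep = _screen_outliers(x, y, design)
    removed = [int(b) for b in x[~keep]]
    values = series.values.copy()
    values[removed] = np.nan
    out = BinnedSeries(
        bin_width=series.bin_width,
        values=values,
        n_observed=series.n_observed,
        transform=series.transform,
        outcome_label=series.outcome_label,
    )
    return out, removed


def _interaction_design(x: np.ndarray) -> np.ndarray:
    after = (x >= 0).astype(float)
    return np.column_stack([np.ones_like(x), x, after, x * after])


def compare_slopes(series: BinnedSeries, outlier_exclusion: bool = True) -> SlopeComparison:
    """Fit the segmented model and test the slope change at intervention.

    Also fits the pooled single line and contrasts its slope against the
    before-only slope (the "does combining before and after move the
    line?" check); because the pooled set contains the before points,
    that contrast is descriptive rather than an independent-samples test.
    """
    x, y = _period_xy(series, "pooled")
    before, after = x < 0, x >= 0
    if before.sum() < 3 or after.sum() < 3:
        raise ValueError("need >= 3 observed bins in each period")

    keep = np.ones(x.size, dtype=bool)
    if outlier_exclusion:
        guard = lambda cand: (cand & before).sum() >= 3 and (cand & after).sum() >= 3
        keep = _screen_outliers(x, y, _interaction_design, min_keep=6, guard=guard)
    excluded = tuple(int(b) for b in x[~keep])
    xk, yk = x[keep], y[keep]

    X = _interaction_design(xk)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design matrix")
    res = sm.OLS(yk, X).fit()
    b3 = float(res.params[3])
    if res.ssr <= 1e-12 * max(1.0, float(np.abs(yk).max()) ** 2):
        # Perfect fit: slope change is either exactly absent or certain.
        p_int = 1.0 if abs(b3) < 1e-12 else 0.0
        p_pf = p_int
    else:
        p_int = float(res.pvalues[3])
        red = sm.OLS(yk, X[:, :3]).fit()
        df_full = xk.size - 4
        f = (red.ssr - res.ssr) / (res.ssr / df_full)
        p_pf = float(stats.f.sf(f, 1, df_full))

    kb, ka = keep & before, keep & after
    fit_before = _ols_stats(x[kb], y[kb], bins=x[kb].astype(int),
                            excluded=tuple(int(b) for b in x[~keep & before]))
    fit_after = _ols_stats(x[ka], y[ka], bins=x[ka].astype(int),
                           excluded=tuple(int(b) for b in x[~keep & after]))
    common_fit = _ols_stats(xk, yk, bins=xk.astype(int), excluded=excluded)
    p_common = _common_vs_before_p(x[kb], y[kb], xk, yk)

    return SlopeComparison(
        fit_before=fit_before,
        fit_after=fit_after,
        interaction_estimate=b3,
        p_interaction=p_int,
        p_partial_f=p_pf,
        common_fit=common_fit,
        p_common_vs_before=p_common,
        excluded_outliers=excluded,
        n=int(keep.sum()),
    )


def _common_vs_before_p(xb, yb, xall, yall) -> float:
    """Slope contrast between the before-only line and the pooled line."""
    g = np.concatenate([np.zeros(xb.size), np.ones(xall.size)])
    xs = np.concatenate([xb, xall])
    ys = np.concatenate([yb, yall])
    X = np.column_stack([np.ones_like(xs), xs, g, xs * g])
    res = sm.OLS(ys, X).fit()
    if res.ssr <= 1e-12 * max(1.0, float(np.abs(ys).max()) ** 2):
        return 1.0 if abs(res.params[3]) < 1e-12 else 0.0
    return float(res.pvalues[3])


def prediction_interval(
    fit: SegmentFit, t: float, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided OLS new-observation interval at bin index ``t``.

    The interval contains a fresh single observation at ``t`` with the
    stated probability; it is symmetric about the fitted value and
    widens with leverage away from the data centroid.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if fit.n < 3:
        raise ValueError("need a fit with n >= 3")
    x = fit.x
    xbar = float(x.mean())
    sxx = float(np.sum((x - xbar) ** 2))
    yhat = float(fit.predict(t))
    se = fit.rmse * np.sqrt(1.0 + 1.0 / fit.n + (t - xbar) ** 2 / sxx)
    crit = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    half = float(crit * se)
    return yhat - half, yhat + half
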