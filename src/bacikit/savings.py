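"""Annualised rate curves, curve intersection and model-based savings.

A sqrt-scale segment fit ``a + b*t`` (t in bins of width ``w`` days)
back-transforms to a natural-scale bin expectation ``(a + b*t)**2``,
which annualises to the quadratic rate curve

    rate(t) = (365/w) * (a + b*t)**2        [AUD (or days, admissions) per year].

Identity-scale fits (e.g. control-minus-test difference series, which
need no transform) annualise linearly, clipped at zero.

Savings over the year after intervention are the area between the
projected before-curve and the actual after-curve, integrated in closed
form from the curves' intersection day (when one falls inside the year)
or from day 0. Integrating the per-year rate over time measured in
years makes the area come out directly in outcome units: for bins,
``total = integral_{t0}^{t1} (a + b*u)^2 du``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regression import SegmentFit

__all__ = [
    "AnnualRateCurve",
    "SavingsEstimate",
    "annualize",
    "find_intersection",
    "estimate_savings",
    "rate_reduction",
    "roi",
]

YEAR_DAYS = 365.0


@dataclass(frozen=True)
class AnnualRateCurve:
    """Annualised natural-scale rate curve from one segment fit."""

    bin_width: int
    a: float
    b: float
    domain: tuple[float, float]
    transform: str = "sqrt"
    unit: str = "AUD"

    def __post_init__(self) -> None:
        if self.transform not in ("sqrt", "identity"):
            raise ValueError("transform must be 'sqrt' or 'identity'")

    @property
    def scale_factor(self) -> float:
        return YEAR_DAYS / self.bin_width

    def sqrt_value(self, t):
        """The underlying transform-scale line a + b*t."""
        return self.a + self.b * np.asarray(t, dtype=float)

    def rate(self, t):
        """Rate in ``unit`` per year at bin index ``t``."""
        line = self.sqrt_value(t)
        if self.transform == "sqrt":
            return self.scale_factor * line**2
        return self.scale_factor * np.clip(line, 0.0, None)


@dataclass(frozen=True)
class SavingsEstimate:
    """Model-based annual savings from a before/after curve pair."""

    projected_annual_total: float
    actual_annual_total: float
    saving: float
    saving_pct: float
    rate_reduction_pct: float | None
    intersection_day: float | None
    start_day: float
    unit: str = "AUD"


def annualize(
    fit: SegmentFit,
    bin_width: int,
    transform: str = "sqrt",
    domain: tuple[float, float] | None = None,
    unit: str = "AUD",
) -> AnnualRateCurve:
    """Convert a segment fit into an annualised natural-scale rate curve."""
    if domain is None:
        if fit.x.size:
            domain = (float(fit.x.min()), float(fit.x.max()))
        else:
            domain = (0.0, YEAR_DAYS / bin_width)
    return AnnualRateCurve(
        bin_width=bin_width, a=fit.intercept, b=fit.slope,
        domain=domain, transform=transform, unit=unit,
    )


def find_intersection(
    before: AnnualRateCurve, after: AnnualRateCurve, horizon_days: float = YEAR_DAYS
) -> float | None:
    """Day (>= 0, within the horizon) where the two curves cross.

    Both curves square (or clip) the same kind of line, so the crossing
    solves ``a1 + b1*t = a2 + b2*t`` on the transform scale. Identical
    lines intersect at day 0 by convention; parallel distinct lines do
    not intersect.
    """
    _check_compatible(before, after)
    a1, b1, a2, b2 = before.a, before.b, after.a, after.b
    if b1 == b2:
        return 0.0 if a1 == a2 else None
    t_star = (a2 - a1) / (b1 - b2)
    day = t_star * before.bin_width
    if 0.0 <= day <= horizon_days:
        return float(day)
    return None


def _check_compatible(before: AnnualRateCurve, after: AnnualRateCurve) -> None:
    if before.bin_width != after.bin_width:
        raise ValueError("curves have different bin widths")
    if before.transform != after.transform:
        raise ValueError("curves are on different transform scales")
    if before.unit != after.unit:
        raise ValueError(f"unit mismatch: {before.unit} vs {after.unit}")


def _integral(curve: AnnualRateCurve, t0: float, t1: float) -> float:
    """Closed-form integral of the natural-scale bin expectation over bins.

    Equals (1/365) * integral of rate over days, i.e. the total outcome
    accrued on [t0, t1] in the curve's unit.
    """
    a, b = curve.a, curve.b
    if curve.transform == "sqrt":
        line0, line1 = a + b * t0, a + b * t1
        if line0 * line1 < 0:
            raise ValueError(
                "sqrt-scale line changes sign inside the integration window; "
                "refusing to extrapolate the squared curve past its root"
            )
        if b == 0:
            return a**2 * (t1 - t0)
        return (line1**3 - line0**3) / (3.0 * b)
    # identity: integrate max(a + b*u, 0) piecewise
    return _clipped_linear_integral(a, b, t0, t1)


def _clipped_linear_integral(a: float, b: float, t0: float, t1: float) -> float:
    def seg(lo: float, hi: float) -> float:
        if hi <= lo:
            return 0.0
        return a * (hi - lo) + 0.5 * b * (hi * hi - lo * lo)

    if b == 0:
        return max(a, 0.0) * (t1 - t0)
    root = -a / b
    if b > 0:
        return seg(max(t0, root), t1) if root > t0 else seg(t0, t1)
    return seg(t0, min(t1, root)) if root < t1 else seg(t0, t1)


def estimate_savings(
    before: AnnualRateCurve,
    after: AnnualRateCurve,
    horizon_days: float = YEAR_DAYS,
    start_day: float | None = None,
) -> SavingsEstimate:
    """Area-between-curves savings over the year after intervention.

    The before-curve (3-year historical trajectory) is projected across
    the after-year; savings accrue from ``start_day`` — by default the
    curves' intersection when it falls inside the year, else day 0 —
    reflecting that the intervention may need time to take effect. An
    after-curve above the before-curve yields a negative saving,
    reported as such.
    """
    _check_compatible(before, after)
    intersection = find_intersection(before, after, horizon_days)
    if start_day is None:
        start_day = intersection if intersection is not None else 0.0
    if not 0.0 <= start_day <= horizon_days:
        raise ValueError("start_day must lie in [0, horizon_days]")
    w = before.bin_width
    t0, t1 = start_day / w, horizon_days / w
    projected = _integral(before, t0, t1)
    actual = _integral(after, t0, t1)
    saving = projected - actual
    saving_pct = 100.0 * saving / projected if projected != 0 else 0.0
    t_year = horizon_days / w
    rb = float(before.rate(t_year))
    if rb > 0:
        reduction = 100.0 * (1.0 - float(after.rate(t_year)) / rb)
    else:
        reduction = 0.0 if float(after.rate(t_year)) == 0.0 else None
    return SavingsEstimate(
        projected_annual_total=float(projected),
        actual_annual_total=float(actual),
        saving=float(saving),
        saving_pct=float(saving_pct),
        rate_reduction_pct=reduction,
        intersection_day=intersection,
        start_day=float(start_day),
        unit=before.unit,
    )


def rate_reduction(
    before: AnnualRateCurve, after: AnnualRateCurve, at_days: float = YEAR_DAYS
) -> float:
    """Percent reduction of the annual rate at ``at_days`` after start."""
    _check_compatible(before, after)
    t = at_days / before.bin_width
    rb = float(before.rate(t))
    if rb == 0:
        raise ValueError("before-curve rate is zero at the evaluation point")
    return 100.0 * (1.0 - float(after.rate(t)) / rb)


def roi(annual_saving: float, annual_service_cost: float) -> float:
    """Return on investment: annual saving per dollar of service cost."""
    if annual_service_cost <= 0:
        raise ValueError("annual_service_cost must be positive")
    return annual_saving / annual_service_cost
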