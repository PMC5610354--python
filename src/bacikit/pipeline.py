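"""End-to-end orchestration: simulate/load -> match -> bin -> regress ->
savings -> mortality -> baseline -> structured report.

Every stochastic step is seeded from the analysis seed, so an identical
configuration produces a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import baseline as bl
from . import mortality as mort
from .errors import ConfigurationError, SchemaError
from .matching import MatchResult, average_controls, match_controls
from .regression import SlopeComparison, compare_slopes
from .savings import annualize, estimate_savings
from .synthetic import generate_cohort
from .timeseries import (
    BinnedSeries,
    average_patients,
    apply_transform,
    bin_patients,
    difference_series,
    select_transform,
)
from .types import (
    ADMISSION_COLUMNS,
    AGE_BANDS,
    CLAIM_COLUMNS,
    CohortConfig,
    age_band_index,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "load_cohort_csvs"]

log = logging.getLogger("bacikit")

COST_OUTCOMES = {"medical_cost": "medical", "pharma_cost": "pharmaceutical"}
HOSPITAL_OUTCOMES = ("admissions", "los")
ALL_OUTCOMES = tuple(COST_OUTCOMES) + HOSPITAL_OUTCOMES
OUTCOME_UNITS = {
    "medical_cost": "AUD",
    "pharma_cost": "AUD",
    "admissions": "admissions",
    "los": "days",
}


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end analysis run."""

    outdir: Path | None = None
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    patients_csv: Path | None = None
    claims_csv: Path | None = None
    admissions_csv: Path | None = None
    outcomes: tuple[str, ...] = ALL_OUTCOMES
    alpha: float = 0.05
    seed: int | None = None
    k_max: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        bad = set(self.outcomes) - set(ALL_OUTCOMES)
        if bad:
            raise ConfigurationError(f"unknown outcomes: {sorted(bad)}")
        if self.seed is not None:
            self.cohort = self.cohort.replace(seed=int(self.seed))
        if not self.simulate:
            missing = [
                n for n, p in (
                    ("patients_csv", self.patients_csv),
                    ("claims_csv", self.claims_csv),
                ) if p is None
            ]
            if missing:
                raise ConfigurationError(f"non-simulated run requires {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig.from_dict(raw.pop("cohort", {}))
        raw.update(overrides)
        raw.setdefault("cohort", cohort)
        if "outcomes" in raw and raw["outcomes"] is not None:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Report models (the published report schema is generated from these).

class SegmentFitReport(BaseModel):
    intercept: float
    slope: float
    se_slope: float
    sse: float
    r2: float
    adj_r2: float
    rmse: float
    n: int
    excluded_outliers: list[int]


class SlopeComparisonReport(BaseModel):
    before: SegmentFitReport
    after: SegmentFitReport
    interaction_estimate: float
    p_interaction: float
    p_partial_f: float
    p_common_vs_before: float


class SavingsReport(BaseModel):
    projected_annual_total: float
    actual_annual_total: float
    saving: float
    saving_pct: float
    rate_reduction_pct: float | None
    intersection_day: float | None
    start_day: float
    unit: str


class ArmOutcomeReport(BaseModel):
    arm: str
    transform: str
    comparison: SlopeComparisonReport | None = None
    savings: SavingsReport | None = None
    error: str | None = None


class OutcomeReport(BaseModel):
    outcome: str
    bin_width: int
    transform: str
    normality_p: dict[str, float]
    arms: list[ArmOutcomeReport]


class MortalityArmReport(BaseModel):
    n: int
    observed_deaths: int
    crude_rate_pct: float


class MortalityReport(BaseModel):
    arms: dict[str, MortalityArmReport]
    crude_reduction_pct: float | None = None
    crude_reduction_pct_as_printed: float | None = None
    expected_total: float | None = None
    deaths_saved: float | None = None
    reduction_pct: float | None = None
    as_printed: dict | None = None


class WindowReport(BaseModel):
    window: str
    variable: str
    control_mean: float
    control_ci: tuple[float, float]
    test_mean: float
    test_ci: tuple[float, float]
    p_paired: float
    method: str
    n_pairs: int
    excluded: list[str]


class BaselineReport(BaseModel):
    windows: list[WindowReport]
    annualized_difference: float | None = None
    annualized_difference_reported: int | None = None


class AnalysisReport(BaseModel):
    """Machine-readable result bundle of one pipeline run."""

    package: str = "bacikit"
    seed: int
    simulated: bool
    cohort_config: dict | None
    n_test: int
    n_controls: int
    n_pairs: int
    unmatched: list[str]
    outcomes: list[OutcomeReport]
    mortality: MortalityReport | None = None
    baseline: BaselineReport | None = None


# ---------------------------------------------------------------------------


def load_cohort_csvs(
    patients_csv: str | Path,
    claims_csv: str | Path,
    admissions_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and schema-check the three cohort tables."""
    patients = pd.read_csv(patients_csv)
    _require(patients, ["patient_id", "arm", "age_at_intervention", "gender",
                        "diagnosis_group", "seifa"], patients_csv)
    if "death_day" not in patients:
        patients["death_day"] = np.nan
    if "matched_test_id" not in patients:
        patients["matched_test_id"] = ""
    patients["matched_test_id"] = patients["matched_test_id"].fillna("")
    claims = pd.read_csv(claims_csv)
    _require(claims, CLAIM_COLUMNS, claims_csv)
    if (claims["cost"] < 0).any():
        row = int(claims.index[claims["cost"] < 0][0])
        raise SchemaError(f"{claims_csv}: negative cost at row {row}, column 'cost'")
    if admissions_csv is not None:
        admissions = pd.read_csv(admissions_csv)
        _require(admissions, ADMISSION_COLUMNS, admissions_csv)
    else:
        admissions = pd.DataFrame(columns=ADMISSION_COLUMNS)
    dup = patients["patient_id"].duplicated()
    if dup.any():
        raise SchemaError(f"{patients_csv}: duplicate patient_id at row {int(patients.index[dup][0])}")
    return patients, claims, admissions


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _events_for(outcome: str, claims: pd.DataFrame, admissions: pd.DataFrame):
    """(events, width, value_col, day_col) for one outcome."""
    if outcome in COST_OUTCOMES:
        ev = claims[claims["category"] == COST_OUTCOMES[outcome]]
        return ev, 30, "cost", "day"
    adm = admissions[admissions["overnight"].astype(bool)].copy()
    if outcome == "admissions":
        adm["count"] = 1.0
        return adm, 100, "count", "admit_day"
    adm["los"] = adm["los"].astype(float)
    return adm, 100, "los", "admit_day"


def _comparison_report(cmp: SlopeComparison) -> SlopeComparisonReport:
    def seg(f):
        return SegmentFitReport(
            intercept=f.intercept, slope=f.slope, se_slope=f.se_slope, sse=f.sse,
            r2=f.r2, adj_r2=f.adj_r2, rmse=f.rmse, n=f.n,
            excluded_outliers=[int(b) for b in f.excluded_outliers],
        )
    return SlopeComparisonReport(
        before=seg(cmp.fit_before),
        after=seg(cmp.fit_after),
        interaction_estimate=cmp.interaction_estimate,
        p_interaction=cmp.p_interaction,
        p_partial_f=cmp.p_partial_f,
        p_common_vs_before=cmp.p_common_vs_before,
    )


def _arm_analysis(
    series: BinnedSeries, arm: str, transform: str, width: int, unit: str
) -> ArmOutcomeReport:
    try:
        working = apply_transform(series, transform) if series.transform == "identity" and transform != "identity" else series
        cmp = compare_slopes(working)
    except ValueError as exc:
        return ArmOutcomeReport(arm=arm, transform=transform, error=str(exc))
    savings_rep = None
    try:
        curve_transform = "sqrt" if transform == "sqrt" else "identity"
        before = annualize(cmp.fit_before, width, transform=curve_transform, unit=unit)
        after = annualize(cmp.fit_after, width, transform=curve_transform, unit=unit)
        est = estimate_savings(before, after)
        savings_rep = SavingsReport(**est.__dict__)
    except ValueError as exc:
        log.warning("savings unavailable for %s: %s", arm, exc)
        return ArmOutcomeReport(
            arm=arm, transform=transform, comparison=_comparison_report(cmp),
            error=f"savings unavailable: {exc}",
        )
    return ArmOutcomeReport(
        arm=arm, transform=transform, comparison=_comparison_report(cmp),
        savings=savings_rep,
    )


def _outcome_report(
    outcome: str,
    claims: pd.DataFrame,
    admissions: pd.DataFrame,
    patients: pd.DataFrame,
    pairs: MatchResult,
    alpha: float,
) -> tuple[OutcomeReport, pd.DataFrame]:
    events, width, value_col, day_col = _events_for(outcome, claims, admissions)
    totals, _ = bin_patients(events, patients, width, value_col=value_col, day_col=day_col)

    test_ids = [p.test_id for p in pairs.pairs]
    test_series = average_patients(totals.loc[test_ids], outcome, width)
    eff = {
        p.test_id: average_controls([totals.loc[c] for c in p.control_ids])
        for p in pairs.pairs
    }
    ctrl_series = average_patients(pd.DataFrame(eff).T, outcome, width)

    transform, normality = select_transform(test_series, alpha=alpha)
    if transform == "log":
        # log curves have no quadratic annualisation; fall back to the
        # next-best of the supported transforms for this machinery.
        transform = max(
            (c for c in ("identity", "sqrt") if c in normality),
            key=normality.get,
        )
    unit = OUTCOME_UNITS[outcome]

    arms = [
        _arm_analysis(test_series, "test", transform, width, unit),
        _arm_analysis(ctrl_series, "control", transform, width, unit),
        _arm_analysis(
            difference_series(ctrl_series, test_series), "difference",
            "identity", width, unit,
        ),
    ]
    rep = OutcomeReport(
        outcome=outcome, bin_width=width, transform=transform,
        normality_p={k: float(v) for k, v in sorted(normality.items())}, arms=arms,
    )

    binned_rows = []
    for arm_name, s in (("test", test_series), ("control", ctrl_series)):
        for b, v in s.values.items():
            binned_rows.append(
                {"outcome_label": outcome, "arm": arm_name, "bin_index": int(b),
                 "n_observed": int(s.n_observed[b]),
                 "value": v, "transform": s.transform}
            )
    return rep, pd.DataFrame(binned_rows)


def _mortality_report(patients: pd.DataFrame, cfg: CohortConfig | None) -> MortalityReport:
    arms: dict[str, MortalityArmReport] = {}
    observed_by_band: dict[str, list[int]] = {}
    for arm in ("test", "control"):
        sub = patients[patients["arm"] == arm]
        died = sub["death_day"].notna()
        arms[arm] = MortalityArmReport(
            n=len(sub), observed_deaths=int(died.sum()),
            crude_rate_pct=mort.crude_rate(int(died.sum()), len(sub)) if len(sub) else 0.0,
        )
        counts = [0] * len(AGE_BANDS)
        for age, d in zip(sub["age_at_intervention"], died):
            if d:
                counts[age_band_index(age)] += 1
        observed_by_band[arm] = counts

    rep = MortalityReport(arms=arms)
    rc, rt = arms["control"].crude_rate_pct, arms["test"].crude_rate_pct
    if rc > 0:
        rep.crude_reduction_pct = mort.crude_reduction(rt, rc)
        rep.crude_reduction_pct_as_printed = mort.crude_reduction(rt, rc, as_printed=True)
    if cfg is not None:
        # Standardise the test arm against the configured register rates,
        # scaled to the simulated observation window.
        window_p = [
            100.0 * (1.0 - (1.0 - p) ** (cfg.days_after / 365.0))
            for p in cfg.asdr_per_band
        ]
        pseudo_pop = 10_000
        table = mort.compute_asdr(
            pop=[pseudo_pop] * len(AGE_BANDS),
            deaths=[int(round(p / 100.0 * pseudo_pop)) for p in window_p],
        )
        sub = patients[patients["arm"] == "test"]
        cohort_counts = [0] * len(AGE_BANDS)
        for age in sub["age_at_intervention"]:
            cohort_counts[age_band_index(age)] += 1
        cmp = mort.expected_deaths(table, cohort_counts, observed_by_band["test"])
        rep.expected_total = cmp.expected_total
        rep.deaths_saved = cmp.deaths_saved
        rep.reduction_pct = (
            cmp.reduction_pct if np.isfinite(cmp.reduction_pct) else None
        )
        rep.as_printed = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in cmp.printed.items()
        }
    return rep


def _baseline_report(
    claims: pd.DataFrame, patients: pd.DataFrame, pairs: MatchResult, default_end: int
) -> BaselineReport:
    windows: list[WindowReport] = []
    ann = None
    for window in ("pre_start", "pre_end"):
        totals, excluded = bl.window_totals(claims, patients, window, default_end)
        test_v, ctrl_v = [], []
        for p in pairs.pairs:
            if p.test_id not in totals.index:
                continue
            ctl = [totals[c] for c in p.control_ids if c in totals.index]
            if not ctl:
                continue
            test_v.append(totals[p.test_id])
            ctrl_v.append(float(np.mean(ctl)))
        if len(test_v) < 3:
            continue
        summary = bl.summarize_window(window, np.array(test_v), np.array(ctrl_v))
        windows.append(
            WindowReport(
                window=window, variable="total",
                control_mean=summary.control_mean, control_ci=summary.control_ci,
                test_mean=summary.test_mean, test_ci=summary.test_ci,
                p_paired=summary.p_paired, method=summary.method,
                n_pairs=summary.n_pairs, excluded=excluded,
            )
        )
        if window == "pre_end":
            raw, reported = bl.annualized_group_difference(
                summary.control_mean, summary.test_mean
            )
            ann = (raw, reported)
    rep = BaselineReport(windows=windows)
    if ann is not None:
        rep.annualized_difference, rep.annualized_difference_reported = ann
    return rep


def run_pipeline(config: AnalysisConfig, write: bool = True) -> AnalysisReport:
    """Execute the full BACI analysis and (optionally) write the bundle.

    Writes ``report.json``, ``summary.txt``, ``binned.csv`` and
    ``pairs.csv`` to ``config.outdir`` (plus the simulated cohort CSVs
    in simulate mode). Identical configs produce identical bundles.
    """
    if config.simulate:
        cohort = generate_cohort(config.cohort)
        patients, claims, admissions = cohort.patients, cohort.claims, cohort.admissions
        cohort_cfg: CohortConfig | None = config.cohort
        default_end = config.cohort.days_after
    else:
        patients, claims, admissions = load_cohort_csvs(
            config.patients_csv, config.claims_csv, config.admissions_csv
        )
        cohort = None
        cohort_cfg = None
        default_end = 360

    tests = patients[patients["arm"] == "test"]
    pool = patients[patients["arm"] == "control"]
    k_max = config.k_max or (cohort_cfg.controls_per_test if cohort_cfg else 2)
    pairs = match_controls(tests, pool, k_max=k_max)
    log.info("matched %d pairs (%d unmatched)", len(pairs.pairs), len(pairs.unmatched))

    outcome_reports: list[OutcomeReport] = []
    binned_frames: list[pd.DataFrame] = []
    for outcome in config.outcomes:
        rep, binned = _outcome_report(
            outcome, claims, admissions, patients, pairs, config.alpha
        )
        outcome_reports.append(rep)
        binned_frames.append(binned)

    report = AnalysisReport(
        seed=config.cohort.seed if config.simulate else (config.seed or 0),
        simulated=config.simulate,
        cohort_config=cohort_cfg.to_dict() if cohort_cfg else None,
        n_test=len(tests),
        n_controls=len(pool),
        n_pairs=len(pairs.pairs),
        unmatched=pairs.unmatched,
        outcomes=outcome_reports,
        mortality=_mortality_report(patients, cohort_cfg),
        baseline=_baseline_report(claims, patients, pairs, default_end),
    )

    if write and config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if cohort is not None:
            cohort.write(outdir)
        pairs.to_frame().to_csv(outdir / "pairs.csv", index=False)
        if binned_frames:
            pd.concat(binned_frames, ignore_index=True).to_csv(
                outdir / "binned.csv", index=False
            )
        (outdir / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
        (outdir / "summary.txt").write_text(summarize(report))
        fits = {
            oc.outcome: {
                a.arm: a.comparison.model_dump() if a.comparison else {"error": a.error}
                for a in oc.arms
            }
            for oc in report.outcomes
        }
        (outdir / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n")
        savings = {
            oc.outcome: {
                a.arm: a.savings.model_dump() for a in oc.arms if a.savings is not None
            }
            for oc in report.outcomes
        }
        (outdir / "savings.json").write_text(
            json.dumps(savings, indent=2, sort_keys=True) + "\n"
        )
    return report


def summarize(report: AnalysisReport) -> str:
    """Short human-readable digest of a report."""
    lines = [
        f"BACI analysis ({'simulated' if report.simulated else 'observed'} cohort, seed {report.seed})",
        f"  {report.n_test} test patients, {report.n_controls} controls, "
        f"{report.n_pairs} matched pairs, {len(report.unmatched)} unmatched",
    ]
    for oc in report.outcomes:
        lines.append(f"  outcome {oc.outcome} ({oc.bin_width}-day bins, {oc.transform} scale):")
        for arm in oc.arms:
            if arm.comparison is None:
                lines.append(f"    {arm.arm}: {arm.error}")
                continue
            c = arm.comparison
            msg = (
                f"    {arm.arm}: slope {c.before.slope:+.4f} -> "
                f"{c.after.slope:+.4f} per bin (interaction p={c.p_interaction:.3g})"
            )
            if arm.savings is not None:
                s = arm.savings
                msg += (
                    f"; saving {s.saving:,.0f} {s.unit}/yr ({s.saving_pct:.1f}%), "
                    f"rate reduction at 1 yr "
                    + (f"{s.rate_reduction_pct:.1f}%" if s.rate_reduction_pct is not None else "n/a")
                )
            lines.append(msg)
    m = report.mortality
    if m is not None:
        for arm, a in m.arms.items():
            lines.append(
                f"  mortality {arm}: {a.observed_deaths}/{a.n} "
                f"(crude {a.crude_rate_pct:.1f}%)"
            )
        if m.reduction_pct is not None:
            lines.append(
                f"  standardised mortality reduction: {m.reduction_pct:.1f}% "
                f"(expected {m.expected_total:.2f} deaths)"
            )
    b = report.baseline
    if b is not None and b.annualized_difference_reported is not None:
        lines.append(
            f"  annualised end-of-trial expenditure difference (control - test): "
            f"{b.annualized_difference_reported} AUD/yr"
        )
    return "\n".join(lines) + "\n"


def write_report_schema(path: str | Path) -> None:
    """Write the JSON schema the report bundle validates against."""
    Path(path).write_text(
        json.dumps(AnalysisReport.model_json_schema(), indent=2, sort_keys=True) + "\n"
    )
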