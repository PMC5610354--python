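"""Synthetic matched-cohort generator.

Emulates the data structure the BACI analysis assumes, without any real
patient records:

* per-patient claim streams whose 30-day bin totals have an
  approximately normal square root, with a linearly drifting sqrt-scale
  mean (rising pre-intervention, drift changed by a per-arm delta from
  intervention onward);
* sparse overdispersed (gamma-Poisson) hospital admission counts per
  100-day bin, each admission carrying a length of stay;
* deaths as a constant per-day hazard within each 10-year age band,
  calibrated so the annual death probability matches the configured
  age-specific death rate, applied from the intervention day onward
  (trial cohorts are alive at enrolment by construction);
* controls generated as exact matches of their test partner on gender,
  diagnosis group, SEIFA level and age band, inheriting the partner's
  intervention anchor date.

For 30-day bin index ``t`` (t = -nb..na-1, nb = days_before/30) the
expected bin total is ``(baseline_sqrt_cost + pre_slope_sqrt*(t+nb) +
delta_arm*max(t, 0))**2``; bin totals are realised as Poisson many
gamma-amount claims rescaled so the bin sum hits the sampled target
exactly, which preserves the sqrt-linear mean structure downstream
regressions rely on.

Identical seeds yield byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import (
    ADMISSION_COLUMNS,
    AGE_BANDS,
    CLAIM_COLUMNS,
    DIAGNOSIS_GROUPS,
    PATIENT_COLUMNS,
    CohortConfig,
)

__all__ = ["Cohort", "generate_cohort"]


@dataclass
class Cohort:
    """A generated cohort: three event tables plus the generating config."""

    patients: pd.DataFrame
    claims: pd.DataFrame
    admissions: pd.DataFrame
    config: CohortConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write patients/claims/admissions CSVs and a JSON config sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": outdir / "patients.csv",
            "claims": outdir / "claims.csv",
            "admissions": outdir / "admissions.csv",
            "config": outdir / "cohort_config.json",
        }
        self.patients.to_csv(paths["patients"], index=False)
        self.claims.to_csv(paths["claims"], index=False)
        self.admissions.to_csv(paths["admissions"], index=False)
        paths["config"].write_text(
            json.dumps(self.config.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        return paths


def _death_days(rng: np.random.Generator, p_annual: np.ndarray, days_after: int) -> np.ndarray:
    """Constant-hazard death day per patient (NaN = survives the window).

    The per-day hazard lam solves 1-exp(-365*lam) = p_annual, so the
    probability of death within one year equals the configured ASDR.
    """
    lam = -np.log1p(-p_annual) / 365.0
    u = rng.random(p_annual.size)
    with np.errstate(divide="ignore"):
        t = np.where(lam > 0, -np.log(u) / np.where(lam > 0, lam, 1.0), np.inf)
    return np.where(t < days_after, np.floor(t), np.nan)


def _claim_events(
    rng: np.random.Generator,
    cfg: CohortConfig,
    is_test: np.ndarray,
    death_day: np.ndarray,
) -> pd.DataFrame:
    n = is_test.size
    nb, na = cfg.days_before // 30, cfg.days_after // 30
    t = np.arange(-nb, na)
    delta = np.where(is_test, cfg.post_slope_delta_test, cfg.post_slope_delta_control)
    line = (
        cfg.baseline_sqrt_cost
        + cfg.pre_slope_sqrt * (t + nb)[None, :]
        + delta[:, None] * np.maximum(t, 0)[None, :]
    )
    line = np.clip(line, 0.0, None)
    sqrt_target = line
    if cfg.cost_noise_sd > 0:
        sqrt_target = np.clip(line + rng.normal(0.0, cfg.cost_noise_sd, line.shape), 0.0, None)
    total = sqrt_target**2

    counts = rng.poisson(cfg.claims_per_bin, total.shape)
    counts = np.where(total > 0, np.maximum(counts, 1), 0)

    flat = counts.ravel()
    cell = np.repeat(np.arange(flat.size), flat)
    pat = cell // t.size
    bin_t = t[cell % t.size]
    amounts = rng.gamma(1.5, 1.0, cell.size)
    cell_sum = np.bincount(cell, weights=amounts, minlength=flat.size)
    cost = amounts * total.ravel()[cell] / cell_sum[cell]
    day = bin_t * 30 + rng.integers(0, 30, cell.size)
    category = np.where(
        rng.random(cell.size) < cfg.medical_fraction, "medical", "pharmaceutical"
    )

    alive = np.isnan(death_day[pat]) | (day <= death_day[pat])
    return pd.DataFrame(
        {"patient_idx": pat[alive], "day": day[alive],
         "category": category[alive], "cost": cost[alive]}
    )


def _admission_events(
    rng: np.random.Generator,
    cfg: CohortConfig,
    is_test: np.ndarray,
    death_day: np.ndarray,
) -> pd.DataFrame:
    n = is_test.size
    nb = -(-cfg.days_before // 100)  # ceil: bin-aligned horizons
    na = -(-cfg.days_after // 100)
    t = np.arange(-nb, na)
    adm_mult = np.where(
        is_test, cfg.admission_post_multiplier_test, cfg.admission_post_multiplier_control
    )
    mu = cfg.admission_rate_per_100d * np.where(
        (t >= 0)[None, :], adm_mult[:, None], 1.0
    )
    if cfg.admission_rate_per_100d > 0:
        k = cfg.admission_dispersion
        lam = rng.gamma(k, mu / k)  # gamma-Poisson mixture -> overdispersed counts
        counts = rng.poisson(lam)
    else:
        counts = np.zeros((n, t.size), dtype=int)

    flat = counts.ravel()
    ev = np.repeat(np.arange(flat.size), flat)
    pat = ev // t.size
    bin_t = t[ev % t.size]
    admit_day = bin_t * 100 + rng.integers(0, 100, ev.size)
    overnight = rng.random(ev.size) < cfg.overnight_fraction
    los_mult = np.where(
        is_test[pat], cfg.los_post_multiplier_test, cfg.los_post_multiplier_control
    )
    mean_los = np.where(admit_day >= 0, cfg.los_mean_days * los_mult, cfg.los_mean_days)
    los = 1 + rng.poisson(np.maximum(mean_los - 1.0, 0.0))
    los = np.where(overnight, los, 1)

    alive = np.isnan(death_day[pat]) | (admit_day <= death_day[pat])
    return pd.DataFrame(
        {"patient_idx": pat[alive], "admit_day": admit_day[alive],
         "los": los[alive], "overnight": overnight[alive]}
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a matched test/control cohort with full event histories.

    Each test patient receives ``controls_per_test`` controls matched
    exactly on gender, diagnosis group, SEIFA and 10-year age band.
    Reproducible: the same config (including seed) yields byte-identical
    tables.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_t, k = cfg.n_test, cfg.controls_per_test

    band_t = rng.choice(len(AGE_BANDS), n_t, p=np.asarray(cfg.age_band_weights))
    gender_t = np.where(rng.random(n_t) < cfg.male_fraction, "M", "F")
    diag_t = rng.choice(DIAGNOSIS_GROUPS, n_t, p=np.asarray(cfg.diagnosis_weights))
    seifa_t = rng.integers(1, cfg.seifa_levels + 1, n_t)
    age_t = 50.0 + band_t * 10 + rng.random(n_t) * 10
    anchor_t = rng.integers(0, 365, n_t)

    # Controls clone the match variables of their test partner; age is
    # re-drawn within the same band so continuous ages differ.
    rep = np.repeat(np.arange(n_t), k)
    band = np.concatenate([band_t, band_t[rep]])
    gender = np.concatenate([gender_t, gender_t[rep]])
    diag = np.concatenate([diag_t, diag_t[rep]])
    seifa = np.concatenate([seifa_t, seifa_t[rep]])
    age_c = 50.0 + band_t[rep] * 10 + rng.random(n_t * k) * 10
    age = np.concatenate([age_t, age_c])
    anchor = np.concatenate([anchor_t, anchor_t[rep]])

    test_ids = np.array([f"T{i + 1:04d}" for i in range(n_t)])
    ctrl_ids = np.array(
        [f"C{i + 1:04d}-{j + 1}" for i in range(n_t) for j in range(k)]
    )
    ids = np.concatenate([test_ids, ctrl_ids])
    arm = np.array(["test"] * n_t + ["control"] * (n_t * k))
    matched = np.concatenate([np.full(n_t, ""), test_ids[rep]])
    is_test = arm == "test"

    p_annual = np.asarray(cfg.asdr_per_band)[band]
    death_day = _death_days(rng, p_annual, cfg.days_after)

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "arm": arm,
            "age_at_intervention": np.round(age, 2),
            "gender": gender,
            "diagnosis_group": diag,
            "seifa": seifa,
            "intervention_date": anchor,
            "death_day": death_day,
            "matched_test_id": matched,
        },
        columns=PATIENT_COLUMNS,
    )

    claims = _claim_events(rng, cfg, is_test, death_day)
    claims["patient_id"] = ids[claims.pop("patient_idx").to_numpy()]
    claims = (
        claims[CLAIM_COLUMNS]
        .sort_values(["patient_id", "day", "category", "cost"], kind="mergesort")
        .reset_index(drop=True)
    )

    admissions = _admission_events(rng, cfg, is_test, death_day)
    admissions["patient_id"] = ids[admissions.pop("patient_idx").to_numpy()]
    admissions = (
        admissions[ADMISSION_COLUMNS]
        .sort_values(["patient_id", "admit_day", "los"], kind="mergesort")
        .reset_index(drop=True)
    )

    return Cohort(patients=patients, claims=claims, admissions=admissions, config=cfg)
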