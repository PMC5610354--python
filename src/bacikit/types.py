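"""Domain types shared across the pipeline.

The analysis operates on three event tables keyed by an opaque
``patient_id`` — demographics, dated claim costs, and hospital
admissions — with all dates expressed as signed integer day offsets
from each patient's intervention anchor (day 0 = first monitored day;
controls inherit the anchor of their matched test patient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

from .errors import ConfigurationError

#: Ten-year age bands spanning the eligible 50-100 range, in order.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (50, 60), (60, 70), (70, 80), (80, 90), (90, 100),
)

AGE_BAND_LABELS: tuple[str, ...] = tuple(f"{lo}-{hi}" for lo, hi in AGE_BANDS)

DIAGNOSIS_GROUPS: tuple[str, ...] = ("cardiovascular", "respiratory", "diabetes")

ARMS: tuple[str, ...] = ("test", "control")

CLAIM_CATEGORIES: tuple[str, ...] = ("medical", "pharmaceutical")


def age_band_index(age: float) -> int:
    """Return the index of the 10-year band containing ``age`` (50-100)."""
    if age < AGE_BANDS[0][0]:
        raise ValueError(f"age {age} below eligibility threshold {AGE_BANDS[0][0]}")
    for i, (lo, hi) in enumerate(AGE_BANDS):
        if lo <= age < hi:
            return i
    return len(AGE_BANDS) - 1  # 100th birthday edge case: top band


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic matched-cohort generator.

    The defaults describe the study conditions the analysis machinery
    assumes: a 100-patient test arm matched 1:2, expenditure whose
    square root drifts linearly upward on the 30-day-bin scale with the
    test arm's drift halved at intervention, sparse overdispersed
    hospital admissions, and age-band death hazards taken from a
    1,429-patient hospital master register of comparable chronically
    ill Australians.

    Units: ``baseline_sqrt_cost``, ``pre_slope_sqrt``, the two slope
    deltas and ``cost_noise_sd`` are on the sqrt(AUD per 30-day bin)
    scale (slopes per bin); ``asdr_per_band`` are annual death
    probabilities; horizons are in days.
    """

    n_test: int = 100
    controls_per_test: int = 2
    age_band_weights: tuple[float, ...] = (0.41, 0.31, 0.14, 0.13, 0.01)
    male_fraction: float = 0.67
    diagnosis_weights: tuple[float, ...] = (0.50, 0.30, 0.20)
    seifa_levels: int = 5
    pre_slope_sqrt: float = 0.12
    post_slope_delta_test: float = -0.06
    post_slope_delta_control: float = 0.0
    baseline_sqrt_cost: float = 20.0
    cost_noise_sd: float = 2.0
    admission_rate_per_100d: float = 0.6
    admission_post_multiplier_test: float = 0.5
    admission_post_multiplier_control: float = 1.0
    los_mean_days: float = 7.0
    los_post_multiplier_test: float = 0.4
    los_post_multiplier_control: float = 1.0
    asdr_per_band: tuple[float, ...] = (0.0944, 0.1484, 0.1361, 0.2198, 0.4405)
    days_before: int = 1080
    days_after: int = 360
    seed: int = 0
    # Event-stream texture (sparse-claims realism; does not affect bin means).
    claims_per_bin: float = 3.0
    medical_fraction: float = 0.65
    admission_dispersion: float = 2.0
    overnight_fraction: float = 0.95

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_test < 1:
            raise ConfigurationError("n_test must be >= 1")
        if not 1 <= self.controls_per_test <= 4:
            raise ConfigurationError("controls_per_test must be in 1..4")
        for name, w, n in (
            ("age_band_weights", self.age_band_weights, len(AGE_BANDS)),
            ("diagnosis_weights", self.diagnosis_weights, len(DIAGNOSIS_GROUPS)),
        ):
            if len(w) != n:
                raise ConfigurationError(f"{name} must have {n} entries")
            if any(x < 0 or x > 1 for x in w):
                raise ConfigurationError(f"{name} entries must lie in [0, 1]")
            if not math.isclose(sum(w), 1.0, abs_tol=1e-9):
                raise ConfigurationError(f"{name} must sum to 1 within 1e-9")
            if max(w) == 0:
                raise ConfigurationError(f"{name} places zero weight everywhere")
        for name, p in (
            ("male_fraction", self.male_fraction),
            ("medical_fraction", self.medical_fraction),
            ("overnight_fraction", self.overnight_fraction),
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if len(self.asdr_per_band) != len(AGE_BANDS):
            raise ConfigurationError(f"asdr_per_band must have {len(AGE_BANDS)} entries")
        if any(p < 0 or p >= 1 for p in self.asdr_per_band):
            raise ConfigurationError("asdr_per_band entries must lie in [0, 1)")
        if self.seifa_levels < 1:
            raise ConfigurationError("seifa_levels must be >= 1")
        if self.days_before <= 0 or self.days_after <= 0:
            raise ConfigurationError("horizons must be positive")
        if self.baseline_sqrt_cost < 0:
            raise ConfigurationError("baseline_sqrt_cost must be >= 0")
        if self.cost_noise_sd < 0:
            raise ConfigurationError("cost_noise_sd must be >= 0")
        if self.claims_per_bin <= 0:
            raise ConfigurationError("claims_per_bin must be > 0")
        if self.admission_rate_per_100d < 0:
            raise ConfigurationError("admission_rate_per_100d must be >= 0")
        if self.admission_dispersion <= 0:
            raise ConfigurationError("admission_dispersion must be > 0")
        if self.los_mean_days < 1:
            raise ConfigurationError("los_mean_days must be >= 1")

    def replace(self, **kwargs) -> "CohortConfig":
        d = self.to_dict()
        d.update(kwargs)
        return CohortConfig.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown CohortConfig fields: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: arm, demographics, intervention anchor, death."""

    patient_id: str
    arm: str
    age_at_intervention: float
    gender: str
    diagnosis_group: str
    seifa: int
    intervention_date: int
    death_day: int | None = None
    matched_test_id: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if self.age_at_intervention < AGE_BANDS[0][0]:
            raise ValueError("age_at_intervention must be >= 50 (inclusion criterion)")
        if self.gender not in ("M", "F"):
            raise ValueError("gender must be 'M' or 'F'")


@dataclass(frozen=True)
class ClaimEvent:
    """One dated medical or pharmaceutical benefit claim."""

    patient_id: str
    day: int
    category: str
    cost: float

    def __post_init__(self) -> None:
        if self.category not in CLAIM_CATEGORIES:
            raise ValueError(f"category must be one of {CLAIM_CATEGORIES}")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")


@dataclass(frozen=True)
class AdmissionEvent:
    """One hospital admission; only overnight stays enter the analysis."""

    patient_id: str
    admit_day: int
    los: int
    overnight: bool

    def __post_init__(self) -> None:
        if self.overnight and self.los < 1:
            raise ValueError("overnight admissions must have los >= 1")


PATIENT_COLUMNS = [
    "patient_id", "arm", "age_at_intervention", "gender", "diagnosis_group",
    "seifa", "intervention_date", "death_day", "matched_test_id",
]
CLAIM_COLUMNS = ["patient_id", "day", "category", "cost"]
ADMISSION_COLUMNS = ["patient_id", "admit_day", "los", "overnight"]
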