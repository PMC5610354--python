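"""Case-matching of control candidates to test patients.

Matching is on gender and diagnosis group as hard constraints, with a
weighted distance over age and SEIFA level; up to four candidates per
test patient, without replacement. Multiple matched controls are later
collapsed into one averaged "effective control" per pair.

The assignment is greedy and deterministic: test patients are processed
in ascending age (ties by patient id), each taking its ``k_max``
closest unused candidates (ties again by patient id). Test patients
with no eligible candidate are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MatchingError

__all__ = ["MatchedPair", "MatchResult", "match_distance", "match_controls", "average_controls"]


@dataclass(frozen=True)
class MatchedPair:
    test_id: str
    control_ids: tuple[str, ...]
    match_distance: float

    def __post_init__(self) -> None:
        if not self.control_ids:
            raise ValueError("a matched pair needs at least one control")
        if self.match_distance < 0:
            raise ValueError("match_distance must be nonnegative")


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    unmatched: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_id": [p.test_id for p in self.pairs],
                "control_ids": [";".join(p.control_ids) for p in self.pairs],
                "match_distance": [p.match_distance for p in self.pairs],
            }
        )


def match_distance(
    test_row, control_row, age_weight: float = 1.0, seifa_weight: float = 1.0
) -> float:
    """Distance between one test patient and one candidate.

    Infinite when a hard constraint (gender, diagnosis group) fails;
    otherwise ``age_weight*|dAge|/10 + seifa_weight*|dSEIFA|``.
    """
    if test_row["gender"] != control_row["gender"]:
        return float("inf")
    if test_row["diagnosis_group"] != control_row["diagnosis_group"]:
        return float("inf")
    return age_weight * abs(
        test_row["age_at_intervention"] - control_row["age_at_intervention"]
    ) / 10.0 + seifa_weight * abs(test_row["seifa"] - control_row["seifa"])


def match_controls(
    tests: pd.DataFrame,
    pool: pd.DataFrame,
    k_max: int = 2,
    age_weight: float = 1.0,
    seifa_weight: float = 1.0,
) -> MatchResult:
    """Greedy sequential matching of up to ``k_max`` controls per test.

    Controls are never reused across pairs. Raises
    :class:`MatchingError` when the pool is empty; a test patient whose
    eligible candidates were all used (or never existed) appears in
    ``unmatched``.
    """
    if not 1 <= k_max <= 4:
        raise ValueError("k_max must be in 1..4")
    if pool.empty:
        raise MatchingError(
            "empty control pool; unmatched test patients: "
            + ", ".join(sorted(tests["patient_id"]))
        )
    overlap = set(tests["patient_id"]) & set(pool["patient_id"])
    if overlap:
        raise MatchingError(f"pool overlaps tests: {sorted(overlap)[:5]}")

    pool = pool.set_index("patient_id", drop=False)
    used: set[str] = set()
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []

    order = tests.sort_values(
        ["age_at_intervention", "patient_id"], kind="mergesort"
    )
    for _, trow in order.iterrows():
        cands = []
        for cid, crow in pool.iterrows():
            if cid in used:
                continue
            d = match_distance(trow, crow, age_weight, seifa_weight)
            if np.isfinite(d):
                cands.append((d, cid))
        if not cands:
            unmatched.append(trow["patient_id"])
            continue
        cands.sort(key=lambda dc: (dc[0], dc[1]))
        chosen = cands[:k_max]
        used.update(cid for _, cid in chosen)
        pairs.append(
            MatchedPair(
                test_id=trow["patient_id"],
                control_ids=tuple(cid for _, cid in chosen),
                match_distance=float(np.mean([d for d, _ in chosen])),
            )
        )
    pairs.sort(key=lambda p: p.test_id)
    return MatchResult(pairs=pairs, unmatched=sorted(unmatched))


def average_controls(series_list: list[pd.Series]) -> pd.Series:
    """Per-bin mean of several controls' binned totals.

    Bins where some control is unobserved (NaN, e.g. post-death) use
    the mean of the remaining controls; a bin unobserved for every
    control stays NaN. All series must share the bin index.
    """
    if not series_list:
        raise MatchingError("no control series to average")
    index = series_list[0].index
    for s in series_list[1:]:
        if not s.index.equals(index):
            raise MatchingError("control series have different bin structures")
    stacked = pd.concat(series_list, axis=1)
    if stacked.notna().sum().sum() == 0:
        raise MatchingError("no overlapping observed bins among controls")
    return stacked.mean(axis=1, skipna=True)
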