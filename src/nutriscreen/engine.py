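"""Screening rule engine for an EMR-embedded daily pediatric nutrition screen.

The screen combines an admission-time nurse-administered instrument (the
PNST, consumed here as an opaque boolean) with seven elements the EMR
derives automatically each day at 06:00, plus three longitudinal
"status-change" elements assessed on hospital day 4 and every Monday,
Wednesday and Friday thereafter.  A patient screens positive when *any*
element in the active subset is positive (OR aggregation).

Element vocabulary
------------------
Daily elements (``DAILY_ELEMENTS``):

- ``enteral_nutrition``     — active tube-feeding order
- ``parenteral_nutrition``  — active intravenous-nutrition order
- ``intubation``            — patient currently intubated
- ``food_allergies_2plus``  — two or more documented food allergies
- ``anthropometric_flag``   — merged anthropometric element: BMI-for-age
  z < −1 for corrected age ≥ 2 y, weight-for-length z < −1 below 2 y.
  The two z-scores are mutually exclusive by age, so they form a single
  analysis variable.
- ``rd_identified_risk``    — subjective dietitian judgment flag (input only)
- ``pnst_positive``         — PNST result carried forward from admission

Status-change elements (``STATUS_CHANGE_ELEMENTS``): intake below 50% of
needs, NPO (nothing by mouth), and unintentional weight loss of at least
5%, each sustained for three or more consecutive days.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

DAILY_ELEMENTS: tuple[str, ...] = (
    "enteral_nutrition",
    "parenteral_nutrition",
    "intubation",
    "food_allergies_2plus",
    "anthropometric_flag",
    "rd_identified_risk",
    "pnst_positive",
)

STATUS_CHANGE_ELEMENTS: tuple[str, ...] = (
    "intake_lt50_3d",
    "npo_gt3d",
    "weight_loss_ge5pct",
)

ALL_ELEMENTS: tuple[str, ...] = DAILY_ELEMENTS + STATUS_CHANGE_ELEMENTS

#: Human-readable labels used in report tables.
ELEMENT_LABELS: Mapping[str, str] = {
    "enteral_nutrition": "Enteral nutrition",
    "parenteral_nutrition": "Parenteral nutrition",
    "intubation": "Intubation",
    "food_allergies_2plus": "2+ food allergies",
    "anthropometric_flag": "BMI-for-age or weight-for-length z-score",
    "rd_identified_risk": "RD-identified risk",
    "pnst_positive": "Positive PNST",
    "intake_lt50_3d": "Intake < 50% for 3 days",
    "npo_gt3d": "NPO >= 3 days",
    "weight_loss_ge5pct": "Weight loss >= 5%",
}

#: z-score threshold for the merged anthropometric element (strict).
ANTHROPOMETRIC_Z_THRESHOLD = -1.0
#: Corrected age (years) at which the dispatch switches from WFL to BMI.
ANTHROPOMETRIC_AGE_SPLIT = 2.0
#: Minimum consecutive days for any status-change element.
STATUS_STREAK_DAYS = 3
#: Fractional weight loss that triggers the weight-loss element.
WEIGHT_LOSS_FRACTION = 0.05


class ScheduleError(ValueError):
    """Status-change evaluation requested on a non-scheduled day."""


@dataclass
class ScreenElementVector:
    """Binary state of every screen element for one patient(-day)."""

    enteral_nutrition: bool = False
    parenteral_nutrition: bool = False
    intubation: bool = False
    food_allergies_2plus: bool = False
    anthropometric_flag: bool = False
    rd_identified_risk: bool = False
    pnst_positive: bool = False
    intake_lt50_3d: bool = False
    npo_gt3d: bool = False
    weight_loss_ge5pct: bool = False

    def __getitem__(self, name: str) -> bool:
        if name not in ALL_ELEMENTS:
            raise KeyError(f"unknown screen element: {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "ScreenElementVector":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown screen elements: {sorted(unknown)}")
        return cls(**{k: bool(v) for k, v in d.items()})


@dataclass(frozen=True)
class LMSReferenceRow:
    """One growth-reference row: Box-Cox power L, median M, CV S."""

    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.S > 0):
            raise ValueError("LMS reference requires M > 0 and S > 0")


@dataclass(frozen=True)
class AnthropometricInput:
    """A precomputed (or LMS-derived) z-score with the age that selected it.

    ``z_score`` is BMI-for-age when ``corrected_age_years`` >= 2 and
    weight-for-length below 2; the dispatch is the caller's duty, recorded
    here so downstream code can audit which branch applied.
    """

    corrected_age_years: float
    z_score: float
    source: str = "precomputed"  # or "lms"

    def __post_init__(self) -> None:
        if self.corrected_age_years < 0:
            raise ValueError("corrected age must be nonnegative")
        if not math.isfinite(self.z_score):
            raise ValueError("z-score must be finite")


def lms_z(value: float, ref: LMSReferenceRow) -> float:
    """Convert a measurement to a z-score under the LMS (Box-Cox) model.

    z = ((value/M)**L - 1) / (L*S) for L != 0, with the log-limit
    ln(value/M)/S at L = 0 (applied for |L| <= 1e-12, where the two
    branches agree to well below any reporting precision).
    """
    if value <= 0:
        raise ValueError("measurement must be positive")
    ratio = value / ref.M
    if abs(ref.L) > 1e-12:
        return (ratio ** ref.L - 1.0) / (ref.L * ref.S)
    return math.log(ratio) / ref.S


def uses_bmi_branch(corrected_age_years: float) -> bool:
    """True when BMI-for-age applies (corrected age two years or more)."""
    return corrected_age_years >= ANTHROPOMETRIC_AGE_SPLIT


def anthropometric_element(inp: AnthropometricInput) -> bool:
    """Merged BMIZ/WFLZ element: z strictly below −1, either age branch."""
    return inp.z_score < ANTHROPOMETRIC_Z_THRESHOLD


@dataclass(frozen=True)
class DailyInputs:
    """Raw per-day inputs from which the seven daily elements derive."""

    en_active: bool = False
    pn_active: bool = False
    intubated: bool = False
    allergy_count: int = 0
    anthropometry: AnthropometricInput | None = None
    rd_identified_risk: bool = False
    pnst_positive: bool = False
    patient_id: str | None = None


def evaluate_daily(inputs: DailyInputs) -> ScreenElementVector:
    """Derive the seven daily elements from raw inputs.

    Missing anthropometry yields a false flag with a logged warning: a
    fully automated daily screen cannot halt on a missing measurement.
    Status-change elements are left false; see
    :func:`evaluate_status_change`.
    """
    if inputs.anthropometry is None:
        log.warning(
            "missing anthropometry for patient %s: anthropometric element "
            "set to negative", inputs.patient_id or "<unknown>",
        )
        anthro = False
    else:
        anthro = anthropometric_element(inputs.anthropometry)
    return ScreenElementVector(
        enteral_nutrition=inputs.en_active,
        parenteral_nutrition=inputs.pn_active,
        intubation=inputs.intubated,
        food_allergies_2plus=inputs.allergy_count >= 2,
        anthropometric_flag=anthro,
        rd_identified_risk=inputs.rd_identified_risk,
        pnst_positive=inputs.pnst_positive,
    )


@dataclass(frozen=True)
class StayHistory:
    """Per-hospital-day observations over a stay, index 0 = hospital day 1.

    ``intake_fraction``: fraction of estimated needs consumed each day.
    ``npo``: nothing-by-mouth status each day.
    ``weight_kg``: daily weight; the weight-loss baseline is the highest
    weight recorded so far in the admission, recomputed daily.
    """

    intake_fraction: Sequence[float] = field(default_factory=tuple)
    npo: Sequence[bool] = field(default_factory=tuple)
    weight_kg: Sequence[float] = field(default_factory=tuple)


def _trailing_streak(flags: Sequence[bool]) -> int:
    n = 0
    for f in reversed(flags):
        if not f:
            break
        n += 1
    return n


def evaluate_status_change(
    history: StayHistory,
    day: int,
    schedule_days: Iterable[int] | None = None,
    permissive: bool = False,
) -> tuple[bool, bool, bool]:
    """Evaluate the three status-change elements on hospital day ``day``.

    Each element is positive when its condition has held on at least
    three consecutive most-recent recorded days (days before ``day``).
    The weight-loss condition on a given day is a drop of 5% or more
    from the admission-maximum weight up to that day.

    When ``schedule_days`` is given, ``day`` must belong to it; in
    permissive mode an off-schedule evaluation proceeds with a warning
    instead of raising :class:`ScheduleError`.
    """
    if schedule_days is not None and day not in set(schedule_days):
        if not permissive:
            raise ScheduleError(f"day {day} is not a scheduled status-change day")
        log.warning("status-change evaluation on off-schedule day %d", day)

    upto = day - 1  # evaluation at 06:00 sees completed days only
    intake = list(history.intake_fraction[:upto])
    npo = list(history.npo[:upto])
    weights = list(history.weight_kg[:upto])

    intake_flag = _trailing_streak([f < 0.5 for f in intake]) >= STATUS_STREAK_DAYS
    npo_flag = _trailing_streak(list(npo)) >= STATUS_STREAK_DAYS

    loss_daily: list[bool] = []
    peak = -math.inf
    for w in weights:
        peak = max(peak, w)
        loss_daily.append((w - peak) / peak <= -WEIGHT_LOSS_FRACTION)
    loss_flag = _trailing_streak(loss_daily) >= STATUS_STREAK_DAYS

    return intake_flag, npo_flag, loss_flag


def aggregate(vector: ScreenElementVector, subset: Iterable[str]) -> bool:
    """OR rule: positive screen iff any element in ``subset`` is positive."""
    names = list(subset)
    if not names:
        raise ValueError("element subset must be nonempty")
    for name in names:
        if name not in ALL_ELEMENTS:
            raise KeyError(f"unknown screen element: {name!r}")
    return any(vector[name] for name in names)


# Monday/Wednesday/Friday as date.weekday() values.
_MWF = {0, 2, 4}


def status_change_days(admission_date: date, horizon: int) -> list[int]:
    """Hospital days on which status-change elements are assessed.

    Day 4 of hospitalization (admission date = day 1), then every Monday,
    Wednesday and Friday thereafter, ascending and deduplicated, limited
    to ``horizon`` hospital days.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1 day")
    days: list[int] = []
    if horizon >= 4:
        days.append(4)
    for d in range(5, horizon + 1):
        if (admission_date + timedelta(days=d - 1)).weekday() in _MWF:
            days.append(d)
    return days


@dataclass(frozen=True)
class ScreeningSchedule:
    """Daily 06:00 screen plus the day-4 / Mon-Wed-Fri status-change cadence."""

    admission_date: date
    horizon_days: int = 30

    def status_change_days(self) -> list[int]:
        return status_change_days(self.admission_date, self.horizon_days)
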