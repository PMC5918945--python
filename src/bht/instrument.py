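"""Deterministic scoring rules of the Brain Health Test (BHT).

The instrument has two parts:

* a **risk score** (RS, 1-18 points) summing age-bin, sex and comorbidity
  weights, together with a **high-risk triage rule** that decides whether a
  subject proceeds to cognitive testing;
* a 16-point short cognitive battery (**BHT-cog**: orientation to time,
  immediate recall of five items, binned categorical verbal fluency, delayed
  recall of five items) with a screen-positive cutoff (default 10, score
  below the cutoff is positive).

All functions here are pure: identical inputs give identical outputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Sex",
    "Decision",
    "RiskProfile",
    "CognitiveRaw",
    "ScreeningResult",
    "RISK_FACTOR_WEIGHTS",
    "MAX_RISK_SCORE",
    "MAX_COG_SCORE",
    "DEFAULT_COG_CUTOFF",
    "DEFAULT_RS_THRESHOLD",
    "age_risk_points",
    "bmi_flag",
    "risk_score",
    "is_high_risk",
    "fluency_points",
    "bht_cog_score",
    "classify_cog",
    "two_stage_classify",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Decision(str, enum.Enum):
    """Final two-stage screen outcome for one subject."""

    LOW_RISK_NEGATIVE = "low_risk_negative"  # triage-negative, cognitive test skipped
    COG_NEGATIVE = "cog_negative"            # high risk, cognitive score at/above cutoff
    COG_POSITIVE = "cog_positive"            # high risk, cognitive score below cutoff


#: Weight of each binary risk factor in the risk score.  Comorbidities carry
#: one point; head trauma with consciousness change and depression carry three.
RISK_FACTOR_WEIGHTS: dict[str, int] = {
    "bmi_lt18": 1,
    "education_lt6": 1,
    "stroke": 1,
    "diabetes": 1,
    "hypertension": 1,
    "hyperlipidemia": 1,
    "head_trauma_loc": 3,
    "depression": 3,
}

MAX_RISK_SCORE = 18
MAX_COG_SCORE = 16
DEFAULT_COG_CUTOFF = 10
DEFAULT_RS_THRESHOLD = 8

_SEX_POINTS = {Sex.MALE: 1, Sex.FEMALE: 2}


def _require_bool(name: str, value: object) -> bool:
    if not isinstance(value, bool):
        raise TypeError(f"{name} must be a bool, got {value!r}")
    return value


@dataclass(frozen=True)
class RiskProfile:
    """One subject's answers to the risk-evaluation part of the instrument.

    ``memory_impairment_doctor`` is recorded for completeness but does not
    enter the triage rule, which names only subject/informant memory-decline
    reports and the assistance-need question.
    """

    age: int
    sex: Sex
    education_lt6: bool = False
    bmi_lt18: bool = False
    stroke: bool = False
    diabetes: bool = False
    hypertension: bool = False
    hyperlipidemia: bool = False
    head_trauma_loc: bool = False
    depression: bool = False
    memory_decline_subject: bool = False
    memory_decline_informant: bool = False
    memory_impairment_doctor: bool = False
    needs_assistance_money_meds: bool = False

    def __post_init__(self) -> None:
        age = self.age
        if isinstance(age, bool) or not isinstance(age, (int, float)):
            raise TypeError(f"age must be numeric, got {age!r}")
        if isinstance(age, float):
            # whole-year ages are recorded; floor fractional input
            object.__setattr__(self, "age", math.floor(age))
        if self.age < 50:
            raise ValueError(
                f"age {self.age} below study inclusion criterion (>= 50 years)"
            )
        object.__setattr__(self, "sex", Sex(self.sex))
        for field in (
            "education_lt6",
            "bmi_lt18",
            "stroke",
            "diabetes",
            "hypertension",
            "hyperlipidemia",
            "head_trauma_loc",
            "depression",
            "memory_decline_subject",
            "memory_decline_informant",
            "memory_impairment_doctor",
            "needs_assistance_money_meds",
        ):
            _require_bool(field, getattr(self, field))


@dataclass(frozen=True)
class CognitiveRaw:
    """Raw item responses of the short cognitive battery.

    ``fluency_count`` is the number of four-legged animals named in one
    minute (unbounded above); the other items are already on their scored
    ranges.
    """

    orientation_time: int
    immediate_recall: int
    fluency_count: int
    delayed_recall: int

    def __post_init__(self) -> None:
        ranges = {
            "orientation_time": (0, 4),
            "immediate_recall": (0, 5),
            "fluency_count": (0, None),
            "delayed_recall": (0, 5),
        }
        for field, (lo, hi) in ranges.items():
            value = getattr(self, field)
            if isinstance(value, bool) or not isinstance(value, int):
                raise TypeError(f"{field} must be an integer, got {value!r}")
            if value < lo or (hi is not None and value > hi):
                bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                raise ValueError(f"{field}={value} outside allowed range {bound}")


@dataclass(frozen=True)
class ScreeningResult:
    """Per-subject outcome of the two-stage screen.

    ``cog_score`` is ``None`` for triage-negative subjects, whose cognitive
    test is skipped.
    """

    risk_score: int
    high_risk: bool
    cog_score: Optional[int]
    decision: Decision

    def __post_init__(self) -> None:
        if not self.high_risk and self.decision is not Decision.LOW_RISK_NEGATIVE:
            raise ValueError("low-risk subjects must be low_risk_negative")
        if self.high_risk and self.decision is Decision.LOW_RISK_NEGATIVE:
            raise ValueError("high-risk subjects cannot be low_risk_negative")

    @property
    def screen_positive(self) -> bool:
        return self.decision is Decision.COG_POSITIVE


def age_risk_points(age: int) -> int:
    """Risk-score points for an age in whole years.

    Decade bins with inclusive edges: [50, 59] -> 0, [60, 69] -> 1,
    [70, 79] -> 2, [80, 89] -> 3, >= 90 -> 4.

    Raises ``ValueError`` for ages below 50 (out of the screened population).
    """
    age = math.floor(age)
    if age < 50:
        raise ValueError(f"age {age} below inclusion criterion (>= 50 years)")
    return min((age - 50) // 10, 4)


def bmi_flag(bmi: float) -> bool:
    """Convenience converter from numeric BMI to the underweight flag (strict < 18)."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    return bmi < 18


def risk_score(profile: RiskProfile) -> int:
    """Total risk score (1-18): age points + sex points + weighted factors."""
    total = age_risk_points(profile.age) + _SEX_POINTS[profile.sex]
    for factor, weight in RISK_FACTOR_WEIGHTS.items():
        if getattr(profile, factor):
            total += weight
    return total


def is_high_risk(
    profile: RiskProfile,
    rs: Optional[int] = None,
    rs_threshold: int = DEFAULT_RS_THRESHOLD,
) -> bool:
    """Triage rule selecting subjects for cognitive testing.

    True iff any of: memory decline reported by the subject or an informant,
    needing assistance to manage money or medications, or total risk score at
    or above ``rs_threshold``.  Doctor-observed memory impairment does not
    trigger triage.
    """
    if rs is None:
        rs = risk_score(profile)
    return (
        profile.memory_decline_subject
        or profile.memory_decline_informant
        or profile.needs_assistance_money_meds
        or rs >= rs_threshold
    )


def fluency_points(fluency_count: int) -> int:
    """Bin a verbal-fluency count to 0-2 points: <5 -> 0, 5-8 -> 1, >=9 -> 2."""
    if fluency_count < 0:
        raise ValueError(f"fluency count must be >= 0, got {fluency_count}")
    if fluency_count < 5:
        return 0
    if fluency_count <= 8:
        return 1
    return 2


def bht_cog_score(raw: CognitiveRaw) -> int:
    """Total cognitive score (0-16): orientation + recalls + binned fluency."""
    return (
        raw.orientation_time
        + raw.immediate_recall
        + fluency_points(raw.fluency_count)
        + raw.delayed_recall
    )


def classify_cog(score: int, cutoff: int = DEFAULT_COG_CUTOFF) -> bool:
    """Screen-positive flag for a cognitive score: positive iff ``score < cutoff``.

    A score at or above the cutoff is negative.
    """
    if not 0 <= score <= MAX_COG_SCORE:
        raise ValueError(f"score {score} outside [0, {MAX_COG_SCORE}]")
    if not 1 <= cutoff <= MAX_COG_SCORE:
        raise ValueError(f"cutoff {cutoff} outside [1, {MAX_COG_SCORE}]")
    return score < cutoff


def two_stage_classify(
    profile: RiskProfile,
    raw: Optional[CognitiveRaw],
    cutoff: int = DEFAULT_COG_CUTOFF,
    rs_threshold: int = DEFAULT_RS_THRESHOLD,
) -> ScreeningResult:
    """Full two-stage screen: triage gate, then cognitive test.

    Low-risk subjects exit immediately as negatives with no cognitive score.
    High-risk subjects are positive iff their cognitive score falls below the
    cutoff; the positive set is therefore the conjunction
    ``high_risk and (cog_score < cutoff)``.

    ``raw`` may be ``None`` only for subjects that turn out low-risk.
    """
    rs = risk_score(profile)
    if not is_high_risk(profile, rs, rs_threshold=rs_threshold):
        return ScreeningResult(
            risk_score=rs,
            high_risk=False,
            cog_score=None,
            decision=Decision.LOW_RISK_NEGATIVE,
        )
    if raw is None:
        raise ValueError("cognitive responses required for a high-risk subject")
    cog = bht_cog_score(raw)
    decision = Decision.COG_POSITIVE if classify_cog(cog, cutoff) else Decision.COG_NEGATIVE
    return ScreeningResult(risk_score=rs, high_risk=True, cog_score=cog, decision=decision)
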