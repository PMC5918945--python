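"""Shared fixtures and strategy helpers for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

from bht.cohort import FACTOR_COLUMNS, CohortRecord
from bht.instrument import CognitiveRaw, RiskProfile, Sex


def make_profile(age: int = 70, sex: str = "male", **flags) -> RiskProfile:
    return RiskProfile(age=age, sex=Sex(sex), **flags)


def make_cognitive(
    orientation: int = 4, immediate: int = 5, fluency: int = 12, delayed: int = 5
) -> CognitiveRaw:
    return CognitiveRaw(
        orientation_time=orientation,
        immediate_recall=immediate,
        fluency_count=fluency,
        delayed_recall=delayed,
    )


def make_record(
    subject_id: str,
    group: str = "healthy",
    profile: RiskProfile | None = None,
    cognitive: CognitiveRaw | None = None,
    **kwargs,
) -> CohortRecord:
    return CohortRecord(
        subject_id=subject_id,
        group=group,
        profile=profile or make_profile(),
        cognitive=cognitive or make_cognitive(),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Hypothesis strategies
# ---------------------------------------------------------------------------

flag_fields = st.fixed_dictionaries({f: st.booleans() for f in FACTOR_COLUMNS})

profiles = st.builds(
    lambda age, sex, flags: RiskProfile(age=age, sex=sex, **flags),
    age=st.integers(min_value=50, max_value=110),
    sex=st.sampled_from([Sex.MALE, Sex.FEMALE]),
    flags=flag_fields,
)

cognitive_raws = st.builds(
    CognitiveRaw,
    orientation_time=st.integers(0, 4),
    immediate_recall=st.integers(0, 5),
    fluency_count=st.integers(0, 40),
    delayed_recall=st.integers(0, 5),
)


@pytest.fixture
def toy_cohort() -> list[CohortRecord]:
    """Six subjects, two per group, with clearly separated cognitive scores."""
    rows = [
        ("H1", "healthy", 16, False),
        ("H2", "healthy", 14, False),
        ("M1", "mci", 11, True),
        ("M2", "mci", 10, True),
        ("D1", "dementia", 4, True),
        ("D2", "dementia", 2, True),
    ]
    records = []
    for sid, group, cog, complain in rows:
        fluency = 12 if cog >= 10 else 4
        rest = cog - (2 if fluency >= 9 else 0)
        orientation = min(rest, 4)
        rest -= orientation
        immediate = min(rest, 5)
        delayed = rest - immediate
        records.append(
            make_record(
                sid,
                group,
                profile=make_profile(age=75, sex="female", memory_decline_subject=complain),
                cognitive=make_cognitive(orientation, immediate, fluency, delayed),
            )
        )
    return records
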