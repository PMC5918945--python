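"""Cohort CSV input/output, record validation, and packaged reference summaries.

CSV dialect: UTF-8, comma-separated, mandatory header, booleans encoded as
0/1, missing optional values as empty strings, group labels lower-case.
Lines starting with ``#`` (e.g. a seed echo written by the simulator) are
skipped.  Column order is fixed by :data:`COHORT_COLUMNS`.
"""

from __future__ import annotations

import csv
import json
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .instrument import CognitiveRaw, RiskProfile, Sex, bht_cog_score, is_high_risk

__all__ = [
    "GROUPS",
    "COHORT_COLUMNS",
    "FACTOR_COLUMNS",
    "ITEM_COLUMNS",
    "CohortRecord",
    "ExclusionReport",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "reference_summary",
    "reference_triage_counts",
    "reference_dementia_subtypes",
]

GROUPS = ("healthy", "mci", "dementia", "unknown")

#: Binary risk-factor columns, in schema order.
FACTOR_COLUMNS = (
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
)

#: Raw cognitive item columns.
ITEM_COLUMNS = (
    "orientation_time",
    "immediate_recall",
    "fluency_count",
    "delayed_recall",
)

COHORT_COLUMNS = (
    ("subject_id", "group", "age", "sex")
    + FACTOR_COLUMNS
    + ITEM_COLUMNS
    + ("mmse", "cdr")
)

_CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class CohortRecord:
    """One validated subject row: identity, diagnostic group, risk profile,
    cognitive responses, optional MMSE/CDR metadata."""

    subject_id: str
    group: str
    profile: RiskProfile
    cognitive: CognitiveRaw
    mmse: Optional[int] = None
    cdr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group {self.group!r} not in {GROUPS}")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse {self.mmse} outside [0, 30]")
        if self.cdr is not None and self.cdr not in _CDR_LEVELS:
            raise ValueError(f"cdr {self.cdr} not in {_CDR_LEVELS}")


@dataclass
class ExclusionReport:
    """Bookkeeping for rows dropped during lenient cohort reading."""

    n_input: int = 0
    exclusions: list[tuple[int, str]] = field(default_factory=list)  # (line no, reason)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded


def _parse_bool(value: str, column: str) -> bool:
    if value == "0":
        return False
    if value == "1":
        return True
    raise ValueError(f"column {column!r}: expected 0/1, got {value!r}")


def _record_from_row(row: dict[str, str]) -> CohortRecord:
    missing = [c for c in COHORT_COLUMNS[:-2] if not (row.get(c) or "").strip()]
    if missing:
        raise ValueError(f"missing required field(s): {', '.join(missing)}")
    profile = RiskProfile(
        age=int(row["age"]),
        sex=Sex(row["sex"]),
        **{f: _parse_bool(row[f], f) for f in FACTOR_COLUMNS},
    )
    cognitive = CognitiveRaw(**{c: int(row[c]) for c in ITEM_COLUMNS})
    mmse = row.get("mmse", "").strip()
    cdr = row.get("cdr", "").strip()
    return CohortRecord(
        subject_id=row["subject_id"],
        group=row["group"].strip().lower(),
        profile=profile,
        cognitive=cognitive,
        mmse=int(mmse) if mmse else None,
        cdr=float(cdr) if cdr else None,
    )


def read_cohort(
    path: Union[str, Path], strict: bool = False
) -> tuple[list[CohortRecord], ExclusionReport]:
    """Read a cohort CSV, validating every row.

    In strict mode the first malformed row raises ``ValueError`` with its
    line number; otherwise invalid rows are dropped and listed in the
    returned :class:`ExclusionReport`.  Duplicate subject ids are invalid.
    """
    path = Path(path)
    report = ExclusionReport()
    records: list[CohortRecord] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        filtered = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(filtered)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        missing_cols = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing_cols:
            raise ValueError(f"{path}: header missing column(s) {sorted(missing_cols)}")
        for row in reader:
            report.n_input += 1
            line_no = reader.line_num
            try:
                record = _record_from_row(row)
                if record.subject_id in seen_ids:
                    raise ValueError(f"duplicate subject_id {record.subject_id!r}")
            except (ValueError, TypeError) as exc:
                if strict:
                    raise ValueError(f"{path}:{line_no}: {exc}") from exc
                report.exclusions.append((line_no, str(exc)))
                continue
            seen_ids.add(record.subject_id)
            records.append(record)
    return records, report


def _record_to_row(record: CohortRecord) -> dict[str, str]:
    row = {
        "subject_id": record.subject_id,
        "group": record.group,
        "age": str(record.profile.age),
        "sex": record.profile.sex.value,
        "mmse": "" if record.mmse is None else str(record.mmse),
        "cdr": "" if record.cdr is None else format(record.cdr, "g"),
    }
    for f in FACTOR_COLUMNS:
        row[f] = "1" if getattr(record.profile, f) else "0"
    for c in ITEM_COLUMNS:
        row[c] = str(getattr(record.cognitive, c))
    return row


def write_cohort(
    path: Union[str, Path],
    records: Iterable[CohortRecord],
    header_comment: Optional[str] = None,
) -> None:
    """Write records as cohort CSV; ``header_comment`` becomes a leading
    ``#`` line (used to echo the simulation seed)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.DictWriter(fh, fieldnames=COHORT_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for record in records:
            writer.writerow(_record_to_row(record))


@dataclass
class CohortSummary:
    """Per-group sizes, factor counts, and cognitive-item mean/SD.

    ``factor_counts`` includes the derived ``memory_decline_either`` factor
    (subject or informant report).  ``high_risk_counts`` and
    ``dementia_subtypes`` are optional extras carried by the packaged
    reference summary and by :func:`summarize_cohort`.
    """

    group_sizes: dict[str, int]
    factor_counts: dict[str, dict[str, int]]
    item_stats: dict[str, dict[str, tuple[float, float]]]
    high_risk_counts: Optional[dict[str, int]] = None
    dementia_subtypes: Optional[dict[str, int]] = None

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def factor_fraction(self, group: str, factor: str) -> float:
        return self.factor_counts[group][factor] / self.group_sizes[group]

    def to_dict(self) -> dict:
        out = {
            "group_sizes": dict(self.group_sizes),
            "factor_counts": {g: dict(c) for g, c in self.factor_counts.items()},
            "item_stats": {
                g: {k: [mean, sd] for k, (mean, sd) in items.items()}
                for g, items in self.item_stats.items()
            },
        }
        if self.high_risk_counts is not None:
            out["high_risk_counts"] = dict(self.high_risk_counts)
        if self.dementia_subtypes is not None:
            out["dementia_subtypes"] = dict(self.dementia_subtypes)
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def summarize_cohort(cohort: Sequence[CohortRecord]) -> CohortSummary:
    """Per-group factor counts and item statistics for a record-level cohort.

    Item SDs use the n-1 (sample) convention; single-subject groups report
    ``nan`` SDs.  Empty groups are simply absent from the output.
    """
    if not cohort:
        raise ValueError("empty cohort")
    by_group: dict[str, list[CohortRecord]] = {}
    for record in cohort:
        by_group.setdefault(record.group, []).append(record)

    group_sizes: dict[str, int] = {}
    factor_counts: dict[str, dict[str, int]] = {}
    item_stats: dict[str, dict[str, tuple[float, float]]] = {}
    high_risk_counts: dict[str, int] = {}
    for group in [g for g in GROUPS if g in by_group]:
        records = by_group[group]
        group_sizes[group] = len(records)
        counts = {"female": sum(r.profile.sex is Sex.FEMALE for r in records)}
        for f in FACTOR_COLUMNS:
            counts[f] = sum(getattr(r.profile, f) for r in records)
        counts["memory_decline_either"] = sum(
            r.profile.memory_decline_subject or r.profile.memory_decline_informant
            for r in records
        )
        factor_counts[group] = counts
        stats_: dict[str, tuple[float, float]] = {}
        ages = [float(r.profile.age) for r in records]
        stats_["age"] = _mean_sd(ages)
        for item in ITEM_COLUMNS:
            stats_[item] = _mean_sd([float(getattr(r.cognitive, item)) for r in records])
        stats_["bht_cog"] = _mean_sd(
            [float(bht_cog_score(r.cognitive)) for r in records]
        )
        mmses = [float(r.mmse) for r in records if r.mmse is not None]
        if mmses:
            stats_["mmse"] = _mean_sd(mmses)
        item_stats[group] = stats_
        high_risk_counts[group] = sum(is_high_risk(r.profile) for r in records)

    return CohortSummary(
        group_sizes=group_sizes,
        factor_counts=factor_counts,
        item_stats=item_stats,
        high_risk_counts=high_risk_counts,
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else math.nan
    return (mean, sd)


# --------------------------------------------------------------------------
# Packaged reference summary (the published validation cohort, n = 813)
# --------------------------------------------------------------------------

_REFERENCE_GROUP_SIZES = {"healthy": 166, "mci": 225, "dementia": 422}

# The published healthy-group hypertension count is misprinted as 930; the
# printed percentage (56%) identifies the intended count as 93 (93/166 = 56%).
_REFERENCE_FACTOR_COUNTS = {
    "healthy": {
        "female": 87,
        "education_lt6": 20,
        "memory_decline_subject": 62,
        "memory_decline_informant": 39,
        "memory_decline_either": 72,
        "memory_impairment_doctor": 16,
        "bmi_lt18": 7,
        "stroke": 22,
        "diabetes": 41,
        "hypertension": 93,
        "hyperlipidemia": 44,
        "head_trauma_loc": 6,
        "needs_assistance_money_meds": 9,
        "depression": 14,
    },
    "mci": {
        "female": 119,
        "education_lt6": 36,
        "memory_decline_subject": 163,
        "memory_decline_informant": 141,
        "memory_decline_either": 209,
        "memory_impairment_doctor": 24,
        "bmi_lt18": 10,
        "stroke": 37,
        "diabetes": 64,
        "hypertension": 121,
        "hyperlipidemia": 61,
        "head_trauma_loc": 13,
        "needs_assistance_money_meds": 47,
        "depression": 33,
    },
    "dementia": {
        "female": 239,
        "education_lt6": 117,
        "memory_decline_subject": 286,
        "memory_decline_informant": 362,
        "memory_decline_either": 405,
        "memory_impairment_doctor": 76,
        "bmi_lt18": 18,
        "stroke": 72,
        "diabetes": 124,
        "hypertension": 238,
        "hyperlipidemia": 108,
        "head_trauma_loc": 44,
        "needs_assistance_money_meds": 262,
        "depression": 120,
    },
}

# Age/MMSE plus the original cognitive-battery item scores (mean, SD).
_REFERENCE_ITEM_STATS = {
    "healthy": {
        "age": (72.3, 8.4),
        "mmse": (27.9, 2.1),
        "orientation_time": (3.7, 0.7),
        "immediate_recall": (3.6, 1.2),
        "fluency_count": (9.5, 3.3),
        "delayed_recall": (3.6, 1.4),
        "bht_cog": (12.5, 2.6),
    },
    "mci": {
        "age": (73.3, 8.7),
        "mmse": (24.6, 3.8),
        "orientation_time": (3.2, 1.1),
        "immediate_recall": (3.2, 1.2),
        "fluency_count": (8.2, 3.2),
        "delayed_recall": (2.6, 1.6),
        "bht_cog": (10.3, 2.9),
    },
    "dementia": {
        "age": (79.0, 8.4),
        "mmse": (16.8, 6.3),
        "orientation_time": (1.2, 1.3),
        "immediate_recall": (1.9, 1.4),
        "fluency_count": (4.7, 3.2),
        "delayed_recall": (1.0, 1.4),
        "bht_cog": (4.7, 3.3),
    },
}

# High-risk head counts under the published triage rule: 89 of 166 healthy
# subjects were high-risk; 8 MCI and 4 dementia subjects were low-risk.
_REFERENCE_HIGH_RISK = {"healthy": 89, "mci": 225 - 8, "dementia": 422 - 4}

_REFERENCE_DEMENTIA_SUBTYPES = {
    "alzheimer": 320,
    "vascular": 33,
    "lewy_body": 7,
    "parkinson": 9,
    "frontotemporal": 7,
    "mixed": 46,
}


def reference_summary() -> CohortSummary:
    """The packaged summary of the published three-group validation cohort
    (166 healthy / 225 MCI / 422 dementia)."""
    return CohortSummary(
        group_sizes=dict(_REFERENCE_GROUP_SIZES),
        factor_counts={g: dict(c) for g, c in _REFERENCE_FACTOR_COUNTS.items()},
        item_stats={g: dict(s) for g, s in _REFERENCE_ITEM_STATS.items()},
        high_risk_counts=dict(_REFERENCE_HIGH_RISK),
        dementia_subtypes=dict(_REFERENCE_DEMENTIA_SUBTYPES),
    )


def reference_triage_counts() -> dict[str, int]:
    """Published per-group high-risk counts under the triage rule."""
    return dict(_REFERENCE_HIGH_RISK)


def reference_dementia_subtypes() -> dict[str, int]:
    """Published dementia aetiology breakdown (n = 422)."""
    return dict(_REFERENCE_DEMENTIA_SUBTYPES)
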