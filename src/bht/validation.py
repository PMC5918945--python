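"""Diagnostic-evaluation statistics for screening-instrument validation.

Closed-form 2x2 metrics (sensitivity/specificity/PPV/NPV), odds ratios with
Woolf (logit) confidence intervals and the Haldane-Anscombe zero-cell
correction, ROC curves for integer scores with trapezoidal AUC and a
Hanley-McNeil interval, Youden-index cutoff selection, and Pearson
correlation.

Internal values are kept at full precision; presentation-layer rounding is
one decimal with round-half-up (see :func:`round_half_up` / :func:`percent`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "ConfusionMetrics",
    "OddsRatioResult",
    "RocCurve",
    "CutoffResult",
    "round_half_up",
    "percent",
    "confusion_metrics",
    "odds_ratio_woolf",
    "roc_curve",
    "optimal_cutoff",
    "pearson_r",
    "build_2x2",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (2.25 -> 2.3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(p: float, ndigits: int = 1) -> float:
    """Proportion -> percentage rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * p, ndigits)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-outcome counts: ``a`` exposed-impaired, ``b`` unexposed-impaired,
    ``c`` exposed-healthy, ``d`` unexposed-healthy."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
                raise TypeError(f"cell {name} must be an integer count, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name} must be >= 0, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 diagnostic accuracy summary.  Ratios with a zero denominator are
    ``None`` (explicitly undefined), never silently zero."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_percent(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        """The four metrics as rounded percentages (``None`` where undefined)."""
        return {
            name: None if v is None else percent(v, ndigits)
            for name, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV and NPV from classification counts."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with a Woolf (logit) confidence interval.

    ``corrected`` is set when the Haldane-Anscombe 0.5 continuity correction
    was applied because of a zero cell.
    """

    estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.estimate, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def odds_ratio_woolf(table: ContingencyTable2x2, alpha: float = 0.05) -> OddsRatioResult:
    """Cross-product odds ratio ``(a*d)/(b*c)`` with Woolf CI
    ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) and
    the result is flagged ``corrected``.  A zero row or column margin leaves
    the odds ratio undefined and raises ``ValueError``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("odds ratio undefined: a table margin is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(estimate)
    return OddsRatioResult(
        estimate=estimate,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        corrected=corrected,
    )


@dataclass(frozen=True)
class RocCurve:
    """ROC curve for an integer-valued score.

    ``points`` are (1 - specificity, sensitivity) pairs, one per threshold,
    running monotonically from (0, 0) to (1, 1).  With ``positive_low`` the
    classifier at threshold ``t`` calls a subject positive iff ``score < t``.
    """

    thresholds: tuple[int, ...]
    points: tuple[tuple[float, float], ...]
    auc: float
    auc_ci: tuple[float, float]
    positive_low: bool = True
    n_pos: int = 0
    n_neg: int = 0
    per_threshold: tuple["ConfusionMetrics", ...] = field(default=(), repr=False)


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, alpha: float) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return (max(auc - z * se, 0.0), min(auc + z * se, 1.0))


def roc_curve(
    scores: Sequence[int],
    labels: Sequence[bool],
    positive_low: bool = True,
    alpha: float = 0.05,
) -> RocCurve:
    """ROC sweep over every integer threshold covering the score range.

    The trapezoidal AUC of the returned curve equals the tie-corrected
    Mann-Whitney probability ``P(score_pos < score_neg) + 0.5 P(tie)`` when
    ``positive_low`` (low scores indicate disease).

    Requires at least one positive and one negative label.
    """
    scores_arr = np.asarray(scores)
    labels_arr = np.asarray(labels, dtype=bool)
    if scores_arr.shape != labels_arr.shape or scores_arr.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    if scores_arr.size == 0:
        raise ValueError("empty input")
    if not np.issubdtype(scores_arr.dtype, np.integer):
        raise TypeError("scores must be integers")
    n_pos = int(labels_arr.sum())
    n_neg = int((~labels_arr).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    lo = min(int(scores_arr.min()), 0)
    hi = int(scores_arr.max()) + 1
    thresholds = tuple(range(lo, hi + 1))

    pos_scores = scores_arr[labels_arr]
    neg_scores = scores_arr[~labels_arr]
    points: list[tuple[float, float]] = []
    cms: list[ConfusionMetrics] = []
    for t in thresholds:
        if positive_low:
            pred_pos = scores_arr < t
        else:
            pred_pos = scores_arr >= t
        tp = int((pred_pos & labels_arr).sum())
        fp = int((pred_pos & ~labels_arr).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        cm = confusion_metrics(tp=tp, fp=fp, tn=tn, fn=fn)
        cms.append(cm)
        points.append((fp / n_neg, tp / n_pos))
    if not positive_low:
        # sweep runs (1,1) -> (0,0); reverse so the curve is non-decreasing
        points.reverse()
        cms.reverse()
        thresholds = tuple(reversed(thresholds))

    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(
        thresholds=thresholds,
        points=tuple(points),
        auc=auc,
        auc_ci=_hanley_mcneil_ci(auc, n_pos, n_neg, alpha),
        positive_low=positive_low,
        n_pos=n_pos,
        n_neg=n_neg,
        per_threshold=tuple(cms),
    )


@dataclass(frozen=True)
class CutoffResult:
    threshold: int
    youden_j: float
    sensitivity: float
    specificity: float
    criterion: str = "youden"


def optimal_cutoff(roc: RocCurve) -> CutoffResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the lower threshold (the more specific operating
    point when low scores are positive).
    """
    best: Optional[CutoffResult] = None
    for t, (fpr, tpr) in sorted(zip(roc.thresholds, roc.points)):
        j = tpr - fpr
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(
                threshold=int(t),
                youden_j=j,
                sensitivity=tpr,
                specificity=1.0 - fpr,
            )
    assert best is not None
    return best


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length samples (n >= 3)."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x_arr.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x_arr, y_arr).statistic)


def build_2x2(summary, factor: str, impaired_groups) -> ContingencyTable2x2:
    """2x2 table for ``factor`` pooling ``impaired_groups`` against the rest.

    ``summary`` may be a :class:`bht.cohort.CohortSummary` or an iterable of
    :class:`bht.cohort.CohortRecord`.  Exposed means the factor is present;
    groups not listed as impaired (excluding ``unknown``) form the healthy
    arm.
    """
    from .cohort import CohortSummary, summarize_cohort  # local import, avoids cycle

    if not isinstance(summary, CohortSummary):
        summary = summarize_cohort(list(summary))
    impaired = {str(g).lower() for g in impaired_groups}
    known = [g for g in summary.group_sizes if g != "unknown"]
    unknown_groups = impaired - set(known)
    if unknown_groups:
        raise KeyError(f"unknown group(s): {sorted(unknown_groups)}")
    healthy_arm = [g for g in known if g not in impaired]
    if not healthy_arm:
        raise ValueError("no comparison group left after pooling impaired groups")

    def exposed(groups: list[str]) -> tuple[int, int]:
        n = sum(summary.group_sizes[g] for g in groups)
        try:
            count = sum(summary.factor_counts[g][factor] for g in groups)
        except KeyError as exc:
            raise KeyError(f"unknown factor {factor!r}") from exc
        return count, n

    a, n_imp = exposed(sorted(impaired))
    c, n_hea = exposed(healthy_arm)
    return ContingencyTable2x2(a=a, b=n_imp - a, c=c, d=n_hea - c)
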