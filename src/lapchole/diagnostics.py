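"""Diagnostic-accuracy engine for an ordinal risk score against a binary
reference standard.

Everything here treats the preoperative score as the index test and the
dichotomised intraoperative grade (easy vs difficult) as the reference
standard.  The score is a small integer, so ties are ubiquitous: the ROC
curve is built with one operating point per integer threshold and its
trapezoidal area coincides with the tie-aware Mann-Whitney statistic
(concordant pairs plus half credit for ties).

Confidence intervals for the AUC use the Hanley-McNeil variance by default;
the DeLong estimator is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Difficulty, ValidationError

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "RocCurve",
    "GroupedCounts",
    "CutoffRow",
    "DegenerateInputError",
    "confusion_at_cutoff",
    "metrics_from_counts",
    "roc_curve",
    "auc_grouped",
    "auc_confidence_interval",
    "delong_auc_variance",
    "cutoff_table",
    "youden_optimal_cutoff",
]


class DegenerateInputError(ValueError):
    """Input lacks one of the two classes (or is otherwise uninformative)."""


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    """Map easy/difficult labels (enum or string) to 0/1 with 1 = difficult."""
    out = np.asarray(
        [1 if Difficulty(l) is Difficulty.DIFFICULT else 0 for l in labels],
        dtype=np.int64,
    )
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts at one cutoff; positive = predicted difficult."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy measures derived from a 2x2 table.

    A field is ``None`` when its denominator is zero (undefined), never 0/0
    coerced to a number.  ``youden`` = sensitivity + specificity - 1.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    youden: Optional[float]


@dataclass(frozen=True)
class RocCurve:
    """Operating points per integer threshold plus trapezoidal AUC and CI.

    ``points[i]`` is the (false-positive rate, true-positive rate) pair for
    ``thresholds[i]``; thresholds ascend from min(score) (where the curve sits
    at (1,1)) to max(score)+1 (where it reaches (0,0)).
    """

    thresholds: tuple[int, ...]
    points: tuple[tuple[float, float], ...]
    auc: float
    auc_ci: tuple[float, float]
    confidence_level: float
    ci_method: str


@dataclass(frozen=True)
class GroupedCounts:
    """Easy/difficult counts per ordered category (e.g. risk strata)."""

    categories: tuple[str, ...]
    easy: tuple[int, ...]
    difficult: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.categories) == len(self.easy) == len(self.difficult)):
            raise ValidationError("grouped counts must have equal lengths")
        if min(self.easy) < 0 or min(self.difficult) < 0:
            raise ValidationError("counts must be nonnegative")


@dataclass(frozen=True)
class CutoffRow:
    cutoff: int
    counts: ConfusionCounts
    metrics: DiagnosticMetrics


def confusion_at_cutoff(
    scores: Sequence[int], labels: Sequence, cutoff: int
) -> ConfusionCounts:
    """Cross-classify predictions (score >= cutoff positive) against the
    reference labels."""
    s = np.asarray(scores)
    y = _as_binary_labels(labels)
    if s.shape[0] != y.shape[0]:
        raise ValidationError(
            f"scores and labels differ in length ({s.shape[0]} vs {y.shape[0]})"
        )
    pos = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        tn=int(np.sum(~pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
    )


def metrics_from_counts(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, predictive values and Youden index from a
    2x2 table; any metric with a zero denominator is None."""
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else None
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    npv = c.tn / (c.tn + c.fn) if c.tn + c.fn > 0 else None
    youden = sens + spec - 1 if sens is not None and spec is not None else None
    return DiagnosticMetrics(sens, spec, ppv, npv, youden)


def roc_curve(
    scores: Sequence[int],
    labels: Sequence,
    confidence_level: float = 0.95,
    ci_method: str = "hanley-mcneil",
) -> RocCurve:
    """ROC curve over all integer thresholds with trapezoidal AUC.

    One operating point is computed per integer threshold from min(score) to
    max(score)+1, so the empirical curve (and its trapezoidal area, which
    equals the tie-aware concordance probability) is represented exactly.
    """
    s = np.asarray(scores)
    y = _as_binary_labels(labels)
    if s.shape[0] != y.shape[0]:
        raise ValidationError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both easy and difficult cases are required")

    lo, hi = int(np.min(s)), int(np.max(s))
    thresholds = tuple(range(lo, hi + 2))
    points = []
    for t in thresholds:
        pos = s >= t
        tpr = float(np.sum(pos & (y == 1))) / n_pos
        fpr = float(np.sum(pos & (y == 0))) / n_neg
        points.append((fpr, tpr))

    # trapezoid over points ordered by descending threshold = ascending FPR
    auc = 0.0
    for (fpr1, tpr1), (fpr0, tpr0) in zip(points[:-1], points[1:]):
        auc += 0.5 * (tpr1 + tpr0) * (fpr1 - fpr0)

    if not 0.0 < auc < 1.0:
        # a boundary AUC has zero Hanley-McNeil variance; keep a point interval
        ci = (auc, auc)
        if ci_method not in ("hanley-mcneil", "delong"):
            raise ValidationError(f"unknown ci_method {ci_method!r}")
    elif ci_method == "hanley-mcneil":
        ci = auc_confidence_interval(auc, n_pos, n_neg, confidence_level)
    elif ci_method == "delong":
        var = delong_auc_variance(s, y)
        z = stats.norm.ppf(0.5 + confidence_level / 2.0)
        half = z * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return RocCurve(thresholds, tuple(points), auc, ci, confidence_level, ci_method)


def auc_grouped(g: GroupedCounts) -> float:
    """Concordance AUC when patients are only known up to an ordered category.

    Every patient in a category shares the same ordinal value, so
    AUC = [#(difficult above easy) + 0.5 * #(same category)] / (n_easy * n_difficult).
    """
    easy = np.asarray(g.easy, dtype=np.float64)
    diff = np.asarray(g.difficult, dtype=np.float64)
    if len(easy) < 2:
        raise ValidationError("at least two categories required")
    n_e, n_d = easy.sum(), diff.sum()
    if n_e == 0 or n_d == 0:
        raise DegenerateInputError("both classes must be present")
    conc = 0.0
    ties = 0.0
    for i, d in enumerate(diff):
        conc += d * easy[:i].sum()
        ties += d * easy[i]
    return float((conc + 0.5 * ties) / (n_e * n_d))


def auc_confidence_interval(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil interval for the AUC.

    Variance = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the symmetric normal interval is
    clipped to [0, 1].
    """
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    if not 0 < auc < 1:
        raise ValidationError(f"auc must be in (0,1), got {auc}")
    if n_pos <= 0 or n_neg <= 0:
        raise ValidationError("class sizes must be positive")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (max(0.0, a - half), min(1.0, a + half))


def delong_auc_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the empirical (tie-aware) AUC.

    Uses the placement-value formulation: V10 for positives, V01 for
    negatives, combined as var(V10)/m + var(V01)/n.
    """
    s = np.asarray(scores, dtype=np.float64)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array(
        [(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos]
    )
    v01 = np.array(
        [(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg]
    )
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def cutoff_table(
    scores: Sequence[int], labels: Sequence, cutoffs: Sequence[int]
) -> list[CutoffRow]:
    """Per-cutoff accuracy battery: one row per requested cutoff."""
    rows = []
    for c in cutoffs:
        counts = confusion_at_cutoff(scores, labels, int(c))
        rows.append(CutoffRow(int(c), counts, metrics_from_counts(counts)))
    return rows


def youden_optimal_cutoff(table: Sequence[CutoffRow]) -> int:
    """Cutoff maximising the Youden index; ties go to the smallest cutoff
    (which favours sensitivity)."""
    if not table:
        raise ValidationError("cutoff table is empty")
    best = None
    best_y = -np.inf
    for row in sorted(table, key=lambda r: r.cutoff):
        y = row.metrics.youden
        if y is not None and y > best_y:
            best, best_y = row.cutoff, y
    if best is None:
        raise DegenerateInputError("no cutoff has a defined Youden index")
    return best
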