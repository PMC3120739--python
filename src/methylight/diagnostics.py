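"""Diagnostic calibration of an RCN cutoff against a gold standard.

Samples carry a non-negative score (standardized relative copy number)
and a binary gold-standard label (here, a prognosis-validated MSP
result).  The classification rule is score >= cutoff => test-positive.
The module builds the full ROC curve, computes AUC by the trapezoid rule
(equal to the Mann-Whitney probability with ties counted half), selects
the cutoff maximizing the Youden index, and summarizes 2x2 association
(odds ratio with Woolf log-normal CI, chi-square or Fisher exact test).

"Accuracy" throughout is the Youden index, sensitivity + specificity - 1:
a chance-corrected summary in [-1, 1] that does not depend on prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DiagnosticsError

Label = Literal["positive", "negative"]


@dataclass(frozen=True)
class LabeledScore:
    sample_id: str
    score: float
    label: Label

    def __post_init__(self) -> None:
        if self.score < 0:
            raise DiagnosticsError(
                f"sample {self.sample_id!r}: score {self.score} is negative"
            )
        if self.label not in ("positive", "negative"):
            raise DiagnosticsError(f"label must be positive/negative, got {self.label!r}")


class ROCPoint(NamedTuple):
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass
class ROCCurve:
    points: list[ROCPoint]
    auc: float


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.score for s in scores if s.label == "positive"], dtype=float)
    neg = np.array([s.score for s in scores if s.label == "negative"], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise DiagnosticsError(
            "ROC needs at least one positive and one negative label"
        )
    return pos, neg


def evaluate_at_cutoff(
    scores: Sequence[LabeledScore], cutoff: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule score >= cutoff => positive."""
    pos, neg = _split(scores)
    sens = float(np.mean(pos >= cutoff))
    spec = float(np.mean(neg < cutoff))
    return sens, spec


def roc_points(scores: Sequence[LabeledScore]) -> ROCCurve:
    """Full ROC curve over every achievable threshold.

    One point per distinct observed score (the cutoff representative for
    the threshold between two adjacent distinct scores is their midpoint,
    a dataset-independent representation), plus the two boundary points:
    cutoff at the minimum score (everything positive, sensitivity 1) and
    a cutoff above the maximum (everything negative, specificity 1).
    """
    pos, neg = _split(scores)
    distinct = np.unique(np.concatenate([pos, neg]))
    cutoffs = [float(distinct[0])]
    cutoffs += [float((a + b) / 2) for a, b in zip(distinct[:-1], distinct[1:])]
    cutoffs.append(float(distinct[-1] + 1.0))
    points = [
        ROCPoint(c, *evaluate_at_cutoff(scores, c)) for c in cutoffs
    ]
    curve = ROCCurve(points=points, auc=math.nan)
    curve.auc = auc_trapezoid(curve)
    return curve


def auc_trapezoid(roc: ROCCurve) -> float:
    """Trapezoidal area under the curve in (1 - specificity, sensitivity)."""
    fpr = np.array([1 - p.specificity for p in roc.points])
    tpr = np.array([p.sensitivity for p in roc.points])
    # order along the curve (decreasing cutoff): fpr and tpr both
    # non-decreasing, so a lexicographic sort recovers the staircase
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


class YoudenResult(NamedTuple):
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float


def accuracy_youden(sensitivity: float, specificity: float) -> float:
    """Youden-index accuracy: sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise DiagnosticsError(f"{name} {v} outside [0, 1]")
    return sensitivity + specificity - 1.0


def youden_cutoff(roc: ROCCurve) -> YoudenResult:
    """The ROC point maximizing the Youden index.

    Ties are broken toward higher specificity, then toward the higher
    cutoff, preferring the more conservative (more specific) rule.
    """
    best: ROCPoint | None = None
    for p in roc.points:
        if best is None:
            best = p
            continue
        j_p = p.sensitivity + p.specificity
        j_b = best.sensitivity + best.specificity
        if (j_p, p.specificity, p.cutoff) > (j_b, best.specificity, best.cutoff):
            best = p
    assert best is not None
    return YoudenResult(
        cutoff=best.cutoff,
        sensitivity=best.sensitivity,
        specificity=best.specificity,
        accuracy=accuracy_youden(best.sensitivity, best.specificity),
    )


# ---------------------------------------------------------------------------
# 2x2 association


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = gold standard (or exposure), columns = outcome.

    a: truth-positive & test-positive   b: truth-positive & test-negative
    c: truth-negative & test-positive   d: truth-negative & test-negative
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DiagnosticsError(f"cell {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def two_by_two(
    predictions: Sequence[bool], truths: Sequence[bool]
) -> ContingencyTable2x2:
    """Cross-tabulate binary test calls against the gold standard."""
    if len(predictions) != len(truths):
        raise DiagnosticsError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if len(predictions) == 0:
        raise DiagnosticsError("empty input")
    p = np.asarray(predictions, dtype=bool)
    t = np.asarray(truths, dtype=bool)
    return ContingencyTable2x2(
        a=int(np.sum(t & p)),
        b=int(np.sum(t & ~p)),
        c=int(np.sum(~t & p)),
        d=int(np.sum(~t & ~p)),
    )


class OddsRatioResult(NamedTuple):
    or_point: float
    ci_low: float
    ci_high: float
    corrected: bool


def odds_ratio_ci(table: ContingencyTable2x2, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with a Woolf log-normal confidence interval.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell, reported via ``corrected``).  The CI method is a toolkit
    choice; other CI constructions (exact, score) give different bounds.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        or_point=or_point,
        ci_low=math.exp(math.log(or_point) - z * se),
        ci_high=math.exp(math.log(or_point) + z * se),
        corrected=corrected,
    )


def association_p(table: ContingencyTable2x2) -> tuple[float, str]:
    """Two-sided association test: chi-square without continuity correction
    when the large-sample approximation is trustworthy (all expected counts
    >= 5 and no empty observed cell), otherwise Fisher's exact test.

    Returns (p-value, method name).
    """
    arr = table.as_array()
    if arr.sum() == 0:
        raise DiagnosticsError("empty table")
    expected = stats.contingency.expected_freq(arr)
    if np.all(expected >= 5) and np.all(arr > 0):
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return float(p), "chi-square"
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p), "fisher-exact"


@dataclass
class DiagnosticSummary:
    """Cutoff calibration plus 2x2 association at that cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    table: ContingencyTable2x2
    or_point: float
    or_ci: tuple[float, float]
    p_value: float
    p_method: str
    flags: list[str] = field(default_factory=list)


def summarize(scores: Sequence[LabeledScore]) -> DiagnosticSummary:
    """End-to-end calibration: ROC, Youden cutoff, and association at it."""
    curve = roc_points(scores)
    y = youden_cutoff(curve)
    preds = [s.score >= y.cutoff for s in scores]
    truths = [s.label == "positive" for s in scores]
    table = two_by_two(preds, truths)
    orr = odds_ratio_ci(table)
    p, method = association_p(table)
    flags = ["zero cell: Haldane-Anscombe correction applied"] if orr.corrected else []
    return DiagnosticSummary(
        cutoff=y.cutoff,
        sensitivity=y.sensitivity,
        specificity=y.specificity,
        accuracy=y.accuracy,
        auc=curve.auc,
        table=table,
        or_point=orr.or_point,
        or_ci=(orr.ci_low, orr.ci_high),
        p_value=p,
        p_method=method,
        flags=flags,
    )
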