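"""Open-set evaluation: four-way judgment, P/R/F, ROC, threshold selection.

The validation methodology treats the rejection option as a first-class
outcome.  Each validation question is labelled by whether the system *has*
a correct answer for it, and each system response is judged:

* TP — answerable, and the system returned the expected answer;
* FN — answerable, but the system returned a wrong answer **or** rejected;
* FP — unanswerable, but the system returned some answer;
* TN — unanswerable, and the system rejected ("I do not have an answer").

Precision = TP/(TP+FP), recall = TP/(TP+FN), F = harmonic mean; the overall
correct rate is 100·(TP+TN)/total.  The operating threshold is chosen by
sweeping a grid, plotting sensitivity = TP/answerable against
1 − specificity where specificity = TN/unanswerable, and maximizing the
Youden index sensitivity − (1 − specificity).  Note "positive" is
*answerable and correctly answered*: a wrong answer to an answerable
question counts against sensitivity even though the system did answer.

Threshold selection on the same set that is reported on is in-sample
calibration; reports produced through ``evaluate(..., threshold="auto")``
carry a flag saying so.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    EvaluationError,
    ParameterError,
    RegistryIOError,
    ValidationDataError,
)
from .router import QASystem, SystemResponse, ask

DEFAULT_GRID = tuple(round(0.01 * i, 2) for i in range(101))


@dataclass(frozen=True)
class ValidationQuestion:
    text: str
    has_answer_in_system: bool
    expected_answer_id: str | None = None
    author_group: str | None = None


@dataclass(frozen=True)
class JudgedResponse:
    question: ValidationQuestion
    response: SystemResponse
    judgment: str  # TP | FN | FP | TN
    note: str = ""  # free-text error annotation (optional)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Precision/recall/F and the correct rate at one threshold.

    Printed fields are rounded the way the original report prints them
    (metrics to 3 decimals, percentage to 1); the ``*_unrounded`` twins keep
    full precision for machine consumption.  Undefined quotients are NaN,
    never silently 0.
    """

    counts: ConfusionCounts
    threshold: float
    precision_unrounded: float
    recall_unrounded: float
    f_measure_unrounded: float
    correct_rate_unrounded: float
    calibrated_in_sample: bool = False
    by_group: dict[str, "MetricsReport"] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return _round3(self.precision_unrounded)

    @property
    def recall(self) -> float:
        return _round3(self.recall_unrounded)

    @property
    def f_measure(self) -> float:
        return _round3(self.f_measure_unrounded)

    @property
    def correct_rate(self) -> float:
        return _round1(self.correct_rate_unrounded)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "counts": vars(self.counts),
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "correct_rate": self.correct_rate,
            "precision_unrounded": self.precision_unrounded,
            "recall_unrounded": self.recall_unrounded,
            "f_measure_unrounded": self.f_measure_unrounded,
            "correct_rate_unrounded": self.correct_rate_unrounded,
            "calibrated_in_sample": self.calibrated_in_sample,
            "by_group": {g: r.to_dict() for g, r in self.by_group.items()},
        }


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity - (1.0 - self.specificity)


def _round3(x: float) -> float:
    return x if math.isnan(x) else round(x, 3)


def _round1(x: float) -> float:
    return x if math.isnan(x) else round(x, 1)


# ---------------------------------------------------------------------------
# Judgment and tallies


def judge(question: ValidationQuestion, response: SystemResponse) -> str:
    """Four-way open-set judgment (see module docstring truth table)."""
    if question.has_answer_in_system:
        if question.expected_answer_id is None:
            raise ValidationDataError(
                "question marked answerable but expected_answer_id is missing: "
                f"{question.text!r}"
            )
        if (
            response.kind == "answered"
            and response.answer_id == question.expected_answer_id
        ):
            return "TP"
        return "FN"  # wrong answer or rejection both count as misses
    if response.kind == "answered":
        return "FP"
    return "TN"


def tally(judged: Iterable[JudgedResponse]) -> ConfusionCounts:
    counts = Counter(j.judgment for j in judged)
    unknown = set(counts) - {"TP", "FN", "FP", "TN"}
    if unknown:
        raise ValidationDataError(f"unknown judgments {sorted(unknown)}")
    return ConfusionCounts(
        tp=counts.get("TP", 0),
        fn=counts.get("FN", 0),
        fp=counts.get("FP", 0),
        tn=counts.get("TN", 0),
    )


def compute_metrics(counts: ConfusionCounts, threshold: float) -> MetricsReport:
    """P/R/F and correct rate from confusion counts; NaN with a warning on
    zero denominators."""
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        warnings.warn("precision undefined (tp + fp = 0); reporting NaN", stacklevel=2)
        precision = math.nan
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        warnings.warn("recall undefined (tp + fn = 0); reporting NaN", stacklevel=2)
        recall = math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f = math.nan
    else:
        f = 2 * precision * recall / (precision + recall)
    if counts.total > 0:
        correct = 100.0 * (counts.tp + counts.tn) / counts.total
    else:
        correct = math.nan
    return MetricsReport(
        counts=counts,
        threshold=threshold,
        precision_unrounded=precision,
        recall_unrounded=recall,
        f_measure_unrounded=f,
        correct_rate_unrounded=correct,
    )


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, rounded to 3 decimals
    (the arithmetic behind every printed F-measure)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ParameterError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        warnings.warn("F undefined for precision = recall = 0; reporting NaN", stacklevel=2)
        return math.nan
    return round(2 * precision * recall / (precision + recall), 3)


# ---------------------------------------------------------------------------
# Threshold sweeps


def _redecide(response: SystemResponse, threshold: float) -> SystemResponse:
    """Re-derive the answer/reject decision of a threshold-0 response at a
    different threshold, without re-running the classifiers."""
    answered = (
        response.answer_id is not None and response.answer_confidence >= threshold
    )
    if answered:
        return SystemResponse(
            kind="answered",
            answer_id=response.answer_id,
            answer_text=response.answer_text,
            category_id=response.category_id,
            sorting_confidence=response.sorting_confidence,
            answer_confidence=response.answer_confidence,
            threshold_used=threshold,
        )
    return SystemResponse(
        kind="no_answer",
        answer_id=None,
        answer_text=None,
        category_id=response.category_id,
        sorting_confidence=response.sorting_confidence,
        answer_confidence=response.answer_confidence,
        threshold_used=threshold,
    )


def roc_curve(
    judged_at_zero_threshold: Sequence[tuple[ValidationQuestion, SystemResponse]],
    thresholds: Sequence[float] = DEFAULT_GRID,
) -> list[ROCPoint]:
    """One ROC point per grid threshold.

    Input responses must carry raw top confidences (obtained at threshold 0);
    at each grid value the answer/reject decision is re-derived, judged and
    tallied.  Sensitivity = TP/answerable, specificity = TN/unanswerable.
    Both strata must be present.
    """
    if not thresholds:
        raise ParameterError("threshold grid must be non-empty")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ParameterError("threshold grid must be ascending")
    n_answerable = sum(1 for q, _ in judged_at_zero_threshold if q.has_answer_in_system)
    n_unanswerable = len(judged_at_zero_threshold) - n_answerable
    if n_answerable == 0 or n_unanswerable == 0:
        raise EvaluationError(
            "ROC analysis needs both answerable and unanswerable validation "
            f"questions (got {n_answerable} answerable, {n_unanswerable} "
            "unanswerable)"
        )
    points = []
    for t in thresholds:
        tp = tn = 0
        for question, response in judged_at_zero_threshold:
            j = judge(question, _redecide(response, t))
            if j == "TP":
                tp += 1
            elif j == "TN":
                tn += 1
        points.append(
            ROCPoint(
                threshold=t,
                sensitivity=tp / n_answerable,
                specificity=tn / n_unanswerable,
            )
        )
    return points


def quantile_grid(
    judged_at_zero_threshold: Sequence[tuple[ValidationQuestion, SystemResponse]],
    n: int = 200,
) -> list[float]:
    """An ascending threshold grid spanning the observed confidence range.

    The default percent grid (0.00–1.00 step 0.01) matches the original
    report's resolution, but a system with many answers per category spreads
    its confidence mass thinly (sum-normalization over hundreds of labels),
    so all the action can sit below 0.01.  This grid places thresholds at
    confidence quantiles instead, plus 0 and 1 as anchors.
    """
    confs = sorted(r.answer_confidence for _, r in judged_at_zero_threshold)
    if not confs:
        raise ParameterError("no responses to build a grid from")
    grid = {0.0, 1.0}
    for i in range(n + 1):
        grid.add(confs[min(len(confs) - 1, (i * len(confs)) // (n + 1))])
    return sorted(grid)


def select_threshold(points: Sequence[ROCPoint]) -> float:
    """Youden-maximizing threshold; ties go to the smallest threshold."""
    if not points:
        raise ParameterError("no ROC points to select from")
    best = max(points, key=lambda p: (p.youden, -p.threshold))
    return best.threshold


# ---------------------------------------------------------------------------
# End-to-end evaluation


def collect_responses(
    system: QASystem, validation: Sequence[ValidationQuestion]
) -> list[tuple[ValidationQuestion, SystemResponse]]:
    """Run every validation question through the system at threshold 0 so
    raw top confidences are retained for threshold sweeps."""
    return [(q, ask(system, q.text, threshold=0.0)) for q in validation]


def evaluate(
    system: QASystem,
    validation: Sequence[ValidationQuestion],
    threshold: float | str = "auto",
    grid: Sequence[float] = DEFAULT_GRID,
) -> MetricsReport:
    """Full validation run.

    ``threshold="auto"`` calibrates on this same validation set (ROC +
    Youden) before reporting — the report's ``calibrated_in_sample`` flag
    records that.  Per-``author_group`` sub-reports are attached when any
    question carries a group label.
    """
    pairs = collect_responses(system, validation)
    if threshold == "auto":
        t = select_threshold(roc_curve(pairs, grid))
        in_sample = True
    else:
        t = float(threshold)
        if not 0.0 <= t <= 1.0:
            raise ParameterError(f"threshold must be in [0, 1], got {t}")
        in_sample = False

    def _report(sub: Sequence[tuple[ValidationQuestion, SystemResponse]]) -> MetricsReport:
        judged = [
            JudgedResponse(q, _redecide(r, t), judge(q, _redecide(r, t)))
            for q, r in sub
        ]
        return compute_metrics(tally(judged), t)

    report = _report(pairs)
    report.calibrated_in_sample = in_sample
    groups = sorted({q.author_group for q, _ in pairs if q.author_group})
    for g in groups:
        report.by_group[g] = _report([(q, r) for q, r in pairs if q.author_group == g])
    return report


# ---------------------------------------------------------------------------
# I/O


def load_validation(path: str | Path) -> list[ValidationQuestion]:
    """Read ``validation.tsv`` (columns: text, has_answer_in_system,
    expected_answer_id, author_group)."""
    path = Path(path)
    out = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"text", "has_answer_in_system"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise RegistryIOError(
                f"{path}: expected columns text, has_answer_in_system"
            )
        for lineno, row in enumerate(reader, start=2):
            flag = (row["has_answer_in_system"] or "").strip().lower()
            if flag not in ("true", "false", "1", "0", "yes", "no"):
                raise RegistryIOError(
                    f"{path}: line {lineno}: bad has_answer_in_system {flag!r}"
                )
            has_answer = flag in ("true", "1", "yes")
            out.append(
                ValidationQuestion(
                    text=row["text"],
                    has_answer_in_system=has_answer,
                    expected_answer_id=(row.get("expected_answer_id") or None),
                    author_group=(row.get("author_group") or None),
                )
            )
    return out


def save_validation(validation: Sequence[ValidationQuestion], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["text", "has_answer_in_system", "expected_answer_id", "author_group"])
        for q in validation:
            writer.writerow(
                [
                    q.text,
                    "true" if q.has_answer_in_system else "false",
                    q.expected_answer_id or "",
                    q.author_group or "",
                ]
            )


def save_roc(points: Sequence[ROCPoint], path: str | Path) -> None:
    """CSV: threshold,sensitivity,specificity,youden."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["threshold", "sensitivity", "specificity", "youden"])
        for p in points:
            writer.writerow([p.threshold, p.sensitivity, p.specificity, p.youden])
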