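import math

import numpy as np
import pytest

import kampoqa as k
from kampoqa.errors import EvaluationError, ParameterError, ValidationDataError
from kampoqa.evaluation import (
    ConfusionCounts,
    JudgedResponse,
    ROCPoint,
    ValidationQuestion,
    compute_metrics,
    evaluate,
    f_from_pr,
    judge,
    load_validation,
    quantile_grid,
    roc_curve,
    save_validation,
    select_threshold,
    tally,
)
from kampoqa.router import SystemResponse


def _response(kind, answer_id, confidence, category="C1"):
    return SystemResponse(
        kind=kind,
        answer_id=answer_id if kind == "answered" else None,
        answer_text="..." if kind == "answered" else None,
        category_id=category,
        sorting_confidence=0.9,
        answer_confidence=confidence,
        threshold_used=0.61,
    )


# The five judgment situations of the original validation worked examples:
# answerable + correct answer (95.2%) -> TP; answerable + wrong answer
# (71.4%) -> FN; answerable but rejected at 45.6% < 61% -> FN;
# unanswerable + rejected (40.5%) -> TN; unanswerable + answered (95.5%) -> FP
JUDGMENT_TABLE = [
    (ValidationQuestion("q", True, "A1"), _response("answered", "A1", 0.952), "TP"),
    (ValidationQuestion("q", True, "A1"), _response("answered", "A2", 0.714), "FN"),
    (ValidationQuestion("q", True, "A1"), _response("no_answer", None, 0.456), "FN"),
    (ValidationQuestion("q", False), _response("no_answer", None, 0.405), "TN"),
    (ValidationQuestion("q", False), _response("answered", "A9", 0.955), "FP"),
]


@pytest.mark.parametrize("question,response,expected", JUDGMENT_TABLE)
def test_open_set_judgment_truth_table(question, response, expected):
    assert judge(question, response) == expected


def test_answerable_question_without_expected_id_is_a_data_error():
    with pytest.raises(ValidationDataError):
        judge(ValidationQuestion("q", True, None), _response("answered", "A1", 0.9))


def test_tally_counts_and_preserves_total():
    assert tally([]) == ConfusionCounts(0, 0, 0, 0)
    judged = [
        JudgedResponse(q, r, j) for q, r, j in JUDGMENT_TABLE
    ]
    counts = tally(judged)
    assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 2, 1, 1)
    assert counts.total == len(judged)

    rng = np.random.default_rng(0)
    labels = rng.choice(["TP", "FN", "FP", "TN"], size=900)
    judged = [
        JudgedResponse(ValidationQuestion("q", False), _response("no_answer", None, 0.1), j)
        for j in labels
    ]
    counts = tally(judged)
    # one-pass recount oracle
    assert counts.tp == (labels == "TP").sum()
    assert counts.fn == (labels == "FN").sum()
    assert counts.fp == (labels == "FP").sum()
    assert counts.tn == (labels == "TN").sum()
    assert counts.total == 900


def test_metric_formulas():
    perfect = compute_metrics(ConfusionCounts(1, 0, 0, 0), 0.5)
    assert (perfect.precision, perfect.recall, perfect.f_measure) == (1.0, 1.0, 1.0)
    sym = compute_metrics(ConfusionCounts(1, 1, 1, 0), 0.5)
    assert (sym.precision, sym.recall, sym.f_measure) == (0.5, 0.5, 0.5)

    rng = np.random.default_rng(1)
    for _ in range(50):
        tp, fn, fp, tn = (int(x) for x in rng.integers(1, 400, size=4))
        report = compute_metrics(ConfusionCounts(tp, fn, fp, tn), 0.5)
        p, r = tp / (tp + fp), tp / (tp + fn)
        assert report.precision_unrounded == pytest.approx(p, abs=1e-12)
        assert report.recall_unrounded == pytest.approx(r, abs=1e-12)
        assert report.f_measure_unrounded == pytest.approx(
            2 * p * r / (p + r), abs=1e-12
        )
        assert report.correct_rate_unrounded == pytest.approx(
            100 * (tp + tn) / (tp + fn + fp + tn), abs=1e-12
        )


def test_undefined_quotients_are_nan_with_warning():
    with pytest.warns(UserWarning, match="precision undefined"):
        report = compute_metrics(ConfusionCounts(0, 1, 0, 1), 0.5)
    assert math.isnan(report.precision)
    assert report.recall == 0.0


@pytest.mark.parametrize(
    "precision,recall,expected",
    [
        (0.986, 0.915, 0.949),  # at the ROC-selected 61% threshold
        (0.982, 0.935, 0.958),  # 50%
        (0.985, 0.917, 0.950),  # 60%
        (0.987, 0.888, 0.935),  # 70%
        (1.0, 1.0, 1.000),
    ],
)
def test_f_measure_harmonic_mean(precision, recall, expected):
    assert f_from_pr(precision, recall) == expected


def test_f_undefined_for_zero_precision_and_recall():
    with pytest.warns(UserWarning):
        assert math.isnan(f_from_pr(0.0, 0.0))
    with pytest.raises(ParameterError):
        f_from_pr(1.2, 0.5)


def _synthetic_pairs(rng, n=200, answerable_frac=0.7, separable=False):
    pairs = []
    for i in range(n):
        answerable = rng.random() < answerable_frac
        if answerable:
            correct = rng.random() < 0.8
            conf = (
                rng.uniform(0.8, 1.0)
                if separable and correct
                else rng.uniform(0.2, 1.0)
            )
            answer = "A-good" if correct else "A-bad"
            q = ValidationQuestion(f"q{i}", True, "A-good")
            pairs.append((q, _response("answered", answer, conf)))
        else:
            conf = rng.uniform(0.0, 0.3) if separable else rng.uniform(0.0, 0.9)
            q = ValidationQuestion(f"q{i}", False)
            pairs.append((q, _response("answered", "A-any", conf)))
    return pairs


def test_roc_matches_exhaustive_rejudging_oracle():
    rng = np.random.default_rng(3)
    pairs = _synthetic_pairs(rng, n=200)
    grid = [round(0.01 * i, 2) for i in range(101)]
    points = roc_curve(pairs, grid)
    n_ans = sum(q.has_answer_in_system for q, _ in pairs)
    n_un = len(pairs) - n_ans
    for point in points:
        tp = tn = 0
        for q, r in pairs:
            answered = r.answer_confidence >= point.threshold
            if q.has_answer_in_system:
                tp += answered and r.answer_id == q.expected_answer_id
            else:
                tn += not answered
        assert point.sensitivity == pytest.approx(tp / n_ans)
        assert point.specificity == pytest.approx(tn / n_un)
        assert point.youden == pytest.approx(
            point.sensitivity - (1 - point.specificity)
        )


def test_separable_confidences_reach_youden_one():
    rng = np.random.default_rng(4)
    pairs = _synthetic_pairs(rng, n=200, separable=True)
    # drop wrong-answer cases: separability is about confidence, and a wrong
    # answer caps sensitivity below 1 regardless of threshold
    pairs = [
        (q, r)
        for q, r in pairs
        if not q.has_answer_in_system or r.answer_id == q.expected_answer_id
    ]
    points = roc_curve(pairs, [round(0.01 * i, 2) for i in range(101)])
    assert max(p.youden for p in points) == pytest.approx(1.0)
    best = select_threshold(points)
    max_unans = max(
        r.answer_confidence for q, r in pairs if not q.has_answer_in_system
    )
    min_correct = min(
        r.answer_confidence for q, r in pairs if q.has_answer_in_system
    )
    assert max_unans < best <= min_correct  # inside the planted gap


def test_threshold_zero_has_zero_specificity_when_everything_is_answered():
    rng = np.random.default_rng(5)
    pairs = _synthetic_pairs(rng, n=100)
    point = roc_curve(pairs, [0.0])[0]
    assert point.specificity == 0.0


def test_roc_requires_both_strata_and_sane_grid():
    rng = np.random.default_rng(6)
    pairs = _synthetic_pairs(rng, n=50, answerable_frac=1.0)
    with pytest.raises(EvaluationError):
        roc_curve(pairs, [0.5])
    pairs = _synthetic_pairs(rng, n=50)
    with pytest.raises(ParameterError):
        roc_curve(pairs, [])
    with pytest.raises(ParameterError):
        roc_curve(pairs, [0.5, 0.4])


def test_select_threshold_tie_breaks_to_smallest():
    points = [ROCPoint(0.2, 0.5, 0.5), ROCPoint(0.4, 0.6, 0.4), ROCPoint(0.6, 0.4, 0.6)]
    assert select_threshold(points) == 0.2  # all youden == 0, smallest wins
    assert select_threshold([ROCPoint(0.3, 0.9, 0.8)]) == 0.3


def test_confusion_monotonicity_in_threshold():
    rng = np.random.default_rng(7)
    pairs = _synthetic_pairs(rng, n=300)
    grid = [round(0.05 * i, 2) for i in range(21)]
    points = roc_curve(pairs, grid)
    sens = [p.sensitivity for p in points]
    spec = [p.specificity for p in points]
    assert all(b <= a for a, b in zip(sens, sens[1:]))  # TP non-increasing
    assert all(b >= a for a, b in zip(spec, spec[1:]))  # TN non-decreasing


def test_evaluate_composes_the_individual_operations(separable_bundle, separable_system):
    from kampoqa.evaluation import collect_responses, _redecide

    validation = separable_bundle.validation
    report = evaluate(separable_system, validation, 0.12)
    # manual composition
    pairs = collect_responses(separable_system, validation)
    judged = [
        JudgedResponse(q, _redecide(r, 0.12), judge(q, _redecide(r, 0.12)))
        for q, r in pairs
    ]
    manual = compute_metrics(tally(judged), 0.12)
    assert report.counts == manual.counts
    assert report.precision_unrounded == manual.precision_unrounded
    assert not report.calibrated_in_sample
    # per-author-group subreports partition the total
    assert set(report.by_group) == {"advanced", "basic", "student"}
    assert sum(r.counts.total for r in report.by_group.values()) == len(validation)


def test_roc_singleton_grid_agrees_with_fixed_threshold_evaluate(
    separable_bundle, separable_system
):
    from kampoqa.evaluation import collect_responses

    validation = separable_bundle.validation
    pairs = collect_responses(separable_system, validation)
    point = roc_curve(pairs, [0.12])[0]
    report = evaluate(separable_system, validation, 0.12)
    n_ans = sum(q.has_answer_in_system for q in validation)
    n_un = len(validation) - n_ans
    assert point.sensitivity == pytest.approx(report.counts.tp / n_ans)
    assert point.specificity == pytest.approx(report.counts.tn / n_un)


def test_precision_rises_and_recall_falls_with_threshold(
    separable_bundle, separable_system
):
    """The qualitative operating-characteristic claim: on a fixed validation
    set, raising the rejection threshold trades recall for precision."""
    reports = [
        evaluate(separable_system, separable_bundle.validation, t)
        for t in (0.0, 0.05, 0.12, 0.5, 0.9)
    ]
    precisions = [r.precision_unrounded for r in reports if r.counts.tp + r.counts.fp > 0]
    recalls = [r.recall_unrounded for r in reports]
    assert all(b >= a - 1e-12 for a, b in zip(precisions, precisions[1:]))
    assert all(b <= a + 1e-12 for a, b in zip(recalls, recalls[1:]))


def test_all_correct_validation_set_scores_perfectly(separable_bundle, separable_system):
    answerable = [q for q in separable_bundle.validation if q.has_answer_in_system]
    unanswerable = [
        q for q in separable_bundle.validation if not q.has_answer_in_system
    ]
    report = evaluate(separable_system, answerable + unanswerable, 0.12)
    assert (report.precision, report.recall, report.f_measure) == (1.0, 1.0, 1.0)
    assert report.correct_rate == 100.0


def test_quantile_grid_spans_observed_confidences():
    rng = np.random.default_rng(8)
    pairs = _synthetic_pairs(rng, n=100)
    grid = quantile_grid(pairs, n=50)
    assert grid[0] == 0.0 and grid[-1] == 1.0
    assert grid == sorted(grid)
    confs = sorted(r.answer_confidence for _, r in pairs)
    assert confs[len(confs) // 2] in grid


def test_validation_file_roundtrip(tmp_path):
    questions = [
        ValidationQuestion("can i use kakkonto", True, "A1", "advanced"),
        ValidationQuestion("unknown drug question", False, None, None),
    ]
    path = tmp_path / "validation.tsv"
    save_validation(questions, path)
    assert load_validation(path) == questions
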