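"""Data model, file I/O and structural validation for the QA registry.

A registry is the curated knowledge base behind the system: a small set of
categories (default six), answer entries (a drug-information text tied to a
category), and registered questions (several natural-language phrasings per
answer, one of which is flagged *representative*).  The two-tier architecture
consumes the registry twice: the representative questions train the upstream
category-sorting classifier, and the full question set trains each per-
category classifier.

Structural constraints mirror the operational quotas of the original
deployment: at least three questions per answer, and per category at most
3,000 answers and 20,000 questions.  They are surfaced as a validation
report rather than hard errors so that a registry under construction can
still be loaded and inspected.

Canonical on-disk form: UTF-8 TSV with a header row, answers and questions
in separate tables (``answers.tsv``, ``questions.tsv``, optional
``categories.tsv``), or a single ``registry.json``.  Writers sort rows by ID
for diff-stable output.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import (
    IntegrityError,
    RegistryIOError,
    UnknownCategoryError,
    ValidationDataError,
)

MIN_QUESTIONS_PER_ANSWER = 3
MAX_ANSWERS_PER_CATEGORY = 3_000
MAX_QUESTIONS_PER_CATEGORY = 20_000


@dataclass(frozen=True)
class Category:
    category_id: str
    name: str = ""
    description: str = ""


@dataclass(frozen=True)
class AnswerEntry:
    answer_id: str
    category_id: str
    answer_text: str
    source_section: str = "package-insert"
    drug_name: str | None = None


@dataclass(frozen=True)
class QuestionEntry:
    question_id: str
    answer_id: str
    text: str
    is_representative: bool = False


@dataclass(frozen=True)
class TrainingPair:
    """One (text, label) supervision example for a classifier tier."""

    text: str
    label: str


@dataclass(frozen=True)
class Violation:
    """One violated registry invariant; ``severity`` is ``"error"`` for
    structural problems and ``"warning"`` for quota-style limits."""

    code: str
    message: str
    offending_ids: tuple[str, ...] = ()
    severity: str = "error"


@dataclass
class QARegistry:
    categories: list[Category] = field(default_factory=list)
    answers: list[AnswerEntry] = field(default_factory=list)
    questions: list[QuestionEntry] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    @property
    def category_ids(self) -> list[str]:
        return [c.category_id for c in self.categories]

    def answer(self, answer_id: str) -> AnswerEntry:
        index = {a.answer_id: a for a in self.answers}
        if answer_id not in index:
            raise IntegrityError(f"unknown answer_id {answer_id!r}")
        return index[answer_id]

    def answers_in_category(self, category_id: str) -> list[AnswerEntry]:
        return [a for a in self.answers if a.category_id == category_id]

    def questions_for_answer(self, answer_id: str) -> list[QuestionEntry]:
        return [q for q in self.questions if q.answer_id == answer_id]

    def check_references(self) -> None:
        """Raise :class:`IntegrityError` on any dangling reference."""
        cat_ids = set(self.category_ids)
        ans_ids = {a.answer_id for a in self.answers}
        for a in self.answers:
            if a.category_id not in cat_ids:
                raise IntegrityError(
                    f"answer {a.answer_id!r} references unknown "
                    f"category_id {a.category_id!r}"
                )
        for q in self.questions:
            if q.answer_id not in ans_ids:
                raise IntegrityError(
                    f"question {q.question_id!r} references unknown "
                    f"answer_id {q.answer_id!r}"
                )


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path: Path, required: tuple[str, ...]) -> Iterator[dict]:
    try:
        fh = path.open(newline="", encoding="utf-8")
    except OSError as exc:
        raise RegistryIOError(str(exc)) from exc
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise RegistryIOError(f"{path}: empty file (header row required)")
        missing = set(required) - set(reader.fieldnames)
        if missing:
            raise RegistryIOError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(col) is None for col in required):
                raise RegistryIOError(f"{path}: line {lineno}: short row")
            yield row


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise RegistryIOError(f"{where}: cannot parse boolean {value!r}")


def _autoflag_representatives(questions: list[QuestionEntry]) -> list[QuestionEntry]:
    """First-listed question per answer becomes representative (used when a
    source lacks the flag; the choice rule is a documented stand-in)."""
    seen: set[str] = set()
    out = []
    for q in questions:
        rep = q.answer_id not in seen
        seen.add(q.answer_id)
        out.append(QuestionEntry(q.question_id, q.answer_id, q.text, rep))
    warnings.warn(
        "registry has no is_representative flags; auto-flagging the "
        "first-listed question per answer",
        stacklevel=3,
    )
    return out


def load_registry(path: str | Path, format: str = "tsv") -> QARegistry:
    """Load a registry from a TSV directory (``answers.tsv`` +
    ``questions.tsv`` + optional ``categories.tsv``) or a JSON file.

    Enforces referential integrity; cardinality constraints are left to
    :func:`validate_registry`.
    """
    path = Path(path)
    if format == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise RegistryIOError(f"{path}: {exc}") from exc
        categories = [Category(**c) for c in data.get("categories", [])]
        answers = [AnswerEntry(**a) for a in data.get("answers", [])]
        questions = [QuestionEntry(**q) for q in data.get("questions", [])]
    elif format in ("tsv", "csv"):
        delim_suffix = ".tsv" if format == "tsv" else ".csv"
        ans_path = path / f"answers{delim_suffix}"
        qst_path = path / f"questions{delim_suffix}"
        answers = []
        for row in _read_tsv(ans_path, ("answer_id", "category_id", "answer_text")):
            answers.append(
                AnswerEntry(
                    answer_id=row["answer_id"],
                    category_id=row["category_id"],
                    answer_text=row["answer_text"],
                    source_section=row.get("source_section") or "package-insert",
                    drug_name=row.get("drug_name") or None,
                )
            )
        questions = []
        has_flag_column = True
        with qst_path.open(newline="", encoding="utf-8") as fh:
            header = csv.reader(fh, delimiter="\t")
            first = next(header, None)
            has_flag_column = bool(first) and "is_representative" in first
        for row in _read_tsv(qst_path, ("question_id", "answer_id", "text")):
            flag = row.get("is_representative", "")
            questions.append(
                QuestionEntry(
                    question_id=row["question_id"],
                    answer_id=row["answer_id"],
                    text=row["text"],
                    is_representative=_parse_bool(flag or "", qst_path.name)
                    if has_flag_column
                    else False,
                )
            )
        if questions and not has_flag_column:
            questions = _autoflag_representatives(questions)
        cat_path = path / f"categories{delim_suffix}"
        if cat_path.exists():
            categories = [
                Category(
                    category_id=row["category_id"],
                    name=row.get("name") or row["category_id"],
                    description=row.get("description") or "",
                )
                for row in _read_tsv(cat_path, ("category_id",))
            ]
        else:
            categories = [
                Category(category_id=cid, name=cid)
                for cid in sorted({a.category_id for a in answers})
            ]
    else:
        raise RegistryIOError(f"unknown registry format {format!r}")

    registry = QARegistry(categories, answers, questions)
    registry.check_references()
    return registry


def save_registry(registry: QARegistry, path: str | Path, format: str = "tsv") -> None:
    """Write a registry; rows sorted by ID for diff-stable output."""
    path = Path(path)
    if format == "json":
        data = {
            "categories": [vars(c) for c in sorted(registry.categories, key=lambda c: c.category_id)],
            "answers": [vars(a) for a in sorted(registry.answers, key=lambda a: a.answer_id)],
            "questions": [vars(q) for q in sorted(registry.questions, key=lambda q: q.question_id)],
        }
        path.write_text(json.dumps(data, ensure_ascii=False, indent=1) + "\n", encoding="utf-8")
        return
    if format not in ("tsv", "csv"):
        raise RegistryIOError(f"unknown registry format {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".tsv" if format == "tsv" else ".csv"

    def _write(name: str, header: list[str], rows: list[list[str]]) -> None:
        with (path / f"{name}{suffix}").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    _write(
        "categories",
        ["category_id", "name", "description"],
        [
            [c.category_id, c.name, c.description]
            for c in sorted(registry.categories, key=lambda c: c.category_id)
        ],
    )
    _write(
        "answers",
        ["answer_id", "category_id", "answer_text", "source_section", "drug_name"],
        [
            [a.answer_id, a.category_id, a.answer_text, a.source_section, a.drug_name or ""]
            for a in sorted(registry.answers, key=lambda a: a.answer_id)
        ],
    )
    _write(
        "questions",
        ["question_id", "answer_id", "text", "is_representative"],
        [
            [q.question_id, q.answer_id, q.text, "true" if q.is_representative else "false"]
            for q in sorted(registry.questions, key=lambda q: q.question_id)
        ],
    )


# ---------------------------------------------------------------------------
# Validation


def validate_registry(registry: QARegistry) -> list[Violation]:
    """Return the list of violated invariants (empty iff the registry is
    fully well-formed, including exactly one representative per answer)."""
    violations: list[Violation] = []

    dup_answers = [a for a, n in Counter(a.answer_id for a in registry.answers).items() if n > 1]
    if dup_answers:
        violations.append(
            Violation("duplicate-answer-id", "answer_id not unique", tuple(sorted(dup_answers)))
        )
    dup_questions = [q for q, n in Counter(q.question_id for q in registry.questions).items() if n > 1]
    if dup_questions:
        violations.append(
            Violation("duplicate-question-id", "question_id not unique", tuple(sorted(dup_questions)))
        )
    dup_categories = [c for c, n in Counter(registry.category_ids).items() if n > 1]
    if dup_categories:
        violations.append(
            Violation("duplicate-category-id", "category_id not unique", tuple(sorted(dup_categories)))
        )

    if not registry.answers:
        violations.append(Violation("no-answers", "registry contains no answers"))

    empty_answers = [a.answer_id for a in registry.answers if not a.answer_text.strip()]
    if empty_answers:
        violations.append(
            Violation("empty-answer-text", "answer_text must be non-empty", tuple(empty_answers))
        )
    empty_questions = [q.question_id for q in registry.questions if not q.text.strip()]
    if empty_questions:
        violations.append(
            Violation("empty-question-text", "question text must be non-empty", tuple(empty_questions))
        )

    cat_ids = set(registry.category_ids)
    dangling = [a.answer_id for a in registry.answers if a.category_id not in cat_ids]
    ans_ids = {a.answer_id for a in registry.answers}
    dangling += [q.question_id for q in registry.questions if q.answer_id not in ans_ids]
    if dangling:
        violations.append(
            Violation("dangling-reference", "orphan question or answer", tuple(sorted(dangling)))
        )

    q_per_answer: Counter[str] = Counter(q.answer_id for q in registry.questions)
    thin = sorted(
        a.answer_id
        for a in registry.answers
        if q_per_answer[a.answer_id] < MIN_QUESTIONS_PER_ANSWER
    )
    if thin:
        violations.append(
            Violation(
                "min-questions-per-answer",
                f"answers with fewer than {MIN_QUESTIONS_PER_ANSWER} questions",
                tuple(thin),
                severity="warning",
            )
        )

    rep_counts: Counter[str] = Counter(
        q.answer_id for q in registry.questions if q.is_representative
    )
    bad_rep = sorted(
        a.answer_id for a in registry.answers if rep_counts.get(a.answer_id, 0) != 1
    )
    if bad_rep:
        violations.append(
            Violation(
                "representative-count",
                "each answer needs exactly one representative question",
                tuple(bad_rep),
            )
        )

    ans_by_cat: Counter[str] = Counter(a.category_id for a in registry.answers)
    answer_cat = {a.answer_id: a.category_id for a in registry.answers}
    q_by_cat: Counter[str] = Counter(
        answer_cat[q.answer_id] for q in registry.questions if q.answer_id in answer_cat
    )
    over_a = sorted(c for c, n in ans_by_cat.items() if n > MAX_ANSWERS_PER_CATEGORY)
    if over_a:
        violations.append(
            Violation(
                "max-answers-per-category",
                f"categories exceeding {MAX_ANSWERS_PER_CATEGORY} answers",
                tuple(over_a),
                severity="warning",
            )
        )
    over_q = sorted(c for c, n in q_by_cat.items() if n > MAX_QUESTIONS_PER_CATEGORY)
    if over_q:
        violations.append(
            Violation(
                "max-questions-per-category",
                f"categories exceeding {MAX_QUESTIONS_PER_CATEGORY} questions",
                tuple(over_q),
                severity="warning",
            )
        )
    return violations


# ---------------------------------------------------------------------------
# Training-set construction


def build_sorting_training_set(registry: QARegistry) -> list[TrainingPair]:
    """One pair per answer: the representative question's text, labelled
    with the answer's category (trains the upstream sorting tier)."""
    reps: dict[str, list[QuestionEntry]] = defaultdict(list)
    for q in registry.questions:
        if q.is_representative:
            reps[q.answer_id].append(q)
    answer_cat = {a.answer_id: a.category_id for a in registry.answers}
    pairs = []
    for a in registry.answers:
        chosen = reps.get(a.answer_id, [])
        if len(chosen) != 1:
            raise ValidationDataError(
                f"answer {a.answer_id!r} has {len(chosen)} representative "
                "questions (exactly one required)"
            )
        pairs.append(TrainingPair(chosen[0].text, answer_cat[a.answer_id]))
    return pairs


def build_category_training_set(
    registry: QARegistry, category_id: str
) -> list[TrainingPair]:
    """All questions (representative or not) of the category's answers,
    labelled with their answer_id (trains one downstream tier)."""
    if category_id not in set(registry.category_ids):
        raise UnknownCategoryError(category_id)
    member = {
        a.answer_id for a in registry.answers if a.category_id == category_id
    }
    return [
        TrainingPair(q.text, q.answer_id)
        for q in registry.questions
        if q.answer_id in member
    ]
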