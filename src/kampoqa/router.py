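"""Two-tier question answering: category sorting, then in-category lookup.

The deployed architecture splits the answer space across several downstream
classifiers because a single classifier could not hold the whole registry
(per-classifier quotas of 3,000 answers / 20,000 questions).  An upstream
*category-sorting* classifier — trained on one representative question per
answer, labelled with the answer's category — routes each incoming question
to one downstream *category* classifier, which ranks that category's answers
and applies the confidence threshold.  Rejection ("I do not have an answer")
is decided at the answer tier only; the top category is always taken (a
sorting-tier threshold exists but defaults to 0).

The routed category is reported even on rejection, so downstream error
analysis can distinguish sorting-tier from category-tier misclassification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import classifier as clf
from .classifier import ClassifierModel
from .errors import QueryError, TrainingError, UnknownCategoryError
from .normalize import Thesaurus, TokenizerSpec, load_thesaurus, normalize, save_thesaurus
from .registry import (
    QARegistry,
    build_category_training_set,
    build_sorting_training_set,
    load_registry,
    save_registry,
)

DEFAULT_THRESHOLD = 0.61  # the original system's ROC-selected operating point


@dataclass
class QASystem:
    registry: QARegistry
    thesaurus: Thesaurus
    tokenizer: TokenizerSpec
    sorting_model: ClassifierModel
    category_models: dict[str, ClassifierModel]
    threshold: float = DEFAULT_THRESHOLD
    sorting_threshold: float = 0.0


@dataclass(frozen=True)
class SystemResponse:
    """End-to-end outcome for one query.

    ``kind`` is ``answered`` or ``no_answer``; the routed ``category_id`` and
    both tier confidences are always present, the answer fields only when
    answered.
    """

    kind: str
    answer_id: str | None
    answer_text: str | None
    category_id: str
    sorting_confidence: float
    answer_confidence: float
    threshold_used: float

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "answer_id": self.answer_id,
            "answer_text": self.answer_text,
            "category_id": self.category_id,
            "sorting_confidence": self.sorting_confidence,
            "answer_confidence": self.answer_confidence,
            "threshold": self.threshold_used,
        }


def _fingerprint(thesaurus: Thesaurus, tokenizer: TokenizerSpec) -> dict:
    digest = hashlib.sha256()
    for keyword in sorted(thesaurus.entries):
        digest.update(keyword.encode("utf-8"))
        for synonym in sorted(thesaurus.entries[keyword]):
            digest.update(b"\x00" + synonym.encode("utf-8"))
    return {
        "thesaurus_sha256": digest.hexdigest(),
        "tokenizer": tokenizer.name,
    }


def build_system(
    registry: QARegistry,
    thesaurus: Thesaurus,
    tokenizer: TokenizerSpec = TokenizerSpec(),
    threshold: float = DEFAULT_THRESHOLD,
    sorting_threshold: float = 0.0,
) -> QASystem:
    """Train the sorting tier and one classifier per category.

    Training texts are normalized with the same thesaurus/tokenizer used at
    query time, so a query and its registered phrasing land on identical
    vectors.  Deterministic: rebuilding from the same inputs yields
    byte-identical serialized models.
    """
    meta = _fingerprint(thesaurus, tokenizer)

    def _norm_pairs(pairs):
        return [
            type(p)(normalize(p.text, thesaurus, tokenizer), p.label) for p in pairs
        ]

    sorting_model = clf.train(
        _norm_pairs(build_sorting_training_set(registry)), tokenizer, meta
    )
    category_models: dict[str, ClassifierModel] = {}
    for category_id in registry.category_ids:
        pairs = _norm_pairs(build_category_training_set(registry, category_id))
        if not pairs:
            raise TrainingError(
                f"category {category_id!r} has no questions to train on"
            )
        category_models[category_id] = clf.train(pairs, tokenizer, meta)
    return QASystem(
        registry=registry,
        thesaurus=thesaurus,
        tokenizer=tokenizer,
        sorting_model=sorting_model,
        category_models=category_models,
        threshold=threshold,
        sorting_threshold=sorting_threshold,
    )


def _answer_tier(
    system: QASystem,
    category_id: str,
    normalized_text: str,
    sorting_confidence: float,
    threshold: float,
) -> SystemResponse:
    result = clf.classify(system.category_models[category_id], normalized_text)
    decision = clf.apply_threshold(result, threshold)
    if decision.kind == "answered":
        answer = system.registry.answer(decision.label)
        return SystemResponse(
            kind="answered",
            answer_id=answer.answer_id,
            answer_text=answer.answer_text,
            category_id=category_id,
            sorting_confidence=sorting_confidence,
            answer_confidence=decision.top_confidence,
            threshold_used=threshold,
        )
    return SystemResponse(
        kind="no_answer",
        answer_id=None,
        answer_text=None,
        category_id=category_id,
        sorting_confidence=sorting_confidence,
        answer_confidence=decision.top_confidence,
        threshold_used=threshold,
    )


def ask(system: QASystem, raw_text: str, threshold: float | None = None) -> SystemResponse:
    """Answer a free-text question end to end.

    Pipeline: normalize -> sorting classify (take the top category) ->
    category classify -> threshold decision.  ``threshold`` overrides the
    system default for this call (used by evaluation sweeps).
    """
    if not raw_text.strip():
        raise QueryError("empty question")
    t = system.threshold if threshold is None else threshold
    normalized = normalize(raw_text, system.thesaurus, system.tokenizer)
    sorting = clf.classify(system.sorting_model, normalized)
    category_id, sorting_confidence = sorting.top
    if sorting_confidence < system.sorting_threshold:
        return SystemResponse(
            kind="no_answer",
            answer_id=None,
            answer_text=None,
            category_id=category_id,
            sorting_confidence=sorting_confidence,
            answer_confidence=0.0,
            threshold_used=t,
        )
    return _answer_tier(system, category_id, normalized, sorting_confidence, t)


def ask_category(
    system: QASystem,
    category_id: str,
    raw_text: str,
    threshold: float | None = None,
) -> SystemResponse:
    """Answer within a caller-chosen category, skipping the sorting tier
    (the API replacement for the original interface's category buttons).
    ``sorting_confidence`` is reported as 1.0 by convention."""
    if not raw_text.strip():
        raise QueryError("empty question")
    if category_id not in system.category_models:
        raise UnknownCategoryError(category_id)
    t = system.threshold if threshold is None else threshold
    normalized = normalize(raw_text, system.thesaurus, system.tokenizer)
    return _answer_tier(system, category_id, normalized, 1.0, t)


# ---------------------------------------------------------------------------
# Bundle persistence


def save_system(system: QASystem, path: str | Path) -> None:
    """Write a system bundle: registry TSVs, thesaurus, per-tier models and
    a config file with threshold/tokenizer/fingerprints."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_registry(system.registry, path / "registry", format="tsv")
    save_thesaurus(system.thesaurus, path / "thesaurus.tsv")
    models = path / "models"
    models.mkdir(exist_ok=True)
    system.sorting_model.save(models / "sorting.json")
    for category_id, model in system.category_models.items():
        model.save(models / f"{category_id}.json")
    config = {
        "threshold": system.threshold,
        "sorting_threshold": system.sorting_threshold,
        "tokenizer": {
            "name": system.tokenizer.name,
            "options": list(system.tokenizer.options),
        },
        "fingerprints": _fingerprint(system.thesaurus, system.tokenizer),
    }
    (path / "config.json").write_text(
        json.dumps(config, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_system(path: str | Path) -> QASystem:
    path = Path(path)
    config = json.loads((path / "config.json").read_text(encoding="utf-8"))
    registry = load_registry(path / "registry", format="tsv")
    thesaurus = load_thesaurus(path / "thesaurus.tsv")
    tokenizer = TokenizerSpec(
        config["tokenizer"]["name"], tuple(config["tokenizer"]["options"])
    )
    sorting_model = ClassifierModel.load(path / "models" / "sorting.json")
    category_models = {
        cid: ClassifierModel.load(path / "models" / f"{cid}.json")
        for cid in registry.category_ids
    }
    return QASystem(
        registry=registry,
        thesaurus=thesaurus,
        tokenizer=tokenizer,
        sorting_model=sorting_model,
        category_models=category_models,
        threshold=float(config["threshold"]),
        sorting_threshold=float(config.get("sorting_threshold", 0.0)),
    )
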