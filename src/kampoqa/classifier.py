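"""Vector-space intent classifier with confidence rates and rejection.

This is the open, fully specified stand-in for the proprietary classifier
behind the original system, whose confidence computation is not disclosed.
The mechanism here is deliberately simple and closed-form so every
downstream number is reproducible and oracle-checkable:

* each training text becomes a tf-idf vector (natural term frequency,
  smoothed logarithmic idf ``ln((1+N)/(1+df)) + 1``), L2-normalized;
* a query is embedded in the same space and scored against every training
  text by cosine similarity;
* the score of a label is the *maximum* similarity over its training texts
  (nearest-neighbour semantics: one well-matching registered question
  suffices);
* confidence rates are the per-label scores divided by their sum, so they
  total 1 across all candidate labels — mirroring the original system's
  contract that candidate confidences sum to 100%.  If every score is zero
  (the query shares no vocabulary with the training set) confidences are
  uniform over labels, so the top confidence is 1/n_labels and any realistic
  threshold rejects the query.

Because confidence mass is shared across *all* labels, absolute confidence
values shrink as the label set grows; operating thresholds therefore have to
be calibrated per system (see the ROC utilities in :mod:`kampoqa.evaluation`)
rather than carried over between systems of different sizes.

There is no randomness anywhere; ties are broken by ascending label ID.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .errors import ParameterError, QueryError, TrainingError
from .normalize import TokenizerSpec, tokenize
from .registry import TrainingPair

DEFAULT_TOP_K = 10


def _terms(text: str, spec: TokenizerSpec) -> list[str]:
    return [t.casefold() for t in tokenize(text, spec).tokens]


@dataclass
class ClassifierModel:
    """A trained vector-space model.

    ``matrix`` holds one L2-normalized tf-idf row per training pair (order =
    training order); ``pair_labels[i]`` is the label of row ``i``.
    """

    labels: tuple[str, ...]
    vocabulary: dict[str, int]
    idf: np.ndarray
    matrix: sparse.csr_matrix
    pair_labels: tuple[str, ...]
    tokenizer: TokenizerSpec = TokenizerSpec()
    metadata: dict = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    # -- serialization (single JSON file, bit-exact round trip) ------------
    def to_dict(self) -> dict:
        coo = self.matrix.tocoo()
        rows: list[list] = [[] for _ in range(self.matrix.shape[0])]
        for r, c, v in zip(coo.row, coo.col, coo.data):
            rows[int(r)].append([int(c), float(v)])
        for row in rows:
            row.sort()
        return {
            "labels": list(self.labels),
            "vocabulary": self.vocabulary,
            "idf": [float(x) for x in self.idf],
            "rows": rows,
            "pair_labels": list(self.pair_labels),
            "tokenizer": {"name": self.tokenizer.name, "options": list(self.tokenizer.options)},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClassifierModel":
        n_terms = len(data["vocabulary"])
        indptr, indices, values = [0], [], []
        for row in data["rows"]:
            for c, v in row:
                indices.append(c)
                values.append(v)
            indptr.append(len(indices))
        matrix = sparse.csr_matrix(
            (np.array(values, dtype=float), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
            shape=(len(data["rows"]), n_terms),
        )
        return cls(
            labels=tuple(data["labels"]),
            vocabulary=dict(data["vocabulary"]),
            idf=np.array(data["idf"], dtype=float),
            matrix=matrix,
            pair_labels=tuple(data["pair_labels"]),
            tokenizer=TokenizerSpec(
                data["tokenizer"]["name"], tuple(data["tokenizer"]["options"])
            ),
            metadata=dict(data.get("metadata", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), ensure_ascii=False, sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ClassificationResult:
    """Ranked candidate labels with confidence rates.

    ``candidates`` is descending by confidence (ties: ascending label) and
    may be truncated to a top-k; the confidences carried are the untruncated
    ones, normalized over *all* labels, so the full distribution sums to 1.
    """

    candidates: tuple[tuple[str, float], ...]
    query_text: str
    n_labels: int

    @property
    def top(self) -> tuple[str, float]:
        return self.candidates[0]


@dataclass(frozen=True)
class Decision:
    """Outcome of comparing the top confidence against a threshold."""

    kind: str  # "answered" | "no_answer"
    label: str | None
    top_confidence: float
    threshold: float


def train(
    pairs: Sequence[TrainingPair],
    tokenizer: TokenizerSpec = TokenizerSpec(),
    metadata: dict | None = None,
) -> ClassifierModel:
    """Fit the tf-idf space and per-pair vectors.

    Deterministic given identical pair ordering.  Raises
    :class:`TrainingError` on an empty training set or empty texts.
    """
    if not pairs:
        raise TrainingError("cannot train on an empty collection of pairs")
    for p in pairs:
        if not p.text.strip() or not p.label:
            raise TrainingError("training pairs must have non-empty text and label")

    docs = [_terms(p.text, tokenizer) for p in pairs]
    vocab: dict[str, int] = {}
    for term in sorted({t for doc in docs for t in doc}):
        vocab[term] = len(vocab)
    n_docs = len(docs)
    df = np.zeros(len(vocab), dtype=float)
    for doc in docs:
        for term in set(doc):
            df[vocab[term]] += 1
    idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0

    indptr, indices, values = [0], [], []
    for doc in docs:
        counts: dict[int, float] = {}
        for term in doc:
            j = vocab[term]
            counts[j] = counts.get(j, 0.0) + 1.0
        items = sorted(counts.items())
        row = np.array([tf * idf[j] for j, tf in items], dtype=float)
        norm = np.linalg.norm(row)
        if norm > 0:
            row /= norm
        indices.extend(j for j, _ in items)
        values.extend(row.tolist())
        indptr.append(len(indices))
    matrix = sparse.csr_matrix(
        (np.array(values, dtype=float), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
        shape=(n_docs, len(vocab)),
    )
    labels = tuple(sorted({p.label for p in pairs}))
    return ClassifierModel(
        labels=labels,
        vocabulary=vocab,
        idf=idf,
        matrix=matrix,
        pair_labels=tuple(p.label for p in pairs),
        tokenizer=tokenizer,
        metadata=dict(metadata or {}),
    )


def classify(
    model: ClassifierModel, text: str, top_k: int | None = DEFAULT_TOP_K
) -> ClassificationResult:
    """Score ``text`` against the model and return ranked candidates.

    ``text`` is expected to be already normalized (the router applies the
    thesaurus before calling in).  ``top_k=None`` returns every label with
    nonzero confidence.
    """
    if not text.strip():
        raise QueryError("cannot classify empty text")
    counts: dict[int, float] = {}
    for term in _terms(text, model.tokenizer):
        j = model.vocabulary.get(term)
        if j is not None:
            counts[j] = counts.get(j, 0.0) + 1.0

    label_index = {lab: i for i, lab in enumerate(model.labels)}
    scores = np.zeros(len(model.labels), dtype=float)
    if counts:
        q = np.zeros(len(model.vocabulary), dtype=float)
        for j, tf in counts.items():
            q[j] = tf * model.idf[j]
        norm = np.linalg.norm(q)
        if norm > 0:
            q /= norm
        sims = model.matrix @ q  # cosine: rows are L2-normalized
        row_to_label = np.fromiter(
            (label_index[lab] for lab in model.pair_labels),
            dtype=np.int64,
            count=len(model.pair_labels),
        )
        np.maximum.at(scores, row_to_label, sims)

    total = float(scores.sum())
    if total <= 0.0:
        conf = np.full(len(model.labels), 1.0 / len(model.labels))
    else:
        conf = scores / total
    order = sorted(range(len(model.labels)), key=lambda i: (-conf[i], model.labels[i]))
    if total > 0.0:
        order = [i for i in order if conf[i] > 0.0]
    if top_k is not None:
        order = order[:top_k]
    candidates = tuple((model.labels[i], float(conf[i])) for i in order)
    return ClassificationResult(
        candidates=candidates, query_text=text, n_labels=len(model.labels)
    )


def apply_threshold(result: ClassificationResult, threshold: float) -> Decision:
    """Answer with the top label iff its confidence reaches ``threshold``,
    otherwise reject with "I do not have an answer"."""
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    label, confidence = result.top
    if confidence >= threshold:
        return Decision("answered", label, confidence, threshold)
    return Decision("no_answer", None, confidence, threshold)
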