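import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kampoqa.classifier import (
    ClassifierModel,
    apply_threshold,
    classify,
    train,
)
from kampoqa.errors import ParameterError, QueryError, TrainingError
from kampoqa.registry import TrainingPair

TOY = [
    TrainingPair("fever and chills after kakkonto", "A"),
    TrainingPair("fever lasting days", "A"),
    TrainingPair("rash on the arms", "B"),
    TrainingPair("itchy rash spreading", "B"),
    TrainingPair("dizziness when standing", "C"),
]


def _oracle_confidences(pairs, query):
    """Brute-force tf-idf/cosine/max-per-label oracle in plain dicts."""
    docs = [p.text.casefold().split() for p in pairs]
    vocab = sorted({t for d in docs for t in d})
    n = len(docs)
    idf = {
        t: math.log((1 + n) / (1 + sum(t in set(d) for d in docs))) + 1 for t in vocab
    }

    def vec(tokens):
        v = {}
        for t in tokens:
            if t in idf:
                v[t] = v.get(t, 0.0) + 1.0
        v = {t: c * idf[t] for t, c in v.items()}
        norm = math.sqrt(sum(x * x for x in v.values()))
        return {t: x / norm for t, x in v.items()} if norm else v

    q = vec(query.casefold().split())
    scores = {}
    for p, d in zip(pairs, docs):
        dv = vec(d)
        sim = sum(q.get(t, 0.0) * w for t, w in dv.items())
        scores[p.label] = max(scores.get(p.label, 0.0), sim)
    total = sum(scores.values())
    if total == 0:
        return {lab: 1 / len(scores) for lab in scores}
    return {lab: s / total for lab, s in scores.items()}


@pytest.mark.parametrize(
    "query",
    ["fever and rash", "dizziness", "rash rash fever", "kakkonto", "nothing known"],
)
def test_confidences_match_brute_force_oracle(query):
    model = train(TOY)
    result = classify(model, query, top_k=None)
    expected = _oracle_confidences(TOY, query)
    got = dict(result.candidates)
    for label, conf in expected.items():
        if conf > 0:
            assert got[label] == pytest.approx(conf, abs=1e-9)


def test_confidences_match_scikit_learn_tfidf_cosine():
    sklearn = pytest.importorskip("sklearn")
    from sklearn.feature_extraction.text import TfidfVectorizer
    from sklearn.metrics.pairwise import cosine_similarity

    vec = TfidfVectorizer(analyzer=lambda s: s.casefold().split(), norm="l2")
    X = vec.fit_transform([p.text for p in TOY])
    model = train(TOY)
    query = "fever and rash after kakkonto"
    q = vec.transform([query])
    sims = cosine_similarity(q, X)[0]
    scores = {}
    for p, s in zip(TOY, sims):
        scores[p.label] = max(scores.get(p.label, 0.0), s)
    expected = {lab: s / sum(scores.values()) for lab, s in scores.items()}
    got = dict(classify(model, query, top_k=None).candidates)
    for label, conf in expected.items():
        if conf > 0:
            assert got[label] == pytest.approx(conf, abs=1e-9)


def test_single_label_model_is_certain():
    model = train([TrainingPair("only one thing", "L")] * 3)
    assert model.n_labels == 1
    result = classify(model, "anything at all related to one thing")
    assert result.candidates == (("L", 1.0),)


def test_verbatim_training_text_ranks_its_label_first():
    model = train(TOY)
    for p in TOY:
        assert classify(model, p.text).top[0] == p.label


def test_out_of_vocabulary_query_gets_uniform_confidences():
    model = train(TOY)
    result = classify(model, "zzz qqq www", top_k=None)
    assert len(result.candidates) == 3
    assert all(c == pytest.approx(1 / 3) for _, c in result.candidates)


def test_duplicate_training_pairs_do_not_change_classification():
    model = train(TOY)
    model_dup = train(TOY + TOY[:3])
    for query in ("fever", "rash on arms", "unrelated words"):
        assert (
            classify(model, query, top_k=None).candidates
            == classify(model_dup, query, top_k=None).candidates
        )


@given(
    corpus=st.lists(
        st.tuples(
            st.lists(
                st.sampled_from("alpha beta gamma delta epsilon zeta".split()),
                min_size=1,
                max_size=6,
            ),
            st.sampled_from(["L1", "L2", "L3", "L4"]),
        ),
        min_size=1,
        max_size=15,
    ),
    query=st.lists(
        st.sampled_from("alpha beta gamma unknown other".split()),
        min_size=1,
        max_size=6,
    ),
)
@settings(max_examples=250, deadline=None)
def test_confidences_always_sum_to_one(corpus, query):
    pairs = [TrainingPair(" ".join(tokens), label) for tokens, label in corpus]
    model = train(pairs)
    result = classify(model, " ".join(query), top_k=None)
    assert sum(c for _, c in result.candidates) == pytest.approx(1.0, abs=1e-9)
    confs = [c for _, c in result.candidates]
    assert confs == sorted(confs, reverse=True)


def test_candidate_cap_keeps_untruncated_confidences():
    pairs = [TrainingPair(f"shared word{i}", f"L{i:02d}") for i in range(15)]
    model = train(pairs)
    capped = classify(model, "shared", top_k=10)
    full = dict(classify(model, "shared", top_k=None).candidates)
    assert len(capped.candidates) == 10
    for label, conf in capped.candidates:
        assert conf == full[label]


def test_tie_break_is_ascending_label_id():
    pairs = [
        TrainingPair("same text", "B"),
        TrainingPair("same text", "A"),
        TrainingPair("other words entirely", "C"),
    ]
    result = classify(train(pairs), "same text", top_k=None)
    assert [lab for lab, _ in result.candidates[:2]] == ["A", "B"]


def test_threshold_decision_semantics():
    # the decisive comparisons behind "answer vs I-do-not-have-an-answer"
    from kampoqa.classifier import ClassificationResult

    r_low = ClassificationResult((("X", 0.456), ("Y", 0.244)), "q", 2)
    r_high = ClassificationResult((("X", 0.952), ("Y", 0.048)), "q", 2)
    assert apply_threshold(r_low, 0.61).kind == "no_answer"
    assert apply_threshold(r_low, 0.61).top_confidence == 0.456
    assert apply_threshold(r_high, 0.61).kind == "answered"
    assert apply_threshold(r_high, 0.61).label == "X"
    assert apply_threshold(r_low, 0.0).kind == "answered"
    with pytest.raises(ParameterError):
        apply_threshold(r_low, 1.5)


def test_raising_threshold_never_resurrects_an_answer():
    from kampoqa.classifier import ClassificationResult

    result = ClassificationResult((("X", 0.6), ("Y", 0.4)), "q", 2)
    kinds = [apply_threshold(result, t / 20).kind for t in range(21)]
    # once no_answer, always no_answer as the threshold rises
    first_reject = kinds.index("no_answer")
    assert all(kind == "no_answer" for kind in kinds[first_reject:])


def test_training_is_deterministic_and_serialization_roundtrips(tmp_path):
    m1, m2 = train(TOY), train(TOY)
    p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
    m1.save(p1)
    m2.save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    loaded = ClassifierModel.load(p1)
    loaded.save(tmp_path / "m3.json")
    assert (tmp_path / "m3.json").read_bytes() == p1.read_bytes()
    for query in ("fever", "rash", "zzz"):
        assert (
            classify(loaded, query, top_k=None).candidates
            == classify(m1, query, top_k=None).candidates
        )


def test_training_and_query_errors():
    with pytest.raises(TrainingError):
        train([])
    with pytest.raises(TrainingError):
        train([TrainingPair("  ", "L")])
    model = train(TOY)
    with pytest.raises(QueryError):
        classify(model, "   ")
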