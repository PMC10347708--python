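# kampoqa

An open, testable re-implementation of a hierarchical closed-domain
question-answering architecture for drug information (the original system
served Kampo — Japanese traditional herbal — medicines to pharmacists), with
the open-set evaluation methodology that goes with it.

A user types a free-text question.  The system:

1. **normalizes** it — tokenization plus thesaurus conversion, replacing
   colloquial synonym surface forms with canonical keywords;
2. **routes** it with a *category-sorting classifier* trained on one
   representative question per answer, choosing one of six category tiers;
3. **ranks** the chosen category's answers with a *category classifier*
   trained on every registered question phrasing, producing candidate
   answers with confidence rates that sum to 1;
4. **rejects** — answers "I do not have an answer" — whenever the top
   confidence falls below an operating threshold calibrated from a ROC
   curve.

The original deployment used a proprietary cloud classifier whose
confidence computation is undisclosed.  This package substitutes a fully
specified vector-space mechanism — tf-idf vectors, cosine similarity,
per-label max over training texts, sum-normalized confidences — so that
every downstream number is reproducible and checkable against brute-force
oracles.

Evaluation treats the rejection option as first class.  For a validation
question that *has* an answer in the system, a correct answer is a TP and
anything else (wrong answer or rejection) an FN; for a question with *no*
answer in the system, an answer is an FP and a rejection a TN.  Then

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F = 2PR / (P + R)                 correct rate = 100 (TP + TN) / total

and the operating threshold maximizes the Youden index
`sensitivity − (1 − specificity)` over a threshold grid, with
`sensitivity = TP/answerable` and `specificity = TN/unanswerable`.

Because the real registry (2,587 curated answers, 21,786 question
phrasings, a 369-keyword/1,429-synonym thesaurus) is private, the package
ships a deterministic synthetic-corpus generator that reproduces its
statistical shape — category structure, per-answer question-count
distribution (min 3, median 7), three question archetypes, thesaurus scale,
paraphrased validation questions with answerable/unanswerable strata — so
the whole pipeline is exercised end to end at full scale with no external
data.

## Worked example

```
$ kampoqa synth --seed 42 --separable --out bundle
wrote bundle: 50 answers, 353 questions, 120 validation questions -> bundle

$ kampoqa train --bundle bundle --threshold 0.0 --out system
trained sorting tier (6 categories) and 6 category models -> system

$ kampoqa calibrate --system system --validation bundle/validation.tsv --out calib
selected threshold: 0.12

$ kampoqa eval --system system --validation bundle/validation.tsv --threshold auto
threshold 0.12  TP 96  FN 0  FP 0  TN 24
precision 1.000  recall 1.000  F 1.000  correct rate 100.0%
  [advanced] precision 1.000 recall 1.000 F 1.000
  [basic] precision 1.000 recall 1.000 F 1.000
  [student] precision 1.000 recall 1.000 F 1.000
```

The `--separable` bundle plants a confidence gap: answerable validation
questions are verbatim registered phrasings while unanswerable ones use
vocabulary the registry has never seen.  Calibration recovers a threshold
inside that gap (0.12 here — above the uniform-confidence floor that
out-of-vocabulary queries receive, below every correct answer's
confidence), so evaluation at the selected threshold is perfect: all 96
answerable questions answered correctly, all 24 unanswerable ones rejected,
for every author-expertise stratum.

Asking questions directly:

```
$ kampoqa ask --system system --threshold 0.12 "is kawasan suitable when kolvor occurs regarding juntab"
{
 "kind": "answered",
 "answer_id": "A00001",
 "answer_text": "registered guidance on dosvorhul for kawasan",
 "category_id": "C1",
 "sorting_confidence": 0.4281792319094308,
 "answer_confidence": 0.20938076598883082,
 "threshold": 0.12
}

$ kampoqa ask --system system --threshold 0.12 "totally unrelated gibberish"
{
 "kind": "no_answer",
 "answer_id": null,
 ...
 "answer_confidence": 0.1111111111111111,
 "threshold": 0.12
}
```

A query sharing no vocabulary with the registry gets uniform confidences
(here 1/9 in the routed nine-answer category), which falls below any
calibrated threshold — rejection emerges from the confidence contract
rather than from a special code path.  The routed `category_id` is reported
even on rejection, so sorting-tier and category-tier errors can be told
apart downstream.

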