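# Methods

## The architecture

The system answers closed-domain drug-information questions by intent
classification: every answer in a curated registry carries several
registered question phrasings, and an incoming question is matched to the
most similar registered phrasing, whose answer is returned.  Two structural
features distinguish it from a flat nearest-neighbour lookup:

1. **Two tiers.**  The registry is partitioned into categories (default
   six, mirroring the original deployment: four package-insert categories,
   one for the serious-adverse-reaction manuals, one for cross-drug
   questions).  An upstream *category-sorting* classifier — trained on one
   representative question per answer, labelled with the answer's category
   — picks a category; the query is then re-classified inside that
   category's own classifier over its answers.  The split originates in
   per-classifier quotas of the original cloud service (3,000 answers /
   20,000 questions per classifier), which the registry validator preserves
   as warnings.  The sorting tier takes its top category unconditionally by
   default (`router.sorting_threshold = 0`); rejection happens at the
   answer tier only, matching the single-rejection-outcome accounting of
   the evaluation scheme.

2. **Thesaurus normalization.**  Before any classification — and,
   symmetrically, before training — synonym surface forms are replaced by
   canonical keywords.  Matching is token-boundary aligned,
   longest-match-first, left to right, in one pass, case-insensitive for
   cased scripts.  A loaded thesaurus must satisfy two invariants: no
   synonym belongs to two keywords, and no keyword appears as a synonym of
   another (no conversion chains).  Together with the single pass these
   guarantee termination and idempotence; a violating thesaurus is refused
   at load time rather than silently producing unstable normalization.
   With the character tokenizer the matcher degenerates to plain substring
   replacement, which is the correct behaviour for unsegmented Japanese; a
   MeCab-style analyzer can be plugged in where installed.

## The confidence mechanism

The original classifier's confidence computation is proprietary; the only
published contract is that candidate confidences sum to 100% and reflect
similarity to registered questions.  This package's substitute is fixed and
deliberately simple:

* terms are casefolded tokens; document frequency is computed over the
  training texts of the classifier at hand;
* `idf(t) = ln((1 + N)/(1 + df(t))) + 1` (smoothed logarithmic idf),
  natural term frequency, L2-normalized vectors;
* similarity is cosine; a label's score is the **maximum** similarity over
  its training texts (one well-matching registered phrasing suffices);
* confidences are the scores divided by their sum over all labels; if every
  score is zero the distribution is uniform, so the top confidence is
  `1/n_labels` and any calibrated threshold rejects the query — the
  "I do not have an answer" behaviour needs no special case.

Ties are broken by ascending label ID; there is no randomness anywhere, and
models serialize to JSON with bit-exact round trips.

One consequence deserves emphasis: because confidence mass is shared across
*all* labels of a classifier, absolute confidences shrink as the label set
grows.  A category holding ~430 answers yields top confidences of order
10⁻², far below the 61% operating point of the original system, whose
proprietary scores were evidently much more concentrated.  Operating
thresholds therefore must be calibrated per system.  The evaluation module
keeps the percent grid (0.00–1.00, step 0.01) as its default, matching the
original report's resolution, and provides `quantile_grid` — thresholds at
the observed confidence quantiles — for systems whose confidence mass sits
below 0.01.  Decision *semantics* around any given confidence are
unaffected; the published per-question confidences themselves are not
reproducible and are not claimed.

## Evaluation

Judgment is four-way and open-set: TP (answerable, correct answer), FN
(answerable, wrong answer **or** rejection), FP (unanswerable, answered),
TN (unanswerable, rejected).  Precision, recall, F (harmonic mean) and the
correct rate `100·(TP+TN)/total` follow; printed values are rounded to 3
decimals (percentages to 1), with unrounded twins retained in
machine-readable output.  Undefined quotients are reported as NaN with a
warning, never silently zero.

The ROC sweep re-derives decisions from threshold-0 responses at each grid
value, so classifiers run once per question regardless of grid size.
Sensitivity is `TP/answerable` and specificity `TN/unanswerable` — the
positive event is *answerable and correctly answered*, the only reading
consistent with the four-way judgment and with the observation that raising
the threshold converts FPs to TNs.  The Youden-maximizing threshold is
selected, ties going to the smallest.  Selecting the threshold on the same
set that is reported on reproduces the original procedure; reports made
that way carry a `calibrated_in_sample` flag.

## The synthetic corpus

The real registry is private, so the generator emulates its statistics, not
its content.  Language is templated pseudo-text over a controlled
vocabulary: the properties under test are vocabulary-overlap structure and
label geometry, not linguistic realism.

* **Scale defaults** are the real registry's: 6 categories, 2,587 answers
  over 33 drugs, a 369-keyword/1,429-synonym thesaurus, 900 validation
  questions.  `CorpusParams.small()` shrinks everything (~50 answers) for
  fast tests without changing the shape.
* **Answers** are (drug, section) pairs.  Only 80% of each category's
  drug × section grid carries answers; the unused combinations supply
  *in-vocabulary* unanswerable validation questions, so rejection must come
  from the confidence mechanism, not out-of-vocabulary detection — the hard
  false-positive regime of the original validation.
* **Questions per answer** follow `3 + min(Geometric(p), 162)` with
  `p = 0.1558`, drawn by inverse transform from a per-answer latent so that
  "indication breadth" correlates monotonically with question count.  `p`
  is pinned by the published order statistics: the median lands on 7 and
  the implied mean (~8.42) reproduces the published totals
  (21,786 questions / 2,587 answers).  The published maximum (165) is
  respected as a clamp; a unimodal distribution with this median and mean
  cannot also make 165 a typical extreme order statistic, so the observed
  maximum in generated registries is smaller (~50).
* **Three archetypes** phrase each question: naming the section directly;
  paraphrasing it through symptom words associated with the section; and
  cross-drug phrasings.  Each answer's first-listed question is its
  *representative* — a dense canonical phrasing covering the answer's whole
  content vocabulary (section, drug, symptoms, category phrasing).  Since
  representatives are the sorting tier's entire training set, they must
  carry every content word a query might lead with; curated registries
  achieve this through human selection, the generator by construction.
* **Category phrasing words.**  Real information-type categories are asked
  about in characteristically different wording (usage vs interactions vs
  adverse-reaction management).  Each synthetic category gets two
  characteristic words, one of which every question carries; this is what
  makes category vocabularies separable.  Paraphrase dropout can remove
  them, which is the generator's mechanism for sorting-tier misrouting.
* **Thesaurus** keywords are symptom/section words; synonyms are suffix
  surface variants, planted into ~20% of registered questions so
  normalization has real work at both training and query time.
* **Validation questions**: answerable ones paraphrase registered questions
  — per-token dropout with probability `noise/2`, synonym substitution with
  probability `noise/2`, whole-archetype switching with probability
  `noise/2` — at three noise strata (0.7×, 1.0×, 1.3× the base noise,
  default 0.3) labelled advanced/basic/student, mimicking author-expertise
  variation.  Distinct targets cover `answer_coverage` of the registry's
  answers (default 0.34; the published 34.7% coverage by 900 questions is
  infeasible to the letter once the answerable/unanswerable split is
  honoured, since ~880 answerable questions cannot cover 898 distinct
  answers).  The default unanswerable fraction is 0.022, back-derived from
  the published confusion percentages (TP 89.4% of 900 with recall 0.915
  implies ~880 answerable questions).
* **`CorpusParams.separable()`** plants a clean confidence gap: noise-free
  answerable questions against fully vocabulary-disjoint unanswerable ones.
  This is the regime for calibration-recovery and monotonicity studies,
  where threshold selection has a right answer (any value in the gap) and
  F = 1 is attainable.

Everything is reproducible from the seed (NumPy PCG64 streams; registry,
thesaurus and validation derive from independent sub-streams).

## What passing tests do and do not show

The synthetic corpus shares the real registry's *structure*, not its
semantics: templated questions have far less expression diversity than
human ones, synonymy is suffix-regular rather than colloquial, and
answer texts are stubs.  Tests therefore demonstrate that the pipeline's
mechanics — normalization idempotence, confidence contract, routing
restriction, judgment truth table, ROC/threshold arithmetic, determinism —
are correct, and that the architecture behaves qualitatively as reported
(precision rises and recall falls with the threshold; misrouted questions
are recoverable by forcing the category).  They do not show that the
substitute classifier reaches the published headline accuracy on real
Japanese pharmaceutical questions; at full synthetic scale with default
noise it reaches perfect precision at roughly half recall, reflecting the
dilution of sum-normalized tf-idf confidences over hundreds of labels.

## Numerical choices and degenerate inputs

* Confidence sum contract verified to 1e-9; metric formula oracles to
  1e-12 before rounding.
* Empty training sets, empty queries, thresholds outside [0,1], missing
  strata in ROC input, and chain-violating thesauri raise typed errors.
* Registries lacking representative flags auto-flag the first-listed
  question per answer, with a warning (the original selection rule is
  unrecorded; first-listed is a documented stand-in, not an inference).
* Quota-style registry limits (3 questions minimum per answer; 3,000
  answers / 20,000 questions per category) are warnings by default, fatal
  under `--strict`.
* Problem sizes in the shipped tests: desk-scale bundles of 50 answers /
  ~350 questions / 120 validation questions for behavioural tests, one
  full-scale run (2,587 answers, ~21.5k questions, 900 validation
  questions) exercising generation, validation, training, calibration and
  evaluation end to end.
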