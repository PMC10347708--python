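"""Deterministic synthetic corpora with the structure of the real registry.

The original knowledge base (Kampo drug-information answers, their
registered question phrasings, and a synonym thesaurus) is private, so this
module generates stand-in corpora that reproduce its *statistical* shape:

* six categories; 2,587 answers; ~21,786 questions with per-answer counts of
  median 7 on a 3–165 range; a thesaurus of 369 keywords and 1,429 synonyms;
* answers are (drug, information-section) pairs, with drug names built from
  kana-style syllables and section/symptom terms from a separate latin-style
  syllable pool, so category vocabularies are distinguishable;
* three question archetypes: phrasings that name the section directly,
  phrasings that paraphrase it through associated symptom words, and
  cross-drug phrasings that ask about one section across formulas;
* synonyms are suffix variants of symptom/section keywords, planted into a
  controlled fraction of registered questions so thesaurus conversion has
  real work to do;
* validation questions are paraphrases of registered questions (word
  dropout, synonym substitution, archetype switching) plus *in-vocabulary*
  unanswerable questions built from drug-section combinations that exist in
  the vocabulary but have no registered answer — rejection has to come from
  the confidence mechanism, not from out-of-vocabulary detection.

The synthetic language is templated pseudo-text over a controlled
vocabulary: the test surface needs vocabulary-overlap structure, not
linguistic realism.  Everything is reproducible from ``CorpusParams.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .evaluation import ValidationQuestion
from .normalize import Thesaurus
from .registry import AnswerEntry, Category, QARegistry, QuestionEntry

# Fraction of the drug x section grid actually given answers; the remainder
# supplies in-vocabulary unanswerable combinations.
_GRID_FILL = 0.8

_DRUG_SYLLABLES = (
    "ka", "ki", "ku", "ke", "ko", "sa", "shi", "su", "se", "so",
    "ta", "chi", "to", "na", "ni", "no", "ha", "hi", "fu", "ma",
    "mi", "mu", "me", "mo", "ya", "yu", "yo", "ra", "ri", "ru",
    "re", "ro", "wa", "gan", "zo", "bu", "do", "ge", "jo", "en",
)
_DRUG_SUFFIXES = ("to", "san", "gan", "in")

_WORD_SYLLABLES = (
    "dos", "cur", "mal", "ven", "tor", "lex", "pan", "qui", "ros", "fen",
    "gal", "mir", "sol", "tab", "nex", "vor", "zel", "hap", "lum", "cer",
    "bri", "dax", "ern", "fol", "gri", "hul", "ixa", "jun", "kol", "lyr",
)
_SYNONYM_SUFFIXES = ("ly", "ish", "oid", "ance", "ive", "ous")

_DIRECT_TEMPLATES = (
    "i want to know the {s} of {d}",
    "tell me the {s} of {d}",
    "what is the {s} of {d}",
    "please show the {s} listed for {d}",
    "what does the {s} of {d} say",
)
_INDIRECT_TEMPLATES = (
    "can i use {d} for patients with {y}",
    "is {d} suitable when {y} occurs",
    "should {d} be given to someone with {y}",
    "my patient has {y} can they take {d}",
    "does {y} matter when prescribing {d}",
)
_CROSS_TEMPLATES = (
    "which formulas like {d} mention {s}",
    "does any formula such as {d} describe {s}",
    "across medications which like {d} cover {s}",
    "is {s} described for several formulas including {d}",
)
_ARCHETYPES = ("direct", "indirect", "cross")

_GROUPS = ("advanced", "basic", "student")
# Paraphrase-noise multipliers mimicking question-author expertise strata:
# experts phrase closer to the registered wording.
_GROUP_NOISE = {"advanced": 0.7, "basic": 1.0, "student": 1.3}


@dataclass(frozen=True)
class CorpusParams:
    """Generation parameters; defaults are the real registry's statistics.

    ``questions_per_answer`` gives (min, median, max) of the per-answer
    question-count distribution.  ``unanswerable_fraction`` and
    ``answer_coverage`` shape the validation set (defaults back-derived from
    the reported validation composition).  ``vocabulary_size`` = 0 lets the
    generator derive the content-word pools from the structure.
    """

    n_categories: int = 6
    n_answers_total: int = 2_587
    n_drugs: int = 33
    questions_per_answer: tuple[int, int, int] = (3, 7, 165)
    n_keywords: int = 369
    synonyms_total: int = 1_429
    vocabulary_size: int = 0
    paraphrase_noise: float = 0.3
    synonym_plant_rate: float = 0.2
    unanswerable_fraction: float = 0.022
    # True (default): unanswerable questions reuse registry vocabulary in
    # drug/section combinations with no answer — hard negatives whose
    # rejection must come from the confidence mechanism.  False: they use
    # entirely novel vocabulary, planting a clean confidence gap for
    # separability / calibration studies.
    unanswerable_in_vocabulary: bool = True
    answer_coverage: float = 0.34
    n_validation: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        qmin, qmed, qmax = self.questions_per_answer
        if not (0 < qmin <= qmed <= qmax):
            raise ParameterError("need 0 < min <= median <= max questions per answer")
        for name in ("n_categories", "n_answers_total", "n_drugs", "n_keywords",
                     "synonyms_total", "n_validation"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("paraphrase_noise", "synonym_plant_rate",
                     "unanswerable_fraction", "answer_coverage"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_answers_total < self.n_categories:
            raise ParameterError("need at least one answer per category")
        if self.synonyms_total > len(_SYNONYM_SUFFIXES) * self.n_keywords:
            raise ParameterError(
                "synonyms_total exceeds the available surface variants "
                f"({len(_SYNONYM_SUFFIXES)} per keyword)"
            )
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "CorpusParams":
        """Desk-scale parameters for fast tests (50 answers, 120 validation
        questions); statistical shape otherwise unchanged."""
        defaults = dict(
            n_answers_total=50,
            n_drugs=10,
            n_keywords=20,
            synonyms_total=60,
            n_validation=120,
            unanswerable_fraction=0.15,
            answer_coverage=0.5,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def separable(cls, seed: int = 0, **overrides) -> "CorpusParams":
        """Desk-scale bundle with a planted confidence gap: noise-free
        answerable questions (verbatim registered phrasings) against
        vocabulary-disjoint unanswerable ones."""
        defaults = dict(
            paraphrase_noise=0.0,
            unanswerable_in_vocabulary=False,
            unanswerable_fraction=0.2,
        )
        defaults.update(overrides)
        return cls.small(seed=seed, **defaults)


@dataclass(frozen=True)
class _AnswerSpec:
    answer_id: str
    category_id: str
    drug: str
    section: str
    symptoms: tuple[str, ...]
    source_section: str


@dataclass
class _World:
    """Deterministic vocabulary and answer layout shared by registry and
    validation generation."""

    categories: list[Category]
    drugs: list[str]
    answer_specs: list[_AnswerSpec]
    # (category_id, drug, section, symptoms) combos with no answer
    unused_pairs: list[tuple[str, str, str, tuple[str, ...]]]
    keywords: list[str]
    # per-category characteristic phrasing words: real information-type
    # categories (usage vs interactions vs adverse reactions) are asked
    # about in characteristically different wording; these words emulate
    # that and are what makes category vocabularies separable
    intents: dict[str, tuple[str, ...]]


def _geometric_p(qmin: int, qmed: int) -> float:
    """Success probability of the clamped-geometric question-count sampler.

    Chosen so the distribution's median lands on ``qmed``; the 0.09 offset
    centres the default (3, 7) case inside the admissible window, where the
    implied mean (~8.4 questions per answer) also matches the real
    registry's overall questions/answers ratio.
    """
    spread = qmed - qmin
    if spread == 0:
        return 1.0
    return 1.0 - 0.5 ** (1.0 / (spread + 0.09))


def sample_questions_per_answer(
    n: int, questions_per_answer: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    """Right-skewed integer counts clamped to [min, max] with the target
    median.  The uniform latent behind each draw doubles as the answer's
    "indication breadth": broader answers get monotonically more questions.
    """
    qmin, qmed, qmax = questions_per_answer
    p = _geometric_p(qmin, qmed)
    breadth = rng.random(n)
    if p >= 1.0:
        extra = np.zeros(n, dtype=int)
    else:
        extra = np.floor(np.log1p(-breadth) / math.log(1.0 - p)).astype(int)
    return qmin + np.minimum(extra, qmax - qmin)


def _unique_words(
    rng: np.random.Generator,
    n: int,
    syllables: Sequence[str],
    suffixes: Sequence[str] = (),
    taken: set[str] | None = None,
) -> list[str]:
    taken = taken if taken is not None else set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ParameterError("vocabulary pool exhausted; reduce counts")
        k = int(rng.integers(2, 4))
        word = "".join(syllables[int(i)] for i in rng.integers(0, len(syllables), size=k))
        if suffixes:
            word += suffixes[int(rng.integers(0, len(suffixes)))]
        if word not in taken:
            taken.add(word)
            out.append(word)
    return out


def _category_name(index: int, n_categories: int) -> tuple[str, str]:
    if n_categories == 6:
        names = (
            "package-insert-usage",
            "package-insert-safety",
            "package-insert-interactions",
            "package-insert-populations",
            "adverse-reaction-manuals",
            "cross-drug",
        )
        sources = (
            "package-insert", "package-insert", "package-insert",
            "package-insert", "manuals", "cross-drug",
        )
        return names[index], sources[index]
    return f"category-{index + 1}", "package-insert"


def _make_world(params: CorpusParams) -> _World:
    rng = np.random.default_rng([params.seed, 11])
    taken: set[str] = set()
    drugs = _unique_words(rng, params.n_drugs, _DRUG_SYLLABLES, _DRUG_SUFFIXES, taken)

    # answers per category, as even as possible
    base, rem = divmod(params.n_answers_total, params.n_categories)
    per_cat = [base + (1 if i < rem else 0) for i in range(params.n_categories)]

    # sections per category sized so only _GRID_FILL of the drug x section
    # grid carries answers, leaving in-vocabulary unanswerable combinations
    sections_per_cat = [
        max(1, math.ceil(n_c / max(1, int(params.n_drugs * _GRID_FILL))))
        for n_c in per_cat
    ]
    total_sections = sum(sections_per_cat)
    symptoms_per_section = max(3, math.ceil(params.n_keywords / max(1, total_sections)))
    if params.vocabulary_size:
        want = params.vocabulary_size - params.n_drugs - total_sections
        if want > 0:
            symptoms_per_section = max(
                symptoms_per_section, math.ceil(want / total_sections)
            )

    categories: list[Category] = []
    answer_specs: list[_AnswerSpec] = []
    unused_pairs: list[tuple[str, str, str, tuple[str, ...]]] = []
    intents: dict[str, tuple[str, ...]] = {}
    answer_counter = 0
    for ci in range(params.n_categories):
        name, source = _category_name(ci, params.n_categories)
        category_id = f"C{ci + 1}"
        categories.append(Category(category_id, name, f"synthetic category {name}"))
        intents[category_id] = tuple(_unique_words(rng, 2, _WORD_SYLLABLES, taken=taken))
        section_words = _unique_words(
            rng, sections_per_cat[ci], _WORD_SYLLABLES, taken=taken
        )
        section_symptoms = {
            s: tuple(_unique_words(rng, symptoms_per_section, _WORD_SYLLABLES, taken=taken))
            for s in section_words
        }
        grid = [(d, s) for s in section_words for d in drugs]
        if per_cat[ci] > len(grid):
            raise ParameterError(
                f"category {category_id}: {per_cat[ci]} answers do not fit a "
                f"{params.n_drugs} x {sections_per_cat[ci]} drug/section grid"
            )
        chosen = rng.choice(len(grid), size=per_cat[ci], replace=False)
        chosen_set = set(int(i) for i in chosen)
        for gi in sorted(chosen_set):
            d, s = grid[gi]
            answer_counter += 1
            answer_specs.append(
                _AnswerSpec(
                    answer_id=f"A{answer_counter:05d}",
                    category_id=category_id,
                    drug=d,
                    section=s,
                    symptoms=section_symptoms[s],
                    source_section=source,
                )
            )
        for gi in range(len(grid)):
            if gi not in chosen_set:
                d, s = grid[gi]
                unused_pairs.append((category_id, d, s, section_symptoms[s]))

    # keywords: symptom words first (colloquial variation is where synonyms
    # live), then section words, shuffled deterministically
    symptom_pool = [y for spec_ in answer_specs for y in spec_.symptoms]
    # de-duplicate preserving order (symptom tuples repeat across answers)
    seen: set[str] = set()
    candidates = [w for w in symptom_pool if not (w in seen or seen.add(w))]
    for _c, d, s, ys in unused_pairs:
        for y in ys:
            if y not in seen:
                seen.add(y)
                candidates.append(y)
    section_candidates = []
    for spec_ in answer_specs:
        if spec_.section not in seen:
            seen.add(spec_.section)
            section_candidates.append(spec_.section)
    candidates.extend(section_candidates)
    if len(candidates) < params.n_keywords:
        raise ParameterError(
            f"only {len(candidates)} content words available for "
            f"{params.n_keywords} keywords; grow the registry or shrink "
            "n_keywords"
        )
    order = rng.permutation(len(candidates))
    keywords = [candidates[int(i)] for i in order[: params.n_keywords]]
    return _World(categories, drugs, answer_specs, unused_pairs, keywords, intents)


def _make_thesaurus(world: _World, params: CorpusParams) -> Thesaurus:
    base, rem = divmod(params.synonyms_total, params.n_keywords)
    taken = set(world.keywords) | set(world.drugs)
    for spec_ in world.answer_specs:
        taken.add(spec_.section)
        taken.update(spec_.symptoms)
    entries: dict[str, set[str]] = {}
    for i, keyword in enumerate(world.keywords):
        want = base + (1 if i < rem else 0)
        synonyms: set[str] = set()
        for suffix in _SYNONYM_SUFFIXES:
            if len(synonyms) == want:
                break
            variant = keyword + suffix
            if variant not in taken:
                taken.add(variant)
                synonyms.add(variant)
        if len(synonyms) < want:
            raise ParameterError(
                f"could not build {want} distinct synonyms for {keyword!r}"
            )
        entries[keyword] = synonyms
    return Thesaurus(entries)


def _compose_question(
    spec_: _AnswerSpec,
    archetype: str,
    intents: tuple[str, ...],
    rng: np.random.Generator,
) -> str:
    if archetype == "direct":
        template = _DIRECT_TEMPLATES[int(rng.integers(0, len(_DIRECT_TEMPLATES)))]
        base = template.format(s=spec_.section, d=spec_.drug)
    elif archetype == "indirect":
        template = _INDIRECT_TEMPLATES[int(rng.integers(0, len(_INDIRECT_TEMPLATES)))]
        symptom = spec_.symptoms[int(rng.integers(0, len(spec_.symptoms)))]
        base = template.format(y=symptom, d=spec_.drug)
    else:
        template = _CROSS_TEMPLATES[int(rng.integers(0, len(_CROSS_TEMPLATES)))]
        base = template.format(s=spec_.section, d=spec_.drug)
    intent = intents[int(rng.integers(0, len(intents)))]
    return f"{base} regarding {intent}"


def _canonical_question(spec_: _AnswerSpec, intents: tuple[str, ...]) -> str:
    """The representative question: a dense canonical phrasing covering the
    answer's whole content vocabulary (section, drug, symptoms, category
    phrasing).  Curated representatives are summaries like this, and the
    sorting tier — trained on representatives only — needs them to carry
    every word a later query might lead with."""
    return (
        f"about the {spec_.section} of {spec_.drug} "
        f"regarding {' '.join(intents)} with {' '.join(spec_.symptoms)}"
    )


def _plant_synonym(
    text: str, thesaurus: Thesaurus, rng: np.random.Generator
) -> str:
    tokens = text.split()
    keyword_positions = [
        i for i, t in enumerate(tokens) if t in thesaurus.entries
    ]
    if not keyword_positions:
        return text
    pos = keyword_positions[int(rng.integers(0, len(keyword_positions)))]
    synonyms = sorted(thesaurus.entries[tokens[pos]])
    tokens[pos] = synonyms[int(rng.integers(0, len(synonyms)))]
    return " ".join(tokens)


def generate_registry(params: CorpusParams) -> tuple[QARegistry, Thesaurus]:
    """Build a synthetic registry + thesaurus, reproducible from the seed.

    The registry always satisfies the structural invariants (min three
    questions per answer, exactly one representative, intact references);
    the thesaurus satisfies the no-chain invariants by construction.
    """
    world = _make_world(params)
    thesaurus = _make_thesaurus(world, params)
    rng = np.random.default_rng([params.seed, 13])
    counts = sample_questions_per_answer(
        len(world.answer_specs), params.questions_per_answer, rng
    )
    answers: list[AnswerEntry] = []
    questions: list[QuestionEntry] = []
    q_counter = 0
    for ai, (spec_, n_q) in enumerate(zip(world.answer_specs, counts)):
        answers.append(
            AnswerEntry(
                answer_id=spec_.answer_id,
                category_id=spec_.category_id,
                answer_text=(
                    f"registered guidance on {spec_.section} for {spec_.drug}"
                ),
                source_section=spec_.source_section,
                drug_name=spec_.drug,
            )
        )
        # question 0 is the canonical representative; the rest cycle through
        # the three archetypes, with the cycle phase rotated per answer
        for qi in range(int(n_q)):
            if qi == 0:
                text = _canonical_question(spec_, world.intents[spec_.category_id])
            else:
                archetype = _ARCHETYPES[(qi + ai) % len(_ARCHETYPES)]
                text = _compose_question(
                    spec_, archetype, world.intents[spec_.category_id], rng
                )
                if rng.random() < params.synonym_plant_rate:
                    text = _plant_synonym(text, thesaurus, rng)
            q_counter += 1
            questions.append(
                QuestionEntry(
                    question_id=f"Q{q_counter:06d}",
                    answer_id=spec_.answer_id,
                    text=text,
                    is_representative=(qi == 0),
                )
            )
    registry = QARegistry(world.categories, answers, questions)
    registry.check_references()
    return registry, thesaurus


def paraphrase(
    text: str, noise: float, thesaurus: Thesaurus, seed: int
) -> str:
    """Stochastic stand-in for human rephrasing.

    Each token is independently dropped with probability ``noise/2`` or —
    when it is a thesaurus keyword — replaced by one of its synonyms with
    probability ``noise/2``.  At least one token always survives.
    Deterministic per seed.
    """
    if not text.strip():
        raise ParameterError("cannot paraphrase empty text")
    if not 0.0 <= noise <= 1.0:
        raise ParameterError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tokens = text.split()
    out: list[str] = []
    for token in tokens:
        u = rng.random()
        if u < noise / 2:
            continue  # dropout
        if u < noise and token in thesaurus.entries:
            synonyms = sorted(thesaurus.entries[token])
            out.append(synonyms[int(rng.integers(0, len(synonyms)))])
        else:
            out.append(token)
    if not out:
        out = [tokens[0]]
    return " ".join(out)


def generate_validation_set(
    registry: QARegistry,
    thesaurus: Thesaurus,
    params: CorpusParams,
) -> list[ValidationQuestion]:
    """Validation questions with ground truth for a generated registry.

    Answerable questions paraphrase registered questions (dropout, synonym
    substitution, archetype switching) at per-author-group noise levels;
    unanswerable questions reuse registry vocabulary in drug/section
    combinations that carry no answer.  Distinct answerable targets cover
    ``answer_coverage`` of the registry's answers.  The registry/thesaurus
    must come from :func:`generate_registry` with the same params (the
    vocabulary layout is re-derived from the seed).
    """
    world = _make_world(params)
    spec_by_id = {s.answer_id: s for s in world.answer_specs}
    known = {a.answer_id for a in registry.answers}
    if set(spec_by_id) != known:
        raise ParameterError(
            "registry does not match these params (answer IDs differ); "
            "generate_validation_set only supports registries produced by "
            "generate_registry with identical CorpusParams"
        )
    rng = np.random.default_rng([params.seed, 17])
    n_unanswerable = int(round(params.n_validation * params.unanswerable_fraction))
    n_answerable = params.n_validation - n_unanswerable
    n_distinct = int(round(params.answer_coverage * len(registry.answers)))
    if n_answerable == 0:
        n_distinct = 0
    elif n_distinct < 1:
        raise ParameterError("answer_coverage selects no answers")
    elif n_distinct > n_answerable:
        raise ParameterError(
            f"cannot cover {n_distinct} distinct answers with only "
            f"{n_answerable} answerable validation questions"
        )
    if (
        n_unanswerable > 0
        and params.unanswerable_in_vocabulary
        and not world.unused_pairs
    ):
        raise ParameterError("no unanswerable drug/section combinations available")

    questions_by_answer: dict[str, list[QuestionEntry]] = {}
    for q in registry.questions:
        questions_by_answer.setdefault(q.answer_id, []).append(q)

    answer_ids = sorted(known)
    targets = [
        answer_ids[int(i)]
        for i in rng.choice(len(answer_ids), size=n_distinct, replace=False)
    ]
    out: list[ValidationQuestion] = []
    for i in range(n_answerable):
        answer_id = targets[i % n_distinct]
        group = _GROUPS[i % len(_GROUPS)]
        noise = min(1.0, params.paraphrase_noise * _GROUP_NOISE[group])
        spec_ = spec_by_id[answer_id]
        if rng.random() < noise / 2:
            # archetype switching: re-express the intent through another
            # question archetype instead of perturbing an existing phrasing
            archetype = _ARCHETYPES[int(rng.integers(0, len(_ARCHETYPES)))]
            text = _compose_question(
                spec_, archetype, world.intents[spec_.category_id], rng
            )
        else:
            pool = questions_by_answer[answer_id]
            source = pool[int(rng.integers(0, len(pool)))]
            text = paraphrase(
                source.text, noise, thesaurus, int(rng.integers(0, 2**31))
            )
        out.append(
            ValidationQuestion(
                text=text,
                has_answer_in_system=True,
                expected_answer_id=answer_id,
                author_group=group,
            )
        )
    for i in range(n_unanswerable):
        group = _GROUPS[(n_answerable + i) % len(_GROUPS)]
        if not params.unanswerable_in_vocabulary:
            # vocabulary-disjoint probe: every token is novel, so every
            # classifier falls back to its uniform confidence floor
            n_tokens = int(rng.integers(4, 8))
            text = " ".join(
                "x" + "".join(
                    _WORD_SYLLABLES[int(j)]
                    for j in rng.integers(0, len(_WORD_SYLLABLES), size=2)
                )
                + "q"
                for _ in range(n_tokens)
            )
            out.append(
                ValidationQuestion(
                    text=text,
                    has_answer_in_system=False,
                    expected_answer_id=None,
                    author_group=group,
                )
            )
            continue
        cid, d, s, symptoms = world.unused_pairs[
            int(rng.integers(0, len(world.unused_pairs)))
        ]
        if rng.random() < 0.5:
            template = _DIRECT_TEMPLATES[int(rng.integers(0, len(_DIRECT_TEMPLATES)))]
            text = template.format(s=s, d=d)
        else:
            template = _INDIRECT_TEMPLATES[
                int(rng.integers(0, len(_INDIRECT_TEMPLATES)))
            ]
            text = template.format(y=symptoms[int(rng.integers(0, len(symptoms)))], d=d)
        intents = world.intents[cid]
        text = f"{text} regarding {intents[int(rng.integers(0, len(intents)))]}"
        out.append(
            ValidationQuestion(
                text=text,
                has_answer_in_system=False,
                expected_answer_id=None,
                author_group=group,
            )
        )
    return out


@dataclass
class GeneratedBundle:
    """A complete synthetic study: registry, thesaurus, validation set."""

    registry: QARegistry
    thesaurus: Thesaurus
    validation: list[ValidationQuestion]
    params: CorpusParams

    @property
    def ground_truth(self) -> dict[str, str | None]:
        return {q.text: q.expected_answer_id for q in self.validation}

    @property
    def answer_coverage(self) -> float:
        covered = {
            q.expected_answer_id for q in self.validation if q.expected_answer_id
        }
        return len(covered) / len(self.registry.answers)


def generate_bundle(params: CorpusParams) -> GeneratedBundle:
    registry, thesaurus = generate_registry(params)
    validation = generate_validation_set(registry, thesaurus, params)
    return GeneratedBundle(registry, thesaurus, validation, params)
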