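import pytest

import kampoqa as k


@pytest.fixture
def tiny_registry() -> k.QARegistry:
    """Hand-built two-category, three-answer registry."""
    categories = [
        k.Category("C1", "safety"),
        k.Category("C2", "usage"),
    ]
    answers = [
        k.AnswerEntry("A1", "C1", "contraindications of kakkonto", drug_name="kakkonto"),
        k.AnswerEntry("A2", "C1", "contraindications of yokukansan", drug_name="yokukansan"),
        k.AnswerEntry("A3", "C2", "indications of kakkonto", drug_name="kakkonto"),
    ]
    questions = [
        k.QuestionEntry("Q1", "A1", "what are the contraindications of kakkonto", True),
        k.QuestionEntry("Q2", "A1", "who must not take kakkonto", False),
        k.QuestionEntry("Q3", "A1", "is kakkonto forbidden for anyone", False),
        k.QuestionEntry("Q4", "A2", "what are the contraindications of yokukansan", True),
        k.QuestionEntry("Q5", "A2", "who must not take yokukansan", False),
        k.QuestionEntry("Q6", "A2", "is yokukansan forbidden for anyone", False),
        k.QuestionEntry("Q7", "A3", "what are the indications of kakkonto", True),
        k.QuestionEntry("Q8", "A3", "what is kakkonto used for", False),
        k.QuestionEntry("Q9", "A3", "which symptoms does kakkonto treat", False),
    ]
    return k.QARegistry(categories, answers, questions)


@pytest.fixture
def tiny_thesaurus() -> k.Thesaurus:
    return k.Thesaurus(
        {
            "abdominal pain": {"belly ache", "stomach ache"},
            "stiff shoulders": {"shoulder stiffness"},
        }
    )


@pytest.fixture(scope="session")
def small_bundle() -> k.GeneratedBundle:
    """Default desk-scale synthetic study (paraphrase noise 0.3,
    in-vocabulary unanswerable questions)."""
    return k.generate_bundle(k.CorpusParams.small(seed=7))


@pytest.fixture(scope="session")
def small_system(small_bundle) -> k.QASystem:
    return k.build_system(
        small_bundle.registry, small_bundle.thesaurus, threshold=0.0
    )


@pytest.fixture(scope="session")
def separable_bundle() -> k.GeneratedBundle:
    """Planted-confidence-gap study: verbatim answerable questions vs
    vocabulary-disjoint unanswerable ones."""
    return k.generate_bundle(k.CorpusParams.separable(seed=7))


@pytest.fixture(scope="session")
def separable_system(separable_bundle) -> k.QASystem:
    return k.build_system(
        separable_bundle.registry, separable_bundle.thesaurus, threshold=0.0
    )
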