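"""Exception hierarchy shared across the package.

All domain errors derive from :class:`KampoQAError` so callers (and the CLI)
can distinguish data/usage problems from genuine bugs.
"""


class KampoQAError(Exception):
    """Base class for all errors raised by kampoqa."""


class RegistryIOError(KampoQAError):
    """A registry, thesaurus or validation file failed to parse."""


class IntegrityError(KampoQAError):
    """A reference inside a registry does not resolve."""


class ValidationDataError(KampoQAError):
    """A record violates a structural invariant (not a parse failure)."""


class UnknownCategoryError(KampoQAError, KeyError):
    """A category_id was requested that the registry does not define."""


class ThesaurusError(KampoQAError):
    """A thesaurus violates the no-chain / uniqueness invariants."""


class ConfigurationError(KampoQAError):
    """A component was configured with something unusable (e.g. a
    morphological tokenizer when no analyzer is installed)."""


class TrainingError(KampoQAError):
    """The classifier was given an unusable training set."""


class QueryError(KampoQAError):
    """An unusable query (e.g. empty text) was submitted."""


class ParameterError(KampoQAError, ValueError):
    """A numeric parameter is outside its legal range or infeasible."""


class EvaluationError(KampoQAError):
    """The validation set cannot support the requested evaluation."""
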