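"""Tokenization and thesaurus-based synonym normalization.

Every question entering the system — at training-set build time and at query
time alike — is first segmented into tokens and then rewritten so that each
synonym surface form is replaced by its canonical keyword.  Canonicalizing
before classification absorbs expression variability (colloquial symptom
descriptions, spelling variants) without inflating the registered-question
set.

Matching is token-boundary aligned, longest-match-first, left to right, in a
single pass; replaced output is never re-scanned.  Together with the
thesaurus no-chain invariant (a keyword never appears as a synonym of another
keyword) this makes normalization idempotent.  Matching is case-insensitive
for cased scripts (via ``str.casefold``) and exact otherwise, which is the
right behaviour for Japanese mixed with Latin drug names.

The tokenizer is pluggable: ``whitespace`` for segmented text, ``character``
for unsegmented text (the fallback that makes Japanese testable without an
external analyzer — token-aligned matching degenerates to plain substring
matching), and ``external-morphological`` for a MeCab-style analyzer when one
is installed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, RegistryIOError, ThesaurusError

_WORD_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class TokenizerSpec:
    """Deterministic tokenizer configuration.

    name:
        ``whitespace`` — split on Unicode whitespace;
        ``character`` — one token per character (substring-matching fallback
        for unsegmented scripts);
        ``external-morphological`` — delegate to an installed morphological
        analyzer (raises :class:`ConfigurationError` when none is available).
    """

    name: str = "whitespace"
    options: tuple = ()

    def __post_init__(self) -> None:
        if self.name not in ("whitespace", "character", "external-morphological"):
            raise ConfigurationError(f"unknown tokenizer: {self.name!r}")


@dataclass(frozen=True)
class TokenSequence:
    """Tokens plus their 0-based half-open character spans in the source."""

    tokens: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, spec: TokenizerSpec = TokenizerSpec()) -> TokenSequence:
    """Segment ``text`` per ``spec``; deterministic for identical inputs."""
    if spec.name == "whitespace":
        tokens, spans = [], []
        for m in _WORD_RE.finditer(text):
            tokens.append(m.group())
            spans.append((m.start(), m.end()))
        return TokenSequence(tuple(tokens), tuple(spans))
    if spec.name == "character":
        return TokenSequence(
            tuple(text), tuple((i, i + 1) for i in range(len(text)))
        )
    # external-morphological
    try:  # pragma: no cover - exercised only where an analyzer is installed
        import fugashi  # type: ignore
    except ImportError:
        raise ConfigurationError(
            "external-morphological tokenizer requested but no analyzer "
            "(fugashi/MeCab) is installed; fall back to the 'character' "
            "tokenizer for unsegmented text or 'whitespace' otherwise"
        ) from None
    tagger = fugashi.Tagger()  # pragma: no cover
    tokens, spans, cursor = [], [], 0  # pragma: no cover
    for word in tagger(text):  # pragma: no cover
        start = text.index(word.surface, cursor)
        tokens.append(word.surface)
        spans.append((start, start + len(word.surface)))
        cursor = start + len(word.surface)
    return TokenSequence(tuple(tokens), tuple(spans))  # pragma: no cover


def _fold(token: str) -> str:
    return token.casefold()


class Thesaurus:
    """Keyword -> synonyms mapping used for pre-classification conversion.

    Invariants enforced at construction:

    * no synonym appears under two different keywords;
    * no keyword appears as a synonym of another keyword (no chains);
    * keywords and synonyms are non-empty.

    Uniqueness is checked on casefolded forms, matching the case-insensitive
    matcher, so the invariants cannot be dodged by capitalization.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        normalized: dict[str, frozenset[str]] = {}
        owner: dict[str, str] = {}
        for keyword, synonyms in entries.items():
            if not keyword or not keyword.strip():
                raise ThesaurusError("empty keyword")
            syns = frozenset(synonyms)
            for s in syns:
                if not s or not s.strip():
                    raise ThesaurusError(f"empty synonym under keyword {keyword!r}")
                f = _fold(s)
                if f in owner and owner[f] != keyword:
                    raise ThesaurusError(
                        f"synonym {s!r} appears under both {owner[f]!r} "
                        f"and {keyword!r}"
                    )
                owner[f] = keyword
            normalized[keyword] = syns
        folded_keywords = {_fold(k) for k in normalized}
        for f, kw in owner.items():
            # a keyword listed as its own synonym is a harmless identity;
            # under any other keyword it would form a conversion chain
            if f in folded_keywords and f != _fold(kw):
                raise ThesaurusError(
                    f"keyword {f!r} also appears as a synonym of {kw!r} "
                    "(conversion chains are not allowed)"
                )
        self.entries: dict[str, frozenset[str]] = normalized
        self._tables: dict[tuple, tuple[dict, int]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_synonyms(self) -> int:
        return sum(len(s) for s in self.entries.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Thesaurus) and self.entries == other.entries

    def _token_table(self, spec: TokenizerSpec) -> tuple[dict, int]:
        """Map folded synonym token tuples -> keyword, plus the longest
        synonym length in tokens.  Cached per tokenizer spec."""
        key = (spec.name, spec.options)
        if key not in self._tables:
            table: dict[tuple[str, ...], str] = {}
            longest = 0
            for keyword, synonyms in self.entries.items():
                for s in synonyms:
                    toks = tuple(_fold(t) for t in tokenize(s, spec).tokens)
                    if toks:
                        table[toks] = keyword
                        longest = max(longest, len(toks))
            self._tables[key] = (table, longest)
        return self._tables[key]


def load_thesaurus(path: str | Path) -> Thesaurus:
    """Read a ``keyword<TAB>synonym`` table (header row required)."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
            "keyword",
            "synonym",
        } <= set(reader.fieldnames):
            raise RegistryIOError(
                f"{path}: expected header with columns 'keyword' and 'synonym'"
            )
        for lineno, row in enumerate(reader, start=2):
            kw, syn = row.get("keyword"), row.get("synonym")
            if kw is None or syn is None:
                raise RegistryIOError(f"{path}: line {lineno}: short row")
            entries.setdefault(kw, set()).add(syn)
    return Thesaurus(entries)


def save_thesaurus(thesaurus: Thesaurus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["keyword", "synonym"])
        for keyword in sorted(thesaurus.entries):
            for synonym in sorted(thesaurus.entries[keyword]):
                writer.writerow([keyword, synonym])


def apply_thesaurus(
    text: str, thesaurus: Thesaurus, spec: TokenizerSpec = TokenizerSpec()
) -> str:
    """Replace every maximal synonym occurrence with its keyword.

    Matching is aligned to token boundaries, longest match first, left to
    right, single pass (replaced output is not rescanned).  Text containing
    no synonyms is returned unchanged (identically, including whitespace).
    """
    table, longest = thesaurus._token_table(spec)
    if not table:
        return text
    seq = tokenize(text, spec)
    folded = [_fold(t) for t in seq.tokens]
    replacements: list[tuple[int, int, str]] = []  # (char_start, char_end, keyword)
    i = 0
    n = len(folded)
    while i < n:
        matched = False
        for length in range(min(longest, n - i), 0, -1):
            keyword = table.get(tuple(folded[i : i + length]))
            if keyword is not None:
                replacements.append(
                    (seq.spans[i][0], seq.spans[i + length - 1][1], keyword)
                )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    if not replacements:
        return text
    out, cursor = [], 0
    for start, end, keyword in replacements:
        out.append(text[cursor:start])
        out.append(keyword)
        cursor = end
    out.append(text[cursor:])
    return "".join(out)


def normalize(
    text: str, thesaurus: Thesaurus, spec: TokenizerSpec = TokenizerSpec()
) -> str:
    """Full pre-classification normalization: tokenize, then convert
    synonyms to keywords.  Idempotent under the no-chain invariant."""
    return apply_thesaurus(text, thesaurus, spec)
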