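"""Regularization of clinical letter text and personal-name masking.

The processing order matters: name masking uses capitalization as its cue,
so it must run before lowercasing. The canonical sequence is::

    mask_personal_names -> regularize -> tokenize

wrapped by :func:`prepare` for convenience.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

from ._lemma import lemmatize
from ._stem import porter_stem
from ._stopwords import DEFAULT_STOPWORDS

#: Reserved surface form replacing every masked personal name. Kept
#: alphanumeric so it survives punctuation normalization unchanged.
MASK_TOKEN = "xxpersonxx"

_SENTENCE_MARKS = frozenset(".!?")


class EmptyLetterError(ValueError):
    """Raised when a letter is empty after whitespace stripping."""


class ConfigurationError(ValueError):
    """Raised for invalid preprocessing configuration (e.g. unknown mode)."""


class Mode(str, Enum):
    STEM = "stem"
    LEMMA = "lemma"


class TokenKind(str, Enum):
    WORD = "word"
    CONCEPT = "concept"
    SEMTYPE = "semtype"
    PERSON_MASK = "person_mask"


@dataclass(frozen=True)
class RawLetter:
    id: str
    text: str


@dataclass(frozen=True)
class Token:
    surface: str
    kind: TokenKind
    span: tuple[int, int]  # 0-based, half-open, into the regularized text


@dataclass
class TokenStream:
    doc_id: str
    tokens: list[Token]
    sentence_breaks: list[int] = field(default_factory=list)
    text: str | None = None

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class VariantLexicon:
    """Surface form -> canonical representative (one-step mappings)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for key, canon in self.entries.items():
            if key != key.lower():
                raise ConfigurationError(f"lexicon key not lowercase: {key!r}")
            if canon.lower() in self.entries:
                raise ConfigurationError(
                    f"canonical form {canon!r} is itself a key (mappings must be one-step)"
                )


def _load_lines(name: str) -> list[str]:
    raw = resources.files("triage_lda.data").joinpath(name).read_text("utf-8")
    return [
        line.strip()
        for line in raw.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def default_honorifics() -> list[str]:
    return _load_lines("honorifics.txt")


def default_patient_triggers() -> list[str]:
    return _load_lines("patient_triggers.txt")


def default_enclitics() -> list[tuple[str, str]]:
    pairs = []
    for line in _load_lines("enclitics.tsv"):
        key, _, expansion = line.partition("\t")
        pairs.append((key, expansion))
    return pairs


def read_variant_lexicon(path) -> VariantLexicon:
    """Read a 2-column TSV (surface TAB canonical); '#' lines are comments."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(f"{path}:{lineno}: expected 2 columns")
            key = parts[0].strip().lower()
            if key in entries:
                raise ConfigurationError(f"{path}:{lineno}: duplicate key {key!r}")
            entries[key] = parts[1].strip().lower()
    return VariantLexicon(entries)


# ---------------------------------------------------------------------------
# name masking
# ---------------------------------------------------------------------------

_CAP_WORD = r"(?:[A-Z]\.|[A-Z][A-Za-z'\-]+)"


def _honorific_pattern(honorifics: Sequence[str]) -> re.Pattern:
    alts = "|".join(re.escape(h) + r"\.?" for h in honorifics)
    # honorific + 1..3 capitalized words (initials allowed)
    return re.compile(
        rf"\b(?:{alts})\s+(?:{_CAP_WORD})(?:\s+(?:{_CAP_WORD})){{0,2}}"
    )


def _trigger_pattern(triggers: Sequence[str]) -> re.Pattern:
    alts = "|".join(re.escape(t) for t in triggers)
    # trigger phrase is case-insensitive, the name itself must be capitalized
    return re.compile(
        rf"\b((?i:{alts}))\s+((?:{_CAP_WORD})(?:\s+(?:{_CAP_WORD})){{0,2}})"
    )


def mask_personal_names(
    letter: RawLetter,
    honorifics: Sequence[str] | None = None,
    triggers: Sequence[str] | None = None,
    mask: str = MASK_TOKEN,
) -> RawLetter:
    """Replace honorific-triggered name sequences with a reserved token.

    Eponymous medical terms carry no honorific and are left untouched.
    Runs on the original-case text: capitalization is the cue.
    """
    honorifics = default_honorifics() if honorifics is None else honorifics
    triggers = default_patient_triggers() if triggers is None else triggers
    text = _honorific_pattern(honorifics).sub(mask, letter.text)

    def _keep_trigger(m: re.Match) -> str:
        return f"{m.group(1)} {mask}"

    text = _trigger_pattern(triggers).sub(_keep_trigger, text)
    return RawLetter(letter.id, text)


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------


def _expand_enclitics(text: str, table: Iterable[tuple[str, str]]) -> str:
    for key, expansion in table:
        if key.startswith("'") or key == "n't":
            pattern = re.compile(r"(?<=[a-z])" + re.escape(key) + r"\b")
        else:
            pattern = re.compile(r"\b" + re.escape(key) + r"\b")
        text = pattern.sub(expansion, text)
    return text


def _apply_variant_lexicon(text: str, lex: VariantLexicon) -> str:
    # longest-first so multiword keys win over their own sub-words
    keys = sorted(lex.entries, key=lambda k: (-len(k.split()), -len(k), k))
    for key in keys:
        pattern = re.compile(r"\b" + re.escape(key) + r"\b")
        text = pattern.sub(lex.entries[key], text)
    return text


def regularize(
    letter: RawLetter,
    lex: VariantLexicon | None = None,
    enclitics: Iterable[tuple[str, str]] | None = None,
) -> RawLetter:
    """Lowercase, expand enclitics, apply variant lexicon, normalize punctuation.

    Idempotent: applying the function to its own output is a no-op.
    """
    if not letter.text.strip():
        raise EmptyLetterError(f"letter {letter.id!r} is empty")
    text = letter.text.lower()
    text = _expand_enclitics(text, default_enclitics() if enclitics is None else enclitics)
    if lex is not None:
        text = _apply_variant_lexicon(text, lex)
    text = re.sub(r"'s\b", "", text)
    text = text.replace("'", " ")
    text = re.sub(r"([.!?])", r" \1 ", text)
    # every other punctuation / special character becomes a space
    text = re.sub(r"[^a-z0-9.!?\s]", " ", text)
    text = re.sub(r"\s+", " ", text).strip()
    return RawLetter(letter.id, text)


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------


def tokenize(
    letter: RawLetter,
    mode: Mode | str = Mode.STEM,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    mask: str = MASK_TOKEN,
) -> TokenStream:
    """Split a regularized letter into reduced word tokens.

    Stop-words are removed; sentence-final marks are dropped from the token
    list but recorded as sentence break positions. Spans index into the
    regularized text.
    """
    try:
        mode = Mode(mode)
    except ValueError:
        raise ConfigurationError(f"unknown tokenization mode: {mode!r}") from None
    reduce = porter_stem if mode is Mode.STEM else lemmatize

    tokens: list[Token] = []
    breaks: list[int] = []
    for m in re.finditer(r"\S+", letter.text):
        raw = m.group(0)
        if raw in _SENTENCE_MARKS:
            if tokens and (not breaks or breaks[-1] != len(tokens)):
                breaks.append(len(tokens))
            continue
        if raw == mask:
            tokens.append(Token(mask, TokenKind.PERSON_MASK, m.span()))
            continue
        if raw in stopwords:
            continue
        tokens.append(Token(reduce(raw), TokenKind.WORD, m.span()))
    return TokenStream(letter.id, tokens, breaks, text=letter.text)


def prepare(
    letter: RawLetter,
    lex: VariantLexicon | None = None,
    mode: Mode | str = Mode.STEM,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    honorifics: Sequence[str] | None = None,
    triggers: Sequence[str] | None = None,
) -> TokenStream:
    """Full preprocessing: mask names, regularize, tokenize."""
    masked = mask_personal_names(letter, honorifics=honorifics, triggers=triggers)
    return tokenize(regularize(masked, lex=lex), mode=mode, stopwords=stopwords)
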