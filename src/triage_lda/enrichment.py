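"""Dictionary-lookup concept recognition and bag-of-words construction.

Matching is word-order insensitive within a sliding window and tolerant to
derivational variation via shared stems, so "tear of meniscus" and
"meniscus tear" resolve to the same concept. Longest token span wins; ties
go to the leftmost match, then the lexicographically smallest concept id.
Accepted matches never overlap.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._stem import porter_stem
from ._stopwords import DEFAULT_STOPWORDS
from .textprep import (
    MASK_TOKEN,
    ConfigurationError,
    Token,
    TokenKind,
    TokenStream,
)

#: derivational suffixes collapsed before stemming (-al, -ic, -ous)
SUFFIX_REWRITES = ("al", "ic", "ous")


def match_key(word: str, rewrites: bool = True) -> str:
    """Reduction applied to both lexicon terms and stream tokens."""
    word = word.lower()
    if rewrites:
        for suffix in SUFFIX_REWRITES:
            if word.endswith(suffix) and len(word) - len(suffix) >= 4:
                word = word[: -len(suffix)]
                break
    return porter_stem(word)


@dataclass(frozen=True)
class LexEntry:
    term: tuple[str, ...]  # lowercase word sequence
    concept_id: str
    semtype: str


@dataclass
class Lexicon:
    entries: list[LexEntry]
    semtype_whitelist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.semtype_whitelist:
            self.semtype_whitelist = frozenset(e.semtype for e in self.entries)
        for e in self.entries:
            if e.semtype not in self.semtype_whitelist:
                raise ConfigurationError(
                    f"entry {' '.join(e.term)!r}: semtype {e.semtype!r} not in whitelist"
                )

    def __len__(self) -> int:
        return len(self.entries)


def read_lexicon(path, semtype_whitelist: Iterable[str] | None = None) -> Lexicon:
    """Read a 3-column TSV: term TAB concept_id TAB semtype."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ConfigurationError(f"{path}:{lineno}: expected 3 columns")
            term = tuple(parts[0].strip().lower().split())
            entries.append(LexEntry(term, parts[1].strip(), parts[2].strip()))
    whitelist = frozenset(semtype_whitelist) if semtype_whitelist else frozenset()
    return Lexicon(entries, whitelist)


@dataclass(frozen=True)
class ConceptMatch:
    doc_id: str
    token_span: tuple[int, int]  # [start, end) over the TokenStream
    concept_id: str
    semtype: str
    matched_term: str


@dataclass(frozen=True)
class EnrichmentVariant:
    include_words: bool
    include_concepts: bool
    include_semtypes: bool


#: the four feature presets: words / +concepts / +semtypes / +both
VARIANTS = {
    "D1": EnrichmentVariant(True, False, False),
    "D2": EnrichmentVariant(True, True, False),
    "D3": EnrichmentVariant(True, False, True),
    "D4": EnrichmentVariant(True, True, True),
}


def _entry_keys(entry: LexEntry, rewrites: bool) -> Counter:
    words = [w for w in entry.term if w not in DEFAULT_STOPWORDS]
    if not words:
        words = list(entry.term)
    return Counter(match_key(w, rewrites) for w in words)


def match_concepts(
    stream: TokenStream,
    lex: Lexicon,
    window: int = 8,
    rewrites: bool = True,
) -> list[ConceptMatch]:
    """Find non-overlapping concept matches in a tokenized stream."""
    entry_keys = [(_entry_keys(e, rewrites), e) for e in lex.entries]
    too_long = [
        " ".join(e.term) for keys, e in entry_keys if sum(keys.values()) > window
    ]
    if too_long:
        raise ConfigurationError(
            f"window={window} smaller than lexicon terms: {too_long}"
        )

    token_keys = [
        match_key(t.surface, rewrites) if t.kind is TokenKind.WORD else None
        for t in stream.tokens
    ]

    candidates: list[tuple[int, int, str, ConceptMatch]] = []
    n = len(token_keys)
    for keys, entry in entry_keys:
        need_total = sum(keys.values())
        for i in range(n):
            if token_keys[i] not in keys:
                continue
            # grow the span rightwards until the entry multiset is covered
            have: Counter = Counter()
            covered = 0
            for j in range(i, min(n, i + window)):
                k = token_keys[j]
                if k in keys and have[k] < keys[k]:
                    have[k] += 1
                    covered += 1
                if covered == need_total:
                    match = ConceptMatch(
                        stream.doc_id,
                        (i, j + 1),
                        entry.concept_id,
                        entry.semtype,
                        " ".join(entry.term),
                    )
                    candidates.append((j + 1 - i, i, entry.concept_id, match))
                    break

    # longest span wins, then leftmost, then smallest concept id
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[ConceptMatch] = []
    taken = np.zeros(n, dtype=bool)
    for _, start, _, match in candidates:
        s, e = match.token_span
        if not taken[s:e].any():
            taken[s:e] = True
            accepted.append(match)
    accepted.sort(key=lambda m: m.token_span)
    return accepted


def annotate(
    stream: TokenStream,
    matches: Sequence[ConceptMatch],
    variant: EnrichmentVariant | str,
) -> TokenStream:
    """Inject concept / semantic-type tokens at match positions.

    Word tokens are retained iff ``variant.include_words``; the D1 preset
    returns the stream unchanged.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant.upper()]
    spans = sorted(m.token_span for m in matches)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping matches at token spans {(s1, e1)} / {(s2, e2)}")

    starts = {m.token_span[0]: m for m in matches}
    out: list[Token] = []
    for i, tok in enumerate(stream.tokens):
        if i in starts and (variant.include_concepts or variant.include_semtypes):
            m = starts[i]
            s_char = stream.tokens[m.token_span[0]].span[0]
            e_char = stream.tokens[m.token_span[1] - 1].span[1]
            if variant.include_concepts:
                out.append(Token(m.concept_id.lower(), TokenKind.CONCEPT, (s_char, e_char)))
            if variant.include_semtypes:
                out.append(Token(m.semtype.lower(), TokenKind.SEMTYPE, (s_char, e_char)))
        if tok.kind is not TokenKind.WORD or variant.include_words:
            out.append(tok)
    return TokenStream(stream.doc_id, out, list(stream.sentence_breaks), text=stream.text)


# ---------------------------------------------------------------------------
# bag of words
# ---------------------------------------------------------------------------


class EmptyCorpusError(ValueError):
    """Raised when every document is empty."""


@dataclass
class BagOfWords:
    vocabulary: tuple[str, ...]
    counts: np.ndarray  # D x V integer counts
    doc_ids: list[str]
    empty_docs: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "vocabulary": list(self.vocabulary),
                    "doc_ids": self.doc_ids,
                    "empty_docs": self.empty_docs,
                    "counts": self.counts.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "BagOfWords":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(
            tuple(data["vocabulary"]),
            np.asarray(data["counts"], dtype=np.int64),
            data["doc_ids"],
            data["empty_docs"],
        )


def build_bow(
    streams: Sequence[TokenStream],
    min_df: int = 1,
    exclude: frozenset[str] = frozenset({MASK_TOKEN}),
) -> BagOfWords:
    """Build a document-term count matrix over a stable, sorted vocabulary."""
    if not streams:
        raise EmptyCorpusError("no documents")
    doc_counters = [
        Counter(t.surface for t in s.tokens if t.surface not in exclude)
        for s in streams
    ]
    if not any(doc_counters):
        raise EmptyCorpusError("all documents empty")
    df: Counter = Counter()
    for c in doc_counters:
        df.update(c.keys())
    vocab = tuple(sorted(t for t, d in df.items() if d >= min_df))
    index = {t: i for i, t in enumerate(vocab)}
    counts = np.zeros((len(streams), len(vocab)), dtype=np.int64)
    for row, c in enumerate(doc_counters):
        for term, k in c.items():
            j = index.get(term)
            if j is not None:
                counts[row, j] = k
    empty = [s.doc_id for s, row in zip(streams, counts) if row.sum() == 0]
    return BagOfWords(vocab, counts, [s.doc_id for s in streams], empty)
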