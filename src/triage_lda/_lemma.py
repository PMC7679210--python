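"""Lightweight lookup/rule lemmatizer.

A deliberately small alternative to stemming: irregular-form lookup plus
conservative suffix rules for plural nouns and regular verb inflections.
Unknown forms are returned unchanged, which is the safe behaviour for a
bag-of-words pipeline (a missed merge is benign, a wrong merge is not).
"""

from __future__ import annotations

_IRREGULAR = {
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "children": "child",
    "knives": "knife",
    "calves": "calf",
    "mice": "mouse",
    "diagnoses": "diagnosis",
    "prostheses": "prosthesis",
    "analyses": "analysis",
    "stenoses": "stenosis",
    "menisci": "meniscus",
    "bursae": "bursa",
    "vertebrae": "vertebra",
    "criteria": "criterion",
    "worse": "bad",
    "worst": "bad",
    "better": "good",
    "best": "good",
    "went": "go",
    "gone": "go",
    "was": "be",
    "were": "be",
    "been": "be",
    "is": "be",
    "are": "be",
    "am": "be",
    "has": "have",
    "had": "have",
    "did": "do",
    "done": "do",
    "said": "say",
    "seen": "see",
    "saw": "see",
    "felt": "feel",
    "torn": "tear",
    "tore": "tear",
    "swollen": "swell",
    "injuries": "injury",
    "surgeries": "surgery",
}

# words that look inflected but are not
_INVARIANT = frozenset(
    {
        "series", "species", "news", "analysis", "diagnosis", "arthritis",
        "osteoarthritis", "bursitis", "tendinitis", "pelvis", "diabetes",
        "this", "his", "its", "is", "as", "us", "bus", "yes", "less",
        "always", "perhaps", "during",
    }
)


def _strip_plural(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("xes", "ches", "shes", "zes")) and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def lemmatize(word: str) -> str:
    word = word.lower()
    if not word.isalpha() or len(word) <= 2:
        return word
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if word in _INVARIANT:
        return word
    return _strip_plural(word)
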