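"""Synthetic referral-letter corpora with known ground truth.

Documents are drawn from a planted topic mixture (Dirichlet document-topic
priors, multinomial word emission over pseudo-word vocabularies), wrapped
in letter boilerplate with honorific-prefixed fabricated names, sprinkled
with abbreviations and synonym clusters that share a concept identifier,
and paired with binary treatment outcomes whose probabilities depend on
the document's topic mixture through a logistic link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ._stem import porter_stem
from ._stopwords import DEFAULT_STOPWORDS
from .enrichment import Lexicon, LexEntry
from .textprep import MASK_TOKEN, RawLetter, VariantLexicon
from .triage import TREATMENTS

#: study treatment counts out of 576 patients, used as default prevalences
STUDY_TREATMENT_COUNTS = {
    "O1": 53, "O2": 173, "O3": 101, "O4": 15, "O5": 152,
    "O6": 112, "O7": 99, "O8": 223, "O9": 16,
}
STUDY_N = 576

_TEMPLATE_WORDS = frozenset(
    "dear thank you for seeing who presents with yours sincerely".split()
)

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "ha", "je", "ki", "lo", "mu", "na", "pe",
    "qui", "ro", "su", "ta", "ve", "wi", "xa", "zo", "bra", "cle", "dri",
    "flo", "gra", "ple", "sta", "tre", "vla", "spo", "kan", "mer", "nil",
    "pol", "rud", "sev", "tum", "vor", "wex", "yat",
]

_SEMTYPES = ("dsyn", "sosy", "topp", "phsu", "diap")


@dataclass
class GeneratorConfig:
    seed: int
    K_true: int = 11
    D: int = 500
    n_core_words: int = 600
    n_synonym_clusters: int = 20
    n_abbreviations: int = 15
    doc_len_mean: float = 120.0
    doc_len_min: int = 20
    alpha_true: float = 0.1
    topic_word_concentration: float = 0.05
    syn_sub_prob: float = 0.3
    abbrev_prob: float = 0.3
    eponym_prob: float = 0.02
    #: per-treatment target prevalences (defaults: study distribution)
    prevalences: dict[str, float] = field(
        default_factory=lambda: {
            t: c / STUDY_N for t, c in STUDY_TREATMENT_COUNTS.items()
        }
    )
    #: log-odds weight of each treatment on the topics; by default treatment
    #: i loads on topic i mod K_true with this effect size
    effect_size: float = 4.0
    treatment_weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        for t, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {t} must be in (0, 1), got {p}")

    def weights_for(self, treatment: str) -> np.ndarray:
        if self.treatment_weights and treatment in self.treatment_weights:
            return np.asarray(self.treatment_weights[treatment], dtype=float)
        w = np.zeros(self.K_true)
        w[TREATMENTS.index(treatment) % self.K_true] = self.effect_size
        return w


@dataclass
class GroundTruth:
    phi: np.ndarray  # K_true x V_emission planted topic-word probabilities
    emission_vocab: tuple[str, ...]
    theta: np.ndarray  # D x K_true
    doc_ids: list[str]
    synonym_clusters: list[tuple[str, str, str]]  # (canonical, sibling, cui)
    abbrev_map: dict[str, str]  # abbreviation surface -> canonical word
    name_spans: dict[str, list[tuple[int, int]]]
    syn_sub_prob: float
    labels: dict[str, list[str]] | None = None
    intercepts: dict[str, float] | None = None

    def effective_surface_phi(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Planted phi over realized surfaces, accounting for synonym swaps.

        A cluster canonical keeps (1 - p) of its mass; its sibling receives
        p. Abbreviations are expanded back at preprocessing time, so they
        move no mass.
        """
        sibling_of = {c: s for c, s, _ in self.synonym_clusters}
        surfaces = list(self.emission_vocab) + [s for _, s, _ in self.synonym_clusters]
        index = {w: i for i, w in enumerate(surfaces)}
        out = np.zeros((self.phi.shape[0], len(surfaces)))
        for j, w in enumerate(self.emission_vocab):
            if w in sibling_of:
                out[:, j] += (1.0 - self.syn_sub_prob) * self.phi[:, j]
                out[:, index[sibling_of[w]]] += self.syn_sub_prob * self.phi[:, j]
            else:
                out[:, j] += self.phi[:, j]
        return out, tuple(surfaces)

    def projected_phi(self, vocabulary, reduce=porter_stem) -> np.ndarray:
        """Planted topics projected onto a learned vocabulary via ``reduce``."""
        eff, surfaces = self.effective_surface_phi()
        col = {term: i for i, term in enumerate(vocabulary)}
        out = np.zeros((eff.shape[0], len(vocabulary)))
        for j, w in enumerate(surfaces):
            i = col.get(reduce(w))
            if i is not None:
                out[:, i] += eff[:, j]
        return out


def _pseudo_words(rng: np.random.Generator, n: int, taken_stems: set[str]) -> list[str]:
    """Pronounceable pseudo-words with pairwise-distinct Porter stems."""
    words: list[str] = []
    while len(words) < n:
        k = rng.integers(2, 5)
        word = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        stem = porter_stem(word)
        if word in DEFAULT_STOPWORDS or word in _TEMPLATE_WORDS or stem in taken_stems:
            continue
        taken_stems.add(stem)
        words.append(word)
    return words


def _bundled_lexicon_entries() -> list[LexEntry]:
    entries = []
    raw = resources.files("triage_lda.data").joinpath("concept_lexicon.tsv").read_text("utf-8")
    for line in raw.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, cui, semtype = line.split("\t")
        entries.append(LexEntry(tuple(term.lower().split()), cui, semtype))
    return entries


def _bundled_variant_entries() -> dict[str, str]:
    entries = {}
    raw = resources.files("triage_lda.data").joinpath("variant_lexicon.tsv").read_text("utf-8")
    for line in raw.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, canon = line.split("\t")
        entries[key.lower()] = canon.lower()
    return entries


def generate_lexicon(cfg: GeneratorConfig):
    """Build the concept and variant lexica plus the emission vocabulary.

    Returns (lexicon, variant_lexicon, core_words, clusters, abbrev_map).
    The concept lexicon always contains the bundled example clusters; the
    random synonym clusters are appended with invented concept ids.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    taken = {porter_stem(w) for w in _TEMPLATE_WORDS}
    core = _pseudo_words(rng, cfg.n_core_words, taken)
    cluster_surfaces = _pseudo_words(rng, 2 * cfg.n_synonym_clusters, taken)

    clusters: list[tuple[str, str, str]] = []
    entries = _bundled_lexicon_entries()
    for i in range(cfg.n_synonym_clusters):
        canonical = cluster_surfaces[2 * i]
        sibling = cluster_surfaces[2 * i + 1]
        cui = f"C9{i:05d}"
        semtype = _SEMTYPES[i % len(_SEMTYPES)]
        clusters.append((canonical, sibling, cui))
        entries.append(LexEntry((canonical,), cui, semtype))
        entries.append(LexEntry((sibling,), cui, semtype))

    variant_entries = _bundled_variant_entries()
    abbrev_map: dict[str, str] = {}
    candidates = [w for w in core if len(w) >= 6]
    chosen = rng.choice(len(candidates), size=min(cfg.n_abbreviations, len(candidates)), replace=False)
    for idx in sorted(chosen):
        word = candidates[idx]
        abbrev = word[:3] + "x"
        if abbrev in variant_entries or abbrev in taken:
            continue
        variant_entries[abbrev] = word
        abbrev_map[abbrev] = word

    return Lexicon(entries), VariantLexicon(variant_entries), core, clusters, abbrev_map


_FIRST_NAMES = ["Alva", "Brin", "Cora", "Dunn", "Elis", "Fenn", "Gale", "Hale",
                "Iona", "Jett", "Kira", "Lore", "Mave", "Nola", "Oren", "Pria"]
_LAST_NAMES = ["Ashford", "Bryce", "Calder", "Dray", "Emsley", "Fairburn",
               "Garrow", "Hollis", "Ibsen", "Jarvis", "Kemble", "Lathom",
               "Marwood", "Norcott", "Ogden", "Pelham"]
_HONORIFICS = ["Dr", "Mr", "Mrs", "Ms", "Miss", "Prof"]
_EPONYMS = ["McMurray test", "Baker cyst", "Hoffa fat pad", "Lachman test"]


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[RawLetter], GroundTruth]:
    """Draw a corpus from the planted topic model, wrapped in letter prose."""
    lexicon, variant_lex, core, clusters, abbrev_map = generate_lexicon(cfg)
    rng = np.random.default_rng([cfg.seed, 1])

    emission_vocab = tuple(core + [c for c, _, _ in clusters])
    V = len(emission_vocab)
    phi = rng.dirichlet(np.full(V, cfg.topic_word_concentration), size=cfg.K_true)
    theta = rng.dirichlet(np.full(cfg.K_true, cfg.alpha_true), size=cfg.D)

    sibling_of = {c: s for c, s, _ in clusters}
    word_to_abbrev = {w: a for a, w in abbrev_map.items()}

    letters: list[RawLetter] = []
    name_spans: dict[str, list[tuple[int, int]]] = {}
    doc_ids = [f"doc{d:04d}" for d in range(cfg.D)]

    for d in range(cfg.D):
        n_tokens = max(cfg.doc_len_min, int(rng.poisson(cfg.doc_len_mean)))
        z = rng.choice(cfg.K_true, size=n_tokens, p=theta[d])
        surfaces = []
        for k in z:
            w = emission_vocab[rng.choice(V, p=phi[k])]
            if w in sibling_of and rng.random() < cfg.syn_sub_prob:
                w = sibling_of[w]
            elif w in word_to_abbrev and rng.random() < cfg.abbrev_prob:
                w = word_to_abbrev[w]
            surfaces.append(w)

        # sentences of 8..14 tokens, occasional eponym phrase
        sentences = []
        i = 0
        while i < len(surfaces):
            step = int(rng.integers(8, 15))
            chunk = surfaces[i : i + step]
            if rng.random() < cfg.eponym_prob:
                chunk.append(_EPONYMS[int(rng.integers(len(_EPONYMS)))].lower())
            sentences.append(" ".join(chunk))
            i += step
        body = ". ".join(sentences) + "."

        hon = _HONORIFICS[int(rng.integers(len(_HONORIFICS)))]
        first = _FIRST_NAMES[int(rng.integers(len(_FIRST_NAMES)))]
        last = _LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]
        signer = f"Dr {_LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]}"

        opening = f"Dear {hon} {first} {last}, thank you for seeing this patient who presents with the following. "
        closing = f" Yours sincerely, {signer}."
        text = opening + body + closing

        spans = [
            (len("Dear "), len("Dear ") + len(f"{hon} {first} {last}")),
            (len(text) - len(closing) + len(" Yours sincerely, "), len(text) - 1),
        ]
        name_spans[doc_ids[d]] = spans
        letters.append(RawLetter(doc_ids[d], text))

    truth = GroundTruth(
        phi=phi,
        emission_vocab=emission_vocab,
        theta=theta,
        doc_ids=doc_ids,
        synonym_clusters=clusters,
        abbrev_map=abbrev_map,
        name_spans=name_spans,
        syn_sub_prob=cfg.syn_sub_prob,
    )
    return letters, truth


class CalibrationError(RuntimeError):
    """Raised when no intercept can reach the target prevalence."""


def generate_treatments(truth: GroundTruth, cfg: GeneratorConfig) -> dict[str, list[str]]:
    """Draw multi-label treatment outcomes from a logistic link on theta.

    Per treatment t, P(t | doc) = logistic(b_t + w_t . theta_doc); the
    intercept b_t is calibrated by root finding so the expected prevalence
    over the generated corpus matches the target within 0.005.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    labels: dict[str, list[str]] = {doc_id: [] for doc_id in truth.doc_ids}
    intercepts: dict[str, float] = {}
    for t in TREATMENTS:
        target = cfg.prevalences[t]
        w = truth.theta @ cfg.weights_for(t)

        def gap(b):
            return float(expit(b + w).mean()) - target

        try:
            b = brentq(gap, -40.0, 40.0, xtol=1e-12)
        except ValueError as exc:  # pragma: no cover - defensive
            raise CalibrationError(f"treatment {t}: cannot reach prevalence {target}") from exc
        if abs(gap(b)) > 0.005:
            raise CalibrationError(f"treatment {t}: calibration residual too large")
        intercepts[t] = float(b)
        draws = rng.random(len(truth.doc_ids)) < expit(b + w)
        for doc_id, hit in zip(truth.doc_ids, draws):
            if hit:
                labels[doc_id].append(t)
    truth.labels = labels
    truth.intercepts = intercepts
    return labels


def greedy_matched_cosine(planted: np.ndarray, learned: np.ndarray) -> float:
    """Mean cosine after greedily matching each planted topic to its best
    unused learned topic (rows of both matrices)."""

    def norm_rows(m):
        n = np.linalg.norm(m, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return m / n

    sims = norm_rows(planted) @ norm_rows(learned).T
    sims = sims.copy()
    total = 0.0
    for _ in range(min(sims.shape)):
        i, j = np.unravel_index(np.argmax(sims), sims.shape)
        total += sims[i, j]
        sims[i, :] = -np.inf
        sims[:, j] = -np.inf
    return total / min(planted.shape[0], learned.shape[0])
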