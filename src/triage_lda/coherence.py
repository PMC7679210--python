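"""Topic coherence over Boolean virtual documents.

Word and word-pair probabilities are presence counts over virtual
documents (the whole letter, a sentence, or a sliding window) divided by
the number of virtual documents. Pairwise primitives (PMI, NPMI, LCP) are
aggregated into the five topic-level measures C_UCI, C_NPMI, C_UMass,
C_cos and C_V.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .textprep import TokenStream
from .topic_model import TopicModel, fit_lda

FULL_DOC = "doc"
SENTENCE = "sentence"
# an integer window value means SLIDING(w)


class Measure(str, Enum):
    C_UCI = "c_uci"
    C_NPMI = "c_npmi"
    C_UMASS = "c_umass"
    C_COS = "c_cos"
    C_V = "c_v"


#: virtual-document policy per measure (literature defaults; the source
#: method names the Boolean-document idea but not the sizes)
DEFAULT_WINDOWS = {
    Measure.C_UCI: 10,
    Measure.C_NPMI: 10,
    Measure.C_UMASS: FULL_DOC,
    Measure.C_COS: 110,
    Measure.C_V: 110,
}


@dataclass
class CoocStats:
    n_vdocs: int
    df: dict[str, int]
    df2: dict[tuple[str, str], int]
    window: object
    eps: float = 1e-12

    def p(self, w: str) -> float:
        if w not in self.df:
            raise LookupError(f"word {w!r} not present in co-occurrence statistics")
        return self.df[w] / self.n_vdocs

    def p2(self, wi: str, wj: str) -> float:
        for w in (wi, wj):
            if w not in self.df:
                raise LookupError(f"word {w!r} not present in co-occurrence statistics")
        if wi == wj:  # a word always co-occurs with itself
            return self.df[wi] / self.n_vdocs
        key = (wi, wj) if wi <= wj else (wj, wi)
        return self.df2.get(key, 0) / self.n_vdocs


def _vdoc_token_lists(stream: TokenStream, window) -> Iterable[list[str]]:
    surfaces = stream.surfaces()
    if window == FULL_DOC:
        yield surfaces
    elif window == SENTENCE:
        bounds = [0, *stream.sentence_breaks, len(surfaces)]
        for s, e in zip(bounds, bounds[1:]):
            if e > s:
                yield surfaces[s:e]
    elif isinstance(window, int) and window >= 2:
        if len(surfaces) <= window:
            yield surfaces
        else:
            for i in range(len(surfaces) - window + 1):
                yield surfaces[i : i + window]
    else:
        raise ValueError(f"invalid window policy: {window!r}")


def build_cooc(
    streams: Sequence[TokenStream],
    window=FULL_DOC,
    restrict: set[str] | None = None,
    eps: float = 1e-12,
) -> CoocStats:
    """Count Boolean presence and co-presence over virtual documents.

    ``restrict`` limits counting to the given words (pairwise tables grow
    quadratically, so restricting to the words that will actually be scored
    keeps this cheap on sliding windows).
    """
    df: dict[str, int] = {}
    df2: dict[tuple[str, str], int] = {}
    n_vdocs = 0
    for stream in streams:
        for vdoc in _vdoc_token_lists(stream, window):
            n_vdocs += 1
            present = set(vdoc)
            if restrict is not None:
                present &= restrict
            for w in present:
                df[w] = df.get(w, 0) + 1
            for wi, wj in combinations(sorted(present), 2):
                df2[(wi, wj)] = df2.get((wi, wj), 0) + 1
    if n_vdocs == 0:
        raise ValueError("zero virtual documents")
    return CoocStats(n_vdocs, df, df2, window, eps)


def pmi(stats: CoocStats, wi: str, wj: str, eps: float | None = None) -> float:
    eps = stats.eps if eps is None else eps
    return math.log((stats.p2(wi, wj) + eps) / (stats.p(wi) * stats.p(wj)))


def npmi(stats: CoocStats, wi: str, wj: str, eps: float | None = None) -> float:
    eps = stats.eps if eps is None else eps
    joint = stats.p2(wi, wj) + eps
    if joint >= 1.0:  # perfect association: the measure's stated upper bound
        return 1.0
    return math.log(joint / (stats.p(wi) * stats.p(wj))) / (-math.log(joint))


def lcp(stats: CoocStats, wi: str, wj: str, eps: float | None = None) -> float:
    """Directed log-conditional probability log P(wi | wj)."""
    eps = stats.eps if eps is None else eps
    return math.log((stats.p2(wi, wj) + eps) / stats.p(wj))


@dataclass
class CoherenceConfig:
    measure: Measure | str = Measure.C_V
    top_n: int = 10
    window: object = None  # None -> per-measure default
    eps: float = 1e-12

    def __post_init__(self) -> None:
        self.measure = Measure(self.measure)
        if self.top_n < 2:
            raise ValueError("top_n must be >= 2")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.window is None:
            self.window = DEFAULT_WINDOWS[self.measure]


@dataclass
class CoherenceResult:
    measure: Measure
    per_topic: list[float]  # nan for undefined topics
    mean: float
    undefined_topics: list[int] = field(default_factory=list)


def _context_vectors(words: list[str], stats: CoocStats, eps: float) -> np.ndarray:
    """Row w_i holds NPMI(w_i, w_j) over the topic's own top words."""
    n = len(words)
    vecs = np.empty((n, n))
    for i, wi in enumerate(words):
        for j, wj in enumerate(words):
            vecs[i, j] = npmi(stats, wi, wj, eps)
    return vecs


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def score_word_set(words: list[str], stats: CoocStats, measure: Measure, eps: float) -> float:
    """Coherence of one ranked word list (descending rank order)."""
    if measure is Measure.C_UCI:
        return float(np.mean([pmi(stats, a, b, eps) for a, b in combinations(words, 2)]))
    if measure is Measure.C_NPMI:
        return float(np.mean([npmi(stats, a, b, eps) for a, b in combinations(words, 2)]))
    if measure is Measure.C_UMASS:
        # the lower-ranked word is conditioned on the higher-ranked one
        terms = [
            lcp(stats, words[j], words[i], eps)
            for i in range(len(words))
            for j in range(i + 1, len(words))
        ]
        return float(np.mean(terms))
    vecs = _context_vectors(words, stats, eps)
    if measure is Measure.C_COS:
        sims = [
            _cosine(vecs[i], vecs[j]) for i, j in combinations(range(len(words)), 2)
        ]
        return float(np.mean(sims))
    if measure is Measure.C_V:
        summed = vecs.sum(axis=0)
        return float(np.mean([_cosine(vecs[i], summed) for i in range(len(words))]))
    raise ValueError(f"unknown measure: {measure!r}")


def topic_coherence(
    model: TopicModel, stats: CoocStats, cfg: CoherenceConfig
) -> CoherenceResult:
    """Per-topic coherence and mean over topics with >= 2 usable words."""
    per_topic: list[float] = []
    undefined: list[int] = []
    for k in range(model.K):
        words = model.top_words(k, cfg.top_n)
        usable = [w for w in words if w in stats.df]
        if len(usable) < len(words):
            warnings.warn(
                f"topic {k}: {len(words) - len(usable)} top words missing from statistics"
            )
        if len(usable) < 2:
            per_topic.append(float("nan"))
            undefined.append(k)
            continue
        per_topic.append(score_word_set(usable, stats, cfg.measure, cfg.eps))
    defined = [v for v in per_topic if not math.isnan(v)]
    mean = float(np.mean(defined)) if defined else float("nan")
    return CoherenceResult(cfg.measure, per_topic, mean, undefined)


def stats_for_model(
    model: TopicModel,
    streams: Sequence[TokenStream],
    cfg: CoherenceConfig,
) -> CoocStats:
    """Co-occurrence statistics restricted to the model's top words."""
    top = set()
    for k in range(model.K):
        top.update(model.top_words(k, cfg.top_n))
    return build_cooc(streams, window=cfg.window, restrict=top, eps=cfg.eps)


@dataclass
class CoherenceKSelection:
    chosen_k: int
    grid: list[int]
    curve: dict[int, float]
    errors: dict[int, str] = field(default_factory=dict)
    flag: str | None = None


def select_k_by_coherence(
    bow,
    streams: Sequence[TokenStream],
    k_grid,
    cfg: CoherenceConfig | None = None,
    seeds: Sequence[int] = (0,),
    **fit_kwargs,
) -> CoherenceKSelection:
    """Fit one model per (K, seed); choose K maximizing mean coherence."""
    k_grid = list(k_grid)
    if len(k_grid) < 3:
        raise ValueError("k_grid must contain at least 3 values")
    cfg = CoherenceConfig() if cfg is None else cfg
    curve: dict[int, float] = {}
    errors: dict[int, str] = {}
    for k in k_grid:
        vals = []
        try:
            for s in seeds:
                model = fit_lda(bow, k, seed=s, **fit_kwargs)
                stats = stats_for_model(model, streams, cfg)
                vals.append(topic_coherence(model, stats, cfg).mean)
            curve[k] = float(np.mean(vals))
        except (ValueError, FloatingPointError) as exc:
            errors[k] = str(exc)
    if not curve:
        raise ValueError(f"every grid value failed: {errors}")
    ks = sorted(curve)
    vals = np.array([curve[k] for k in ks])
    if np.allclose(vals, vals[0]):
        return CoherenceKSelection(ks[0], k_grid, curve, errors, flag="constant_curve")
    chosen = ks[int(np.argmax(vals))]
    return CoherenceKSelection(chosen, k_grid, curve, errors)
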