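"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Estimates are posterior means over thinned post-burn-in samples by default
(``estimate="mean"``), or the final-state count estimate
(``estimate="final"``). Everything is reproducible from the seed: the same
seed yields bit-identical topic assignments, phi and theta.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import _gibbs
from .enrichment import BagOfWords


@dataclass
class TopicModel:
    K: int
    phi: np.ndarray  # K x V, rows on the simplex
    theta: np.ndarray  # D x K, rows on the simplex
    alpha: float
    beta: float
    vocabulary: tuple[str, ...]
    seed: int
    iterations: int
    burn_in: int
    doc_ids: list[str]
    word_marginal: np.ndarray  # empirical corpus p(w), length V
    empty_docs: list[str] = field(default_factory=list)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    def top_words(self, topic: int, n: int) -> list[str]:
        order = np.argsort(-self.phi[topic], kind="stable")[:n]
        return [self.vocabulary[i] for i in order]

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "K": self.K,
            "alpha": self.alpha,
            "beta": self.beta,
            "seed": self.seed,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "vocabulary": list(self.vocabulary),
            "doc_ids": self.doc_ids,
            "empty_docs": self.empty_docs,
        }
        (path / "meta.json").write_text(json.dumps(meta), "utf-8")
        # %.17g round-trips float64 exactly, keeping the layout plain text
        np.savetxt(path / "phi.txt", self.phi, fmt="%.17g")
        np.savetxt(path / "theta.txt", self.theta, fmt="%.17g")
        np.savetxt(path / "word_marginal.txt", self.word_marginal, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "TopicModel":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text("utf-8"))
        phi = np.loadtxt(path / "phi.txt", ndmin=2)
        theta = np.loadtxt(path / "theta.txt", ndmin=2)
        pw = np.loadtxt(path / "word_marginal.txt", ndmin=1)
        return cls(
            K=meta["K"],
            phi=phi,
            theta=theta,
            alpha=meta["alpha"],
            beta=meta["beta"],
            vocabulary=tuple(meta["vocabulary"]),
            seed=meta["seed"],
            iterations=meta["iterations"],
            burn_in=meta["burn_in"],
            doc_ids=meta["doc_ids"],
            word_marginal=pw,
            empty_docs=meta["empty_docs"],
        )


def _expand_tokens(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a count matrix into parallel (word, doc) token arrays."""
    docs_idx, words_idx = np.nonzero(counts)
    reps = counts[docs_idx, words_idx]
    return (
        np.repeat(words_idx, reps).astype(np.int64),
        np.repeat(docs_idx, reps).astype(np.int64),
    )


def fit_lda(
    bow: BagOfWords,
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    iterations: int = 1000,
    burn_in: int = 500,
    n_samples: int = 10,
    seed: int = 0,
    estimate: str = "mean",
) -> TopicModel:
    """Fit an LDA model to a bag of words by collapsed Gibbs sampling."""
    D, V = bow.counts.shape
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > V:
        raise ValueError(f"K={K} exceeds vocabulary size V={V}")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not iterations > burn_in >= 0:
        raise ValueError("require iterations > burn_in >= 0")
    if estimate not in ("mean", "final"):
        raise ValueError(f"unknown estimate: {estimate!r}")
    if bow.empty_docs:
        warnings.warn(
            f"excluding {len(bow.empty_docs)} all-zero documents: {bow.empty_docs}"
        )

    words, docs = _expand_tokens(bow.counts)
    n_tokens = words.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=n_tokens, dtype=np.int64)

    ndk = np.zeros((D, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (docs, z), 1)
    np.add.at(nkw, (z, words), 1)
    np.add.at(nk, z, 1)

    nd = bow.counts.sum(axis=1).astype(np.float64)
    phi_acc = np.zeros((K, V))
    theta_acc = np.zeros((D, K))
    taken = 0
    span = iterations - burn_in
    thin = max(1, span // n_samples)

    for it in range(iterations):
        _gibbs.sweep(words, docs, z, ndk, nkw, nk, float(alpha), float(beta), rng.random(n_tokens))
        if estimate == "mean" and it >= burn_in and (it - burn_in) % thin == thin - 1:
            phi_acc += (nkw + beta) / (nk + V * beta)[:, None]
            theta_acc += (ndk + alpha) / (nd + K * alpha)[:, None]
            taken += 1

    if estimate == "final" or taken == 0:
        phi = (nkw + beta) / (nk + V * beta)[:, None]
        theta = (ndk + alpha) / (nd + K * alpha)[:, None]
    else:
        phi = phi_acc / taken
        theta = theta_acc / taken

    # empty documents carry no evidence: their theta is the prior mean
    empty_rows = nd == 0
    theta[empty_rows] = 1.0 / K

    total = bow.counts.sum()
    word_marginal = bow.counts.sum(axis=0) / total
    return TopicModel(
        K=K,
        phi=phi,
        theta=theta,
        alpha=float(alpha),
        beta=float(beta),
        vocabulary=bow.vocabulary,
        seed=seed,
        iterations=iterations,
        burn_in=burn_in,
        doc_ids=list(bow.doc_ids),
        word_marginal=word_marginal,
        empty_docs=list(bow.empty_docs),
    )


def project_counts(model: TopicModel, doc) -> np.ndarray:
    """Project a document onto the model vocabulary (OOV tokens dropped).

    Accepts a length-V count vector, a mapping term -> count, or an
    iterable of token surfaces.
    """
    if isinstance(doc, np.ndarray):
        if doc.shape != (model.V,):
            raise ValueError("count vector length does not match vocabulary")
        return doc.astype(np.int64)
    if not isinstance(doc, dict):
        doc = Counter(doc)
    index = {t: i for i, t in enumerate(model.vocabulary)}
    vec = np.zeros(model.V, dtype=np.int64)
    for term, c in doc.items():
        j = index.get(term)
        if j is not None:
            vec[j] = c
    return vec


def infer_theta(
    model: TopicModel,
    doc,
    iterations: int = 200,
    burn_in: int = 100,
    n_samples: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Fold-in Gibbs inference of a topic distribution with phi frozen."""
    counts = project_counts(model, doc)
    K = model.K
    if counts.sum() == 0:
        warnings.warn("document empty after vocabulary projection; returning uniform")
        return np.full(K, 1.0 / K)
    words = np.repeat(np.nonzero(counts)[0], counts[np.nonzero(counts)[0]]).astype(np.int64)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    z = rng.integers(0, K, size=words.shape[0], dtype=np.int64)
    nd = np.zeros(K, dtype=np.int64)
    np.add.at(nd, z, 1)
    total = float(words.shape[0])

    acc = np.zeros(K)
    taken = 0
    thin = max(1, (iterations - burn_in) // n_samples)
    for it in range(iterations):
        _gibbs.sweep_doc(words, z, nd, model.phi, float(model.alpha), rng.random(words.shape[0]))
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            acc += (nd + model.alpha) / (total + K * model.alpha)
            taken += 1
    if taken == 0:
        return (nd + model.alpha) / (total + K * model.alpha)
    return acc / taken


def perplexity(model: TopicModel, bow: BagOfWords, theta: np.ndarray | None = None) -> float:
    """exp(-mean per-token log likelihood) with p(w|d) = theta_d . phi[:,w]."""
    if tuple(bow.vocabulary) != tuple(model.vocabulary):
        raise ValueError("bag of words vocabulary differs from model vocabulary")
    if theta is None:
        if bow.doc_ids == model.doc_ids:
            theta = model.theta
        else:
            theta = np.vstack([infer_theta(model, row) for row in bow.counts])
    pwd = theta @ model.phi  # D x V
    docs_idx, words_idx = np.nonzero(bow.counts)
    probs = pwd[docs_idx, words_idx]
    if np.any(probs <= 0):
        raise FloatingPointError("zero probability word despite smoothing")
    reps = bow.counts[docs_idx, words_idx]
    loglik = float(np.sum(reps * np.log(probs)))
    n_tokens = int(bow.counts.sum())
    return float(np.exp(-loglik / n_tokens))


class RankMode(str, Enum):
    PROBABILITY = "probability"
    LIFT = "lift"
    RELEVANCE = "relevance"


@dataclass
class RankedTopicWords:
    topic: int
    words: list[str]
    scores: np.ndarray  # non-increasing
    mode: RankMode
    lam: float


def rank_words(
    model: TopicModel,
    topic: int,
    n: int = 30,
    mode: RankMode | str = RankMode.RELEVANCE,
    lam: float = 0.6,
) -> RankedTopicWords:
    """Rank a topic's words by probability, lift, or lambda-relevance.

    relevance = lam * log(phi_kw) + (1 - lam) * log(phi_kw / p(w));
    lam=1 reduces to probability order, lam=0 to lift order.
    """
    mode = RankMode(mode)
    if mode is RankMode.PROBABILITY:
        lam = 1.0
    elif mode is RankMode.LIFT:
        lam = 0.0
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if n > model.V:
        raise ValueError(f"n={n} exceeds vocabulary size {model.V}")
    log_phi = np.log(model.phi[topic])
    log_lift = log_phi - np.log(model.word_marginal)
    scores = lam * log_phi + (1.0 - lam) * log_lift
    order = np.argsort(-scores, kind="stable")[:n]
    return RankedTopicWords(
        topic, [model.vocabulary[i] for i in order], scores[order], mode, lam
    )


@dataclass
class KSelection:
    chosen_k: int
    grid: list[int]
    scores: dict[int, float]
    rejected: list[int] = field(default_factory=list)
    flag: str | None = None


def select_k_by_perplexity(
    bow: BagOfWords,
    k_grid,
    seed: int = 0,
    holdout: float = 0.1,
    **fit_kwargs,
) -> KSelection:
    """Held-out perplexity per K; pick the elbow (max second difference)."""
    k_grid = list(k_grid)
    if len(k_grid) < 3:
        raise ValueError("k_grid must contain at least 3 values")
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    V = bow.n_terms
    rejected = [k for k in k_grid if k > V]
    k_grid = [k for k in k_grid if k <= V]
    if len(k_grid) < 3:
        raise ValueError(f"fewer than 3 usable grid values (rejected: {rejected})")

    rng = np.random.default_rng(seed)
    order = rng.permutation(bow.n_docs)
    n_test = max(1, int(round(holdout * bow.n_docs)))
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])

    def subset(idx):
        return BagOfWords(
            bow.vocabulary,
            bow.counts[idx],
            [bow.doc_ids[i] for i in idx],
            [bow.doc_ids[i] for i in idx if bow.counts[i].sum() == 0],
        )

    train, test = subset(train_idx), subset(test_idx)
    scores: dict[int, float] = {}
    for k in k_grid:
        model = fit_lda(train, k, seed=seed, **fit_kwargs)
        theta = np.vstack([infer_theta(model, row) for row in test.counts])
        scores[k] = perplexity(model, test, theta=theta)

    # elbow = point of maximum distance to the chord between the curve's
    # endpoints; on a strictly linear curve every distance is zero (no elbow)
    ks = np.asarray(k_grid, dtype=float)
    vals = np.array([scores[k] for k in k_grid])
    x0, y0, x1, y1 = ks[0], vals[0], ks[-1], vals[-1]
    dist = np.abs((y1 - y0) * ks - (x1 - x0) * vals + x1 * y0 - y1 * x0)
    dist /= np.hypot(y1 - y0, x1 - x0) if (x0, y0) != (x1, y1) else 1.0
    tol = 1e-9 * max(1.0, float(np.abs(vals).max()))
    if np.all(dist <= tol):
        return KSelection(k_grid[0], k_grid, scores, rejected, flag="no_elbow")
    chosen = k_grid[int(np.argmax(dist))]
    return KSelection(chosen, k_grid, scores, rejected)
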