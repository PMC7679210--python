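from dataclasses import dataclass

import numpy as np
import pytest

from triage_lda.enrichment import build_bow
from triage_lda.synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_lexicon,
    generate_treatments,
)
from triage_lda.textprep import prepare
from triage_lda.topic_model import TopicModel, fit_lda


@dataclass
class Bundle:
    cfg: GeneratorConfig
    letters: list
    truth: object
    labels: dict
    lexicon: object
    variant_lexicon: object
    streams: list
    bow: object


def _make_bundle(cfg: GeneratorConfig) -> Bundle:
    letters, truth = generate_corpus(cfg)
    labels = generate_treatments(truth, cfg)
    lexicon, vlex, _, _, _ = generate_lexicon(cfg)
    streams = [prepare(l, lex=vlex, mode="stem") for l in letters]
    return Bundle(cfg, letters, truth, labels, lexicon, vlex, streams, build_bow(streams))


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    cfg = GeneratorConfig(
        seed=11, K_true=4, D=80, n_core_words=150, n_synonym_clusters=6,
        n_abbreviations=5, doc_len_mean=50.0,
    )
    return _make_bundle(cfg)


@pytest.fixture(scope="session")
def small_model(small_bundle) -> TopicModel:
    return fit_lda(small_bundle.bow, 4, alpha=0.1, iterations=200, burn_in=100, seed=5)


def random_topic_model(rng: np.random.Generator, vocab: tuple[str, ...], K: int) -> TopicModel:
    """A syntactically valid model with random simplex rows (for coherence tests)."""
    V = len(vocab)
    phi = rng.dirichlet(np.ones(V) * 0.5, size=K)
    theta = rng.dirichlet(np.ones(K), size=3)
    pw = rng.dirichlet(np.ones(V))
    return TopicModel(
        K=K, phi=phi, theta=theta, alpha=0.1, beta=0.01, vocabulary=vocab,
        seed=0, iterations=0, burn_in=0, doc_ids=[f"d{i}" for i in range(3)],
        word_marginal=pw,
    )
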