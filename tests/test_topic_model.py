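import math

import numpy as np
import pytest

from triage_lda import _gibbs
from triage_lda.enrichment import BagOfWords
from triage_lda.synthetic import greedy_matched_cosine
from triage_lda.topic_model import (
    TopicModel,
    fit_lda,
    infer_theta,
    perplexity,
    rank_words,
    select_k_by_perplexity,
)

from conftest import random_topic_model


def _bow(counts, prefix="d"):
    counts = np.asarray(counts, dtype=np.int64)
    vocab = tuple(f"w{j}" for j in range(counts.shape[1]))
    ids = [f"{prefix}{i}" for i in range(counts.shape[0])]
    empty = [ids[i] for i in range(len(ids)) if counts[i].sum() == 0]
    return BagOfWords(vocab, counts, ids, empty)


def _planted_bow(rng, K, V, D, tokens_per_doc, alpha=0.1, conc=0.05):
    phi = rng.dirichlet(np.full(V, conc), size=K)
    theta = rng.dirichlet(np.full(K, alpha), size=D)
    counts = np.zeros((D, V), dtype=np.int64)
    for d in range(D):
        z = rng.choice(K, size=tokens_per_doc, p=theta[d])
        for k in z:
            counts[d, rng.choice(V, p=phi[k])] += 1
    return _bow(counts), phi, theta


class TestFitLda:
    def test_single_topic_corpus_k2(self):
        # corpus drawn from one topic; beta large enough that the sampler
        # cannot overfit multinomial noise into a fake second topic
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.full(50, 0.1))
        counts = rng.multinomial(60, phi, size=30)
        model = fit_lda(
            _bow(counts), 2, alpha=0.01, beta=5.0, iterations=400,
            burn_in=200, seed=1, estimate="final",
        )
        dominant = model.theta.argmax(axis=1)
        assert (dominant == dominant[0]).all()  # one and the same topic
        assert (model.theta.max(axis=1) >= 0.95).all()

    def test_planted_topics_recovered(self):
        rng = np.random.default_rng(7)
        bow, phi, _ = _planted_bow(rng, K=5, V=400, D=400, tokens_per_doc=80)
        model = fit_lda(bow, 5, alpha=0.1, iterations=300, burn_in=150, seed=2)
        assert greedy_matched_cosine(phi, model.phi) >= 0.9

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        bow, _, _ = _planted_bow(rng, K=3, V=60, D=40, tokens_per_doc=30)
        a = fit_lda(bow, 3, iterations=100, burn_in=50, seed=9)
        b = fit_lda(bow, 3, iterations=100, burn_in=50, seed=9)
        assert np.array_equal(a.phi, b.phi) and np.array_equal(a.theta, b.theta)

    def test_simplex_invariants(self, small_model):
        assert np.allclose(small_model.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(small_model.theta.sum(axis=1), 1.0, atol=1e-9)
        assert (small_model.phi > 0).all() and (small_model.theta > 0).all()

    def test_k_greater_than_v_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            fit_lda(_bow([[1, 1], [1, 1]]), 3, iterations=10, burn_in=5)

    def test_k_below_2_rejected(self):
        with pytest.raises(ValueError, match="K"):
            fit_lda(_bow([[1, 1], [1, 1]]), 1, iterations=10, burn_in=5)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            fit_lda(_bow([[1, 1], [1, 1]]), 2, iterations=5, burn_in=5)

    def test_empty_docs_excluded_with_warning(self):
        counts = [[3, 2, 1], [0, 0, 0], [1, 4, 2]]
        with pytest.warns(UserWarning, match="all-zero"):
            model = fit_lda(_bow(counts), 2, iterations=50, burn_in=10, seed=0)
        assert model.empty_docs == ["d1"]
        assert np.allclose(model.theta[1], 0.5)

    def test_save_load_bit_exact(self, small_model, tmp_path):
        small_model.save(tmp_path / "m")
        loaded = TopicModel.load(tmp_path / "m")
        assert np.array_equal(loaded.phi, small_model.phi)
        assert np.array_equal(loaded.theta, small_model.theta)
        assert loaded.vocabulary == small_model.vocabulary
        assert loaded.alpha == small_model.alpha


class TestInferTheta:
    def test_training_doc_self_consistency(self, small_bundle, small_model):
        rows = [0, 5, 17]
        for d in rows:
            theta = infer_theta(small_model, small_bundle.bow.counts[d], seed=42)
            tv = 0.5 * np.abs(theta - small_model.theta[d]).sum()
            assert tv <= 0.15

    def test_empty_doc_uniform(self, small_model):
        with pytest.warns(UserWarning, match="empty"):
            theta = infer_theta(small_model, np.zeros(small_model.V, dtype=np.int64))
        assert np.allclose(theta, 1.0 / small_model.K)

    def test_pure_topic_doc(self):
        rng = np.random.default_rng(11)
        bow, phi, _ = _planted_bow(rng, K=4, V=200, D=150, tokens_per_doc=60)
        model = fit_lda(bow, 4, alpha=0.1, iterations=300, burn_in=150, seed=4)
        # build a doc from the single planted topic best matching learned topic 0
        sims = (phi / np.linalg.norm(phi, axis=1, keepdims=True)) @ (
            model.phi[0] / np.linalg.norm(model.phi[0])
        )
        k_planted = int(np.argmax(sims))
        doc = np.zeros(model.V, dtype=np.int64)
        for w in rng.choice(200, size=60, p=phi[k_planted]):
            doc[w] += 1
        theta = infer_theta(model, doc, seed=1)
        assert theta[0] >= 0.8

    def test_simplex(self, small_model):
        theta = infer_theta(small_model, np.ones(small_model.V, dtype=np.int64))
        assert abs(theta.sum() - 1.0) < 1e-9


class TestPerplexity:
    def test_uniform_model_equals_v(self):
        V, K, D = 30, 3, 5
        vocab = tuple(f"w{j}" for j in range(V))
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 4, size=(D, V)).astype(np.int64)
        model = TopicModel(
            K=K, phi=np.full((K, V), 1.0 / V), theta=rng.dirichlet(np.ones(K), D),
            alpha=0.1, beta=0.01, vocabulary=vocab, seed=0, iterations=0,
            burn_in=0, doc_ids=[f"d{i}" for i in range(D)],
            word_marginal=np.full(V, 1.0 / V),
        )
        bow = BagOfWords(vocab, counts, model.doc_ids)
        assert perplexity(model, bow) == pytest.approx(V, abs=1e-9)

    def test_deterministic_model_equals_one(self):
        vocab = ("w0", "w1")
        model = TopicModel(
            K=2, phi=np.array([[1.0, 0.0], [0.0, 1.0]]),
            theta=np.array([[1.0, 0.0]]), alpha=0.1, beta=0.01,
            vocabulary=vocab, seed=0, iterations=0, burn_in=0,
            doc_ids=["d0"], word_marginal=np.array([1.0, 0.0]),
        )
        bow = BagOfWords(vocab, np.array([[7, 0]], dtype=np.int64), ["d0"])
        assert perplexity(model, bow) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        vocab = tuple(f"w{j}" for j in range(12))
        model = random_topic_model(rng, vocab, K=3)
        counts = rng.integers(0, 5, size=(3, 12)).astype(np.int64)
        bow = BagOfWords(vocab, counts, model.doc_ids)
        # independent token-by-token summation
        loglik, n = 0.0, 0
        for d in range(3):
            for j in range(12):
                for _ in range(counts[d, j]):
                    p = sum(model.theta[d, k] * model.phi[k, j] for k in range(3))
                    loglik += math.log(p)
                    n += 1
        expected = math.exp(-loglik / n)
        assert perplexity(model, bow) == pytest.approx(expected, rel=1e-10)


class TestRankWords:
    def test_lambda_one_is_probability_order(self, small_model):
        ranked = rank_words(small_model, 0, n=10, mode="relevance", lam=1.0)
        by_phi = rank_words(small_model, 0, n=10, mode="probability")
        assert ranked.words == by_phi.words

    def test_lambda_zero_is_lift_order(self, small_model):
        ranked = rank_words(small_model, 0, n=10, mode="relevance", lam=0.0)
        lift = small_model.phi[0] / small_model.word_marginal
        order = np.argsort(-lift, kind="stable")[:10]
        assert ranked.words == [small_model.vocabulary[i] for i in order]

    def test_hand_computed_toy(self):
        vocab = ("a", "b", "c", "d", "e")
        phi = np.array([[0.4, 0.3, 0.15, 0.1, 0.05]])
        pw = np.array([0.5, 0.1, 0.15, 0.05, 0.2])
        model = TopicModel(
            K=1, phi=phi, theta=np.array([[1.0]]), alpha=0.1, beta=0.01,
            vocabulary=vocab, seed=0, iterations=0, burn_in=0,
            doc_ids=["d0"], word_marginal=pw,
        )
        lam = 0.6
        expected = {
            w: lam * math.log(phi[0][i]) + (1 - lam) * math.log(phi[0][i] / pw[i])
            for i, w in enumerate(vocab)
        }
        ranked = rank_words(model, 0, n=5, mode="relevance", lam=lam)
        assert ranked.words == sorted(vocab, key=lambda w: -expected[w])
        for w, s in zip(ranked.words, ranked.scores):
            assert s == pytest.approx(expected[w], rel=1e-12)
        assert (np.diff(ranked.scores) <= 1e-15).all()

    def test_n_exceeding_v_rejected(self, small_model):
        with pytest.raises(ValueError, match="vocabulary"):
            rank_words(small_model, 0, n=small_model.V + 1)

    def test_bad_lambda_rejected(self, small_model):
        with pytest.raises(ValueError, match="lambda"):
            rank_words(small_model, 0, n=5, mode="relevance", lam=1.5)


class TestSelectKByPerplexity:
    def test_returns_grid_value(self):
        rng = np.random.default_rng(13)
        bow, _, _ = _planted_bow(rng, K=3, V=80, D=60, tokens_per_doc=40)
        sel = select_k_by_perplexity(
            bow, [2, 3, 4, 5], seed=0, alpha=0.1, iterations=80, burn_in=40
        )
        assert sel.chosen_k in [2, 3, 4, 5]
        assert set(sel.scores) == {2, 3, 4, 5}
        assert all(v > 0 for v in sel.scores.values())

    def test_small_grid_rejected(self):
        bow = _bow([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="at least 3"):
            select_k_by_perplexity(bow, [2], seed=0, iterations=10, burn_in=5)

    def test_unsorted_grid_rejected(self):
        bow = _bow([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="sorted"):
            select_k_by_perplexity(bow, [4, 2, 3], seed=0, iterations=10, burn_in=5)

    def test_oversized_k_reported(self):
        rng = np.random.default_rng(1)
        bow, _, _ = _planted_bow(rng, K=2, V=6, D=30, tokens_per_doc=10)
        sel = select_k_by_perplexity(
            bow, [2, 3, 4, 9], seed=0, iterations=40, burn_in=20
        )
        assert sel.rejected == [9]

    def test_linear_curve_flagged(self, monkeypatch):
        import triage_lda.topic_model as tm

        rng = np.random.default_rng(2)
        bow, _, _ = _planted_bow(rng, K=2, V=20, D=30, tokens_per_doc=10)
        fake_scores = {2: 100.0, 3: 90.0, 4: 80.0, 5: 70.0}
        monkeypatch.setattr(tm, "fit_lda", lambda b, k, **kw: k)
        monkeypatch.setattr(tm, "infer_theta", lambda m, row: np.array([1.0]))
        monkeypatch.setattr(tm, "perplexity", lambda m, b, theta=None: fake_scores[m])
        sel = tm.select_k_by_perplexity(bow, [2, 3, 4, 5], seed=0)
        assert sel.flag == "no_elbow"
        assert sel.chosen_k == 2


class TestGibbsKernels:
    def test_python_and_compiled_sweeps_agree(self):
        rng = np.random.default_rng(0)
        D, V, K, N = 4, 10, 3, 60
        words = rng.integers(0, V, N).astype(np.int64)
        docs = rng.integers(0, D, N).astype(np.int64)
        z0 = rng.integers(0, K, N).astype(np.int64)
        uniforms = rng.random(N)

        def run(sweep):
            z = z0.copy()
            ndk = np.zeros((D, K), np.int64)
            nkw = np.zeros((K, V), np.int64)
            nk = np.zeros(K, np.int64)
            np.add.at(ndk, (docs, z), 1)
            np.add.at(nkw, (z, words), 1)
            np.add.at(nk, z, 1)
            sweep(words, docs, z, ndk, nkw, nk, 0.5, 0.01, uniforms)
            return z

        assert np.array_equal(run(_gibbs._sweep_python), run(_gibbs.sweep))

    def test_against_independent_reference_sampler(self):
        """Posterior mean phi from an independently coded collapsed Gibbs
        sampler agrees within Monte-Carlo tolerance (TV <= 0.05 per topic)."""
        rng = np.random.default_rng(21)
        K, V, D = 2, 6, 30
        planted_phi = np.array(
            [[0.3, 0.3, 0.3, 0.03, 0.03, 0.04],
             [0.04, 0.03, 0.03, 0.3, 0.3, 0.3]]
        )
        theta = rng.dirichlet([0.3, 0.3], size=D)
        counts = np.zeros((D, V), dtype=np.int64)
        for d in range(D):
            z = rng.choice(K, size=12, p=theta[d])
            for k in z:
                counts[d, rng.choice(V, p=planted_phi[k])] += 1
        bow = _bow(counts)
        alpha, beta = 0.5, 0.01

        model = fit_lda(
            bow, K, alpha=alpha, beta=beta, iterations=2000, burn_in=1000,
            n_samples=50, seed=3,
        )

        # --- independent reference: different code path and RNG stream ---
        ref_rng = np.random.default_rng(99)
        tokens = [
            (d, w)
            for d in range(D)
            for w in range(V)
            for _ in range(counts[d, w])
        ]
        z = [int(ref_rng.integers(K)) for _ in tokens]
        ndk = np.zeros((D, K)); nkw = np.zeros((K, V)); nk = np.zeros(K)
        for (d, w), k in zip(tokens, z):
            ndk[d, k] += 1; nkw[k, w] += 1; nk[k] += 1
        phi_acc = np.zeros((K, V)); taken = 0
        for it in range(2000):
            for t, (d, w) in enumerate(tokens):
                k = z[t]
                ndk[d, k] -= 1; nkw[k, w] -= 1; nk[k] -= 1
                p = (ndk[d] + alpha) * (nkw[:, w] + beta) / (nk + V * beta)
                k = int(ref_rng.choice(K, p=p / p.sum()))
                z[t] = k
                ndk[d, k] += 1; nkw[k, w] += 1; nk[k] += 1
            if it >= 1000 and it % 20 == 19:
                phi_acc += (nkw + beta) / (nk + V * beta)[:, None]
                taken += 1
        ref_phi = phi_acc / taken

        # match topics (label switching) then compare total variation
        if np.abs(model.phi[0] - ref_phi[0]).sum() > np.abs(model.phi[0] - ref_phi[1]).sum():
            ref_phi = ref_phi[::-1]
        for k in range(K):
            tv = 0.5 * np.abs(model.phi[k] - ref_phi[k]).sum()
            assert tv <= 0.05
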