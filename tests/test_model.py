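"""Network forward/backward, both losses, gradients and the training loop."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ddxrank import (
    DiseaseRanker,
    GeneratorConfig,
    LossConfig,
    RankingModel,
    ScoredList,
    TrainConfig,
    approx_ndcg_loss,
    approx_positions,
    generate_corpus,
    gradient,
    mse_loss,
    ndcg,
    train,
)

TINY = GeneratorConfig(
    n_diseases=8, n_symptoms=24, n_cases=40, n_differentials=(2, 3), seed=2
)


# ---------------------------------------------------------------------------
# forward


class TestForward:
    def test_zero_input_is_biases_through_the_network(self):
        m = RankingModel(6, 4, hidden_dim=5, seed=3)
        m.b1 = np.linspace(-1, 1, 5)
        m.b2 = np.linspace(0, 1, 4)
        expected = np.maximum(m.b1, 0.0) @ m.W2 + m.b2
        np.testing.assert_allclose(m.forward(np.zeros(6)), expected, atol=1e-12)

    def test_deterministic_and_correct_length(self):
        m = RankingModel(6, 4, seed=0)
        x = np.zeros(6)
        x[[1, 3]] = 1.0
        out = m.forward(x)
        assert out.shape == (4,)
        np.testing.assert_array_equal(out, m.forward(x))

    def test_dimension_mismatch_rejected(self):
        m = RankingModel(6, 4)
        with pytest.raises(ValueError):
            m.forward(np.zeros(7))

    def test_same_seed_same_init(self):
        a, b = RankingModel(6, 4, seed=9), RankingModel(6, 4, seed=9)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)


# ---------------------------------------------------------------------------
# approx_positions


class TestApproxPositions:
    def test_equal_scores_give_mean_rank(self):
        np.testing.assert_allclose(approx_positions(np.zeros(3), 10.0), [2, 2, 2])

    def test_sum_conservation(self, rng):
        for alpha in (0.1, 1.0, 10.0, 1e4):
            for _ in range(50):
                n = int(rng.integers(1, 12))
                pi = approx_positions(rng.normal(size=n), alpha)
                assert pi.sum() == pytest.approx(n * (n + 1) / 2, abs=1e-9)
                assert np.all(pi >= 1 - 1e-9) and np.all(pi <= n + 1e-9)

    def test_large_alpha_recovers_true_ranks(self, rng):
        scores = np.array([0.3, -1.2, 2.5, 0.9])
        true_ranks = np.array([3, 4, 1, 2])
        np.testing.assert_allclose(
            approx_positions(scores, 1e4), true_ranks, atol=1e-3
        )


# ---------------------------------------------------------------------------
# losses


class TestApproxNDCGLoss:
    def test_single_relevant_item(self):
        sl = ScoredList(np.array([0.7]), np.array([2.0]))
        assert approx_ndcg_loss(sl) == pytest.approx(-1.0)

    def test_all_zero_labels_policy(self):
        sl = ScoredList(np.array([1.0, -1.0]), np.zeros(2))
        assert approx_ndcg_loss(sl) == 0.0

    @pytest.mark.parametrize("standardize", [True, False])
    def test_bounded_in_minus_one_zero(self, rng, standardize):
        cfg = LossConfig(alpha=5.0, standardize=standardize)
        for _ in range(100):
            n = int(rng.integers(2, 10))
            sl = ScoredList(rng.normal(size=n), np.abs(rng.normal(size=n)))
            loss = approx_ndcg_loss(sl, cfg)
            assert -1.0 - 1e-9 <= loss <= 0.0

    @pytest.mark.parametrize("standardize", [True, False])
    def test_limit_agreement_with_exact_ndcg(self, rng, standardize):
        cfg = LossConfig(alpha=1e4, standardize=standardize)
        for _ in range(100):
            sl = ScoredList(rng.normal(size=6), np.abs(rng.normal(size=6)))
            assert -approx_ndcg_loss(sl, cfg) == pytest.approx(ndcg(sl), abs=1e-3)


class TestMSELoss:
    def test_zero_at_perfect_fit(self):
        y = np.array([1.0, 3.0, 0.0])
        assert mse_loss(ScoredList(y.copy(), y)) == 0.0

    def test_hand_computed(self):
        assert mse_loss(ScoredList(np.zeros(2), np.array([1.0, 3.0]))) == pytest.approx(5.0)

    def test_quadratic_homogeneity(self, rng):
        s, y = rng.normal(size=5), np.abs(rng.normal(size=5))
        c = 3.7
        assert mse_loss(ScoredList(c * s, c * y)) == pytest.approx(
            c**2 * mse_loss(ScoredList(s, y))
        )


# ---------------------------------------------------------------------------
# gradients


def finite_difference(loss_fn, sl: ScoredList, h: float = 1e-5) -> np.ndarray:
    g = np.zeros(len(sl))
    for i in range(len(sl)):
        up, dn = sl.scores.copy(), sl.scores.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (
            loss_fn(ScoredList(up, sl.labels)) - loss_fn(ScoredList(dn, sl.labels))
        ) / (2 * h)
    return g


class TestGradient:
    def test_mse_gradient_zero_at_minimum(self):
        y = np.array([1.0, 2.0, 0.5])
        g = gradient(ScoredList(y.copy(), y), LossConfig(loss="mse"))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_mse_gradient_closed_form(self, rng):
        s, y = rng.normal(size=7), np.abs(rng.normal(size=7))
        g = gradient(ScoredList(s, y), LossConfig(loss="mse"))
        np.testing.assert_allclose(g, 2 * (s - y) / 7, atol=1e-12)

    @pytest.mark.parametrize(
        "loss_cfg,loss_fn",
        [
            (
                LossConfig(loss="approx_ndcg", alpha=10.0, standardize=True),
                lambda sl: approx_ndcg_loss(sl, LossConfig(alpha=10.0, standardize=True)),
            ),
            (
                LossConfig(loss="approx_ndcg", alpha=10.0, standardize=False),
                lambda sl: approx_ndcg_loss(sl, LossConfig(alpha=10.0, standardize=False)),
            ),
            (LossConfig(loss="mse"), mse_loss),
        ],
        ids=["approx_ndcg", "approx_ndcg_raw", "mse"],
    )
    def test_matches_finite_differences(self, rng, loss_cfg, loss_fn):
        worst = 0.0
        for _ in range(20):
            s = rng.normal(size=6)
            y = np.abs(rng.normal(size=6))
            y[rng.integers(6)] = 0.0
            sl = ScoredList(s, y)
            analytic = gradient(sl, loss_cfg)
            numeric = finite_difference(loss_fn, sl)
            rel = np.linalg.norm(analytic - numeric, np.inf) / max(
                np.linalg.norm(numeric, np.inf), 1e-12
            )
            worst = max(worst, rel)
        assert worst < 1e-4


# ---------------------------------------------------------------------------
# training loop


class TestTraining:
    def test_bit_reproducible_under_fixed_seed(self):
        corpus = generate_corpus(TINY)
        cfg = TrainConfig(epochs=3, seed=4)
        m1, c1 = train(corpus, LossConfig(), cfg)
        m2, c2 = train(corpus, LossConfig(), cfg)
        for p1, p2 in zip(m1.parameters, m2.parameters):
            np.testing.assert_array_equal(p1, p2)
        assert c1.train_ndcg == c2.train_ndcg

    def test_listwise_training_reduces_its_loss(self):
        corpus = generate_corpus(TINY)
        ranker = DiseaseRanker(corpus, LossConfig(), TrainConfig(epochs=10, seed=0))
        res = ranker.fit()
        assert res.curves.train_ndcg[-1] > res.curves.train_ndcg[0]

    def test_separable_corpus_is_recoverable(self):
        from ddxrank import separable_config, topk_report

        corpus = generate_corpus(separable_config(n_diseases=5, n_cases=60, seed=7))
        res = DiseaseRanker(
            corpus,
            LossConfig(alpha=1.0),
            TrainConfig(epochs=150, seed=0),
        ).fit()
        assert res.curves.train_ndcg[-1] >= 0.99

    def test_divergence_raises_naming_epoch(self):
        corpus = generate_corpus(TINY)
        cfg = TrainConfig(epochs=10, optimizer="sgd", learning_rate=1e150, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(FloatingPointError, match="epoch"):
                DiseaseRanker(corpus, LossConfig(loss="mse"), cfg).fit()

    def test_empty_corpus_rejected(self, tiny_corpus):
        from ddxrank import CaseCorpus

        empty = CaseCorpus(tiny_corpus.symptom_vocab, tiny_corpus.disease_vocab, ())
        with pytest.raises(ValueError):
            DiseaseRanker(empty)

    def test_early_stopping_keeps_best_validation_model(self):
        corpus = generate_corpus(TINY)
        res = DiseaseRanker(
            corpus,
            LossConfig(),
            TrainConfig(epochs=40, seed=1, early_stopping_patience=3),
        ).fit()
        assert len(res.curves.epochs) <= 40

    def test_summary_mentions_loss_and_dimensions(self):
        corpus = generate_corpus(TINY)
        res = DiseaseRanker(corpus, LossConfig(), TrainConfig(epochs=2, seed=0)).fit()
        text = res.summary()
        assert "approx_ndcg" in text and "24 -> 64" in text and "ndcg" in text

    def test_curves_export(self, tmp_path):
        corpus = generate_corpus(TINY)
        _, curves = train(corpus, LossConfig(), TrainConfig(epochs=2, seed=0))
        curves.to_csv(tmp_path / "curves.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "curves.csv")
        assert set(df.columns) == {"split", "epoch", "ndcg", "mse"}
        assert set(df["split"]) == {"train", "validation"}


# ---------------------------------------------------------------------------
# serialization


class TestSerialization:
    def test_round_trip_preserves_scores(self, tmp_path):
        corpus = generate_corpus(TINY)
        res = DiseaseRanker(corpus, LossConfig(), TrainConfig(epochs=2, seed=0)).fit()
        path = tmp_path / "model.json"
        res.save(path)
        loaded = RankingModel.load(
            path, corpus.symptom_vocab, corpus.disease_vocab
        )
        x = np.zeros(TINY.n_symptoms)
        x[:3] = 1.0
        np.testing.assert_allclose(loaded.forward(x), res.model.forward(x))

    def test_refuses_mismatched_vocabulary(self, tmp_path, tiny_corpus):
        corpus = generate_corpus(TINY)
        res = DiseaseRanker(corpus, LossConfig(), TrainConfig(epochs=1, seed=0)).fit()
        path = tmp_path / "model.json"
        res.save(path)
        with pytest.raises(ValueError, match="vocabulary"):
            RankingModel.load(path, tiny_corpus.symptom_vocab, None)
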