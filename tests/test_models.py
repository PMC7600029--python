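import numpy as np
import pytest

from crystalbone.embeddings import (
    CodeEmbedding,
    CodeEmbeddingConfig,
    WindowEmbeddingConfig,
    train_window_embedding,
)
from crystalbone.evaluation import auroc
from crystalbone.lstm import LSTMClassifier, LSTMConfig
from crystalbone.models import (
    predict,
    static_features,
    train_baseline,
    train_ensemble,
    train_gbdt,
    train_lstm,
)
from crystalbone.windows import Vocabulary
from tests.test_windows import toy_window


class TestLSTMGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Analytic BPTT gradients agree with central finite differences."""
        cfg = LSTMConfig(hidden=4, static_hidden=3, merge_hidden=3, seed=1)
        net = LSTMClassifier(input_dim=3, static_dim=2, config=cfg)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 6, 3))
        S = rng.normal(size=(5, 2))
        y = rng.integers(0, 2, 5).astype(float)
        _, grads = net.loss_and_grads(X, S, y)
        eps = 1e-6
        for name in ("Wx", "Wh", "b", "Ws", "Wm", "w", "b0"):
            P = net.params[name]
            flat = P.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, S, y)
                flat[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, S, y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


def _toy_embedding(tokens, dim=6, seed=0):
    rng = np.random.default_rng(seed)
    vocab = Vocabulary({t: 9 for t in tokens}, min_count=1)
    matrix = np.vstack([np.zeros((2, dim)), rng.normal(size=(len(tokens), dim))])
    return CodeEmbedding(vocab, matrix.astype(np.float32), CodeEmbeddingConfig(dim=dim))


def _labeled_windows(n=60, seed=0, signal_token="W:sig"):
    """Positive windows carry the signal token; negatives never do."""
    rng = np.random.default_rng(seed)
    tokens = [f"W:b{i}" for i in range(8)]
    wins = []
    for i in range(n):
        label = i % 2 == 0
        codes = list(rng.choice(tokens, size=10))
        if label:
            codes += [signal_token] * 3
        wins.append(toy_window(f"p{i}", label, codes, age=float(60 + rng.integers(0, 20))))
    return wins, tokens + [signal_token]


class TestTrainLSTM:
    def test_learns_a_separating_token_and_is_seed_deterministic(self):
        wins, tokens = _labeled_windows(n=80, seed=1)
        emb = _toy_embedding(tokens)
        cfg = LSTMConfig(hidden=8, static_hidden=4, merge_hidden=4, epochs=20,
                         batch_size=16, lr=5e-3, seed=2)
        m1 = train_lstm(wins, emb, cfg, max_len=16, seed=2)
        m2 = train_lstm(wins, emb, cfg, max_len=16, seed=2)
        p1 = m1.predict_proba(wins)
        p2 = m2.predict_proba(wins)
        assert np.array_equal(p1, p2)
        assert auroc(p1, [w.label for w in wins]) > 0.9

    def test_empty_and_single_class_training_sets_error(self):
        wins, tokens = _labeled_windows(n=10)
        emb = _toy_embedding(tokens)
        with pytest.raises(ValueError):
            train_lstm([], emb)
        with pytest.raises(ValueError):
            train_lstm([w for w in wins if w.label], emb)


@pytest.fixture(scope="module")
def dbow_model():
    tokens = [f"W:b{i}" for i in range(8)] + ["W:sig"]
    corpus = [list(np.random.default_rng(i).choice(tokens, 12)) for i in range(30)]
    vocab = Vocabulary({t: 30 for t in tokens}, min_count=1)
    return train_window_embedding(
        corpus, vocab, WindowEmbeddingConfig(dim=8, epochs=10, subsample=0, seed=4)
    )


class TestTrainGBDT:
    def test_perfectly_separating_feature_gives_full_training_recall(self, dbow_model):
        wins, _ = _labeled_windows(n=60, seed=3)
        for w in wins:  # dx_count separates classes exactly (13 vs 10)
            assert (w.dx_count == 13) == w.label
        model = train_gbdt(wins, dbow_model, seed=0)
        preds = predict(model, wins)
        flagged_pos = [p for p, w in zip(preds, wins) if w.label]
        assert all(p.flag for p in flagged_pos)

    def test_feature_table_width_is_vector_dim_plus_three(self, dbow_model):
        wins, _ = _labeled_windows(n=20, seed=5)
        model = train_gbdt(wins, dbow_model, seed=0)
        F = model.featurize(wins)
        assert F.shape == (20, dbow_model.config.dim + 3)


class TestBaselines:
    def test_two_feature_baseline_never_sees_dx_count(self):
        wins, _ = _labeled_windows(n=40, seed=6)
        model = train_baseline(wins, ("age", "sex"), seed=0)
        assert model.booster.n_features_in_ == 2
        assert model.kind == "baseline_age_sex"

    def test_three_feature_baseline_learns_separating_count(self):
        wins, _ = _labeled_windows(n=60, seed=7)
        model = train_baseline(wins, ("age", "sex", "dx_count"), seed=0)
        assert auroc(model.predict_proba(wins), [w.label for w in wins]) > 0.95

    def test_unknown_feature_rejected(self):
        wins, _ = _labeled_windows(n=10)
        with pytest.raises(ValueError):
            train_baseline(wins, ("age", "height"))


class TestEnsemble:
    def test_coefficients_recovered_from_known_logistic(self, rng):
        n = 20000
        p1 = rng.random(n)
        p2 = rng.random(n)
        logit = -1.0 + 3.0 * p1 + 1.5 * p2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        model = train_ensemble(p1, p2, y)
        assert model.coef_[0] == pytest.approx(3.0, abs=0.25)
        assert model.coef_[1] == pytest.approx(1.5, abs=0.25)

    def test_identical_bases_leave_ranking_unchanged(self, rng):
        p = rng.random(300)
        y = (p + rng.normal(0, 0.3, 300) > 0.6).astype(int)
        model = train_ensemble(p, p + 1e-9 * rng.random(300), y)
        combined = model.predict_from_probs(p, p)
        assert auroc(combined, y) == pytest.approx(auroc(p, y), abs=1e-6)
        assert np.all((combined >= 0) & (combined <= 1))

    def test_constant_base_probabilities_error(self):
        with pytest.raises(ValueError):
            train_ensemble([0.5] * 10, list(np.linspace(0, 1, 10)), [0, 1] * 5)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        wins, _ = _labeled_windows(n=50, seed=9)
        return train_baseline(wins, ("age", "sex", "dx_count"), seed=1), wins

    def test_order_permutation_permutes_output(self, fitted, rng):
        model, wins = fitted
        perm = rng.permutation(len(wins))
        base = predict(model, wins)
        shuffled = predict(model, [wins[i] for i in perm])
        for j, i in enumerate(perm):
            assert shuffled[j].probability == base[i].probability

    def test_flag_equals_threshold_rule(self, fitted):
        model, wins = fitted
        for p in predict(model, wins):
            assert p.flag == (p.probability >= model.threshold)

    def test_batch_matches_single_window_predictions(self, fitted):
        model, wins = fitted
        batch = model.predict_proba(wins[:10])
        singles = [model.predict_proba([w])[0] for w in wins[:10]]
        assert np.allclose(batch, singles)

    def test_probabilities_in_unit_interval(self, fitted):
        model, wins = fitted
        probs = model.predict_proba(wins)
        assert np.all((probs >= 0) & (probs <= 1))


class TestStaticFeatures:
    def test_sex_encoding_and_column_order(self):
        wins = [
            toy_window("p1", False, sex="female"),
            toy_window("p2", False, sex="male"),
            toy_window("p3", False, sex="unknown"),
        ]
        F = static_features(wins)
        assert F[:, 1].tolist() == [0.0, 1.0, 0.5]
        assert F.shape == (3, 3)
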