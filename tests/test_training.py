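"""Objective, optimisation loop, evaluation, reproducibility."""

import numpy as np
import pytest

from spikewav import ModelConfig, TrainConfig, build_model, evaluate, loss, train, \
    train_test_split
from spikewav.autodiff import Tensor, sigmoid


@pytest.fixture(scope="module")
def toy_data():
    """Tiny linearly-separable encoded windows: class differs by map side."""
    rng = np.random.default_rng(17)
    n = 24
    x = rng.random((n, 2, 1, 16, 16)).astype(np.float32) * 0.1
    y = np.array([i % 2 for i in range(n)])
    x[y == 0, :, :, :, :8] += 0.8
    x[y == 1, :, :, :, 8:] += 0.8
    return x, y


def toy_cfg(**kw):
    base = dict(t_steps=2, n_blocks=1, d=8, patch_grid=4, heads=2, mlp_ratio=2,
                grid=16, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestLoss:
    def test_uniform_scores_give_ln2(self):
        scores = Tensor(np.zeros((4, 2)))
        assert float(loss(scores, np.array([0, 1, 0, 1])).data) == pytest.approx(np.log(2))

    def test_confident_correct_scores_drive_loss_to_zero(self):
        scores = Tensor(np.array([[20.0, 0.0], [0.0, 20.0]]))
        assert float(loss(scores, np.array([0, 1])).data) < 1e-6

    def test_zero_penalty_weight_equals_pure_cross_entropy(self, rng):
        scores = Tensor(rng.normal(size=(6, 2)))
        labels = rng.integers(0, 2, 6)
        coeffs = [Tensor(rng.normal(size=(2, 3)))]
        assert float(loss(scores, labels, coeffs, 0.0).data) == pytest.approx(
            float(loss(scores, labels).data)
        )

    def test_penalty_adds_l1_of_coefficients(self, rng):
        scores = Tensor(np.zeros((2, 2)))
        labels = np.array([0, 1])
        coeffs = [Tensor(np.array([[1.0, -2.0]])), Tensor(np.array([[0.5]]))]
        expected = np.log(2) + 0.1 * 3.5
        assert float(loss(scores, labels, coeffs, 0.1).data) == pytest.approx(expected)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            loss(Tensor(np.zeros((2, 2))), np.array([0, 2]))


class TestSplit:
    def test_stratified_and_deterministic(self):
        y = np.array([0] * 30 + [1] * 30)
        x = np.arange(60)[:, None]
        xtr, ytr, xte, yte = train_test_split(x, y, 0.2, seed=4)
        assert len(yte) == 12 and (yte == 0).sum() == 6
        xtr2, _, xte2, _ = train_test_split(x, y, 0.2, seed=4)
        np.testing.assert_array_equal(xte, xte2)
        assert set(xtr.ravel()) | set(xte.ravel()) == set(range(60))


class TestTrainLoop:
    def test_one_epoch_smoke(self, toy_data):
        x, y = toy_data
        model = build_model(toy_cfg())
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0, val_fraction=0.25)
        _, hist = train(model, x[:8], y[:8], cfg)
        assert len(hist.train_loss) == 1
        assert np.isfinite(hist.train_loss[0])

    def test_same_seed_reproduces_history_exactly(self, toy_data):
        x, y = toy_data
        cfg = TrainConfig(epochs=2, batch_size=8, seed=3, val_fraction=0.25)
        _, h1 = train(build_model(toy_cfg(seed=3)), x, y, cfg)
        _, h2 = train(build_model(toy_cfg(seed=3)), x, y, cfg)
        assert h1.as_dict() == h2.as_dict()

    def test_loss_decreases_on_separable_toy(self, toy_data):
        x, y = toy_data
        model = build_model(toy_cfg(seed=1))
        cfg = TrainConfig(epochs=8, batch_size=8, seed=1, lr=1e-3, val_fraction=0.0)
        _, hist = train(model, x, y, cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(toy_cfg()), np.zeros((0, 2, 1, 16, 16)), np.zeros(0),
                  TrainConfig())


class TestEvaluate:
    def test_perfect_and_per_class_identity(self, toy_data, monkeypatch):
        x, y = toy_data
        model = build_model(toy_cfg())
        monkeypatch.setattr(model, "predict", lambda b: np.zeros(len(b), dtype=int))
        res = evaluate(model, x, y)
        # all-zero predictor: class 0 perfect, class 1 never; overall = mean
        assert res.per_class[0] == 1.0 and res.per_class[1] == 0.0
        weights = [np.mean(y == c) for c in (0, 1)]
        overall = sum(w * res.per_class[c] for c, w in enumerate(weights))
        assert res.accuracy == pytest.approx(overall)

    def test_empty_dataset_rejected(self, toy_data):
        model = build_model(toy_cfg())
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 2, 1, 16, 16)), np.zeros(0, dtype=int))

    def test_random_predictor_near_chance(self, rng):
        preds = rng.integers(0, 2, 2000)
        labels = rng.integers(0, 2, 2000)
        acc = np.mean(preds == labels)
        assert abs(acc - 0.5) < 0.04  # ~3 sigma binomial bound


class TestGradientSanity:
    def test_surrogate_relaxed_toy_network_matches_finite_differences(self):
        # 2-neuron toy: x -> w1 -> sigmoid surrogate -> w2 -> squared loss.
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 2))
        target = rng.normal(size=(5, 1))
        w1_0 = rng.normal(size=(2, 2))
        w2_0 = rng.normal(size=(2, 1))

        def loss_value(w1v, w2v):
            w1, w2 = Tensor(w1v, requires_grad=True), Tensor(w2v, requires_grad=True)
            h = sigmoid(Tensor(x) @ w1 * 4.0)  # relaxed spike nonlinearity
            out = h @ w2
            return ((out - Tensor(target)) ** 2).mean(), w1, w2

        l, w1, w2 = loss_value(w1_0, w2_0)
        l.backward()
        eps = 1e-6
        for wt, w0 in ((w1, w1_0), (w2, w2_0)):
            num = np.zeros_like(w0)
            it = np.nditer(w0, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                up, dn = w0.copy(), w0.copy()
                up[i] += eps
                dn[i] -= eps
                a = (up, w2_0) if wt is w1 else (w1_0, up)
                b = (dn, w2_0) if wt is w1 else (w1_0, dn)
                num[i] = (float(loss_value(*a)[0].data) - float(loss_value(*b)[0].data)) / (
                    2 * eps
                )
            rel = np.abs(wt.grad - num).max() / max(1e-12, np.abs(num).max())
            assert rel < 1e-3
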