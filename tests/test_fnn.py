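import numpy as np
import pytest

from fnnsweep.evaluation import roc_auc
from fnnsweep.fnn import (DimensionError, HyperParams, NetworkParams, activate,
                          backward, effective_lr, forward, init_params,
                          load_checkpoint, loss, predict, save_checkpoint,
                          sgd_update, train)
from fnnsweep.gradcheck import (max_relative_error, numerical_gradients,
                                random_small_configs)


class TestHyperParams:
    def test_base_values_are_study_defaults(self):
        hp = HyperParams()
        assert (hp.output_activation, hp.weight_initializer) == ("sigmoid", "glorot_normal")
        assert (hp.n_hidden_layers, hp.hidden_width) == (2, 75)
        assert (hp.learning_rate, hp.momentum, hp.decay) == (0.005, 0.9, 0.01)
        assert (hp.dropout_rate, hp.epochs, hp.batch_size) == (0.5, 100, 10)
        assert (hp.l1, hp.l2) == (0.0, 0.008)

    @pytest.mark.parametrize("kwargs", [
        {"output_activation": "tanh"}, {"weight_initializer": "he_normal"},
        {"momentum": 1.0}, {"dropout_rate": 1.0}, {"learning_rate": 0.0},
        {"decay": -0.1}, {"epochs": 0}, {"n_hidden_layers": 0}, {"l1": -1e-9},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HyperParams(**kwargs)

    def test_layer_size_chain(self):
        assert HyperParams(n_hidden_layers=3).layer_sizes(31) == [31, 75, 75, 75, 1]


class TestInitializers:
    def test_glorot_normal_sd_matches_formula(self):
        params = init_params([31, 75], "glorot_normal", seed=0)
        # single layer has only 2325 entries; pool many seeds for 1e5 draws
        draws = np.concatenate([
            init_params([31, 75], "glorot_normal", seed=s).weights[0].ravel()
            for s in range(50)])
        assert draws.size >= 1e5
        assert draws.std() == pytest.approx(np.sqrt(2 / 106), rel=0.02)
        assert abs(draws.mean()) < 0.005
        assert params.biases[0].sum() == 0

    def test_lecun_uniform_bound(self):
        w = init_params([75, 10], "lecun_uniform", seed=1).weights[0]
        assert np.all(np.abs(w) <= 0.2)  # sqrt(3/75) = 0.2
        assert np.abs(w).max() > 0.18  # actually fills the range

    @pytest.mark.parametrize("scheme,bound", [("uniform", 0.05), ("glorot_uniform", np.sqrt(6 / 85))])
    def test_uniform_schemes_bounded_and_centered(self, scheme, bound):
        w = init_params([75, 10], scheme, seed=2).weights[0]
        assert np.all(np.abs(w) <= bound)
        assert abs(w.mean()) < bound / 10

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown initializer"):
            init_params([4, 1], "xavier", seed=0)

    def test_velocities_zero_and_shape_matched(self):
        p = init_params([5, 3, 1], "normal", seed=3)
        for v, w in zip(p.velocities_w, p.weights):
            assert v.shape == w.shape and not v.any()


class TestActivations:
    def test_closed_form_values(self):
        assert activate(0.0, "sigmoid") == 0.5
        assert activate(0.0, "hard_sigmoid") == 0.5
        assert activate(-2.0, "relu") == 0.0
        assert activate(3.0, "relu") == 3.0
        assert activate(3.0, "hard_sigmoid") == 1.0  # 0.2*3+0.5 clipped
        assert activate(-3.0, "hard_sigmoid") == 0.0

    def test_hard_sigmoid_linear_on_ramp(self):
        x = np.linspace(-2.4, 2.4, 9)
        np.testing.assert_allclose(activate(x, "hard_sigmoid"), 0.2 * x + 0.5)

    def test_sigmoid_stable_at_extremes(self):
        assert activate(1000.0, "sigmoid") == 1.0
        assert activate(-1000.0, "sigmoid") == 0.0


class TestForward:
    def test_dropout_zero_training_equals_inference(self):
        hp = HyperParams(dropout_rate=0.0)
        p = init_params(hp.layer_sizes(6), "glorot_normal", 0)
        X = np.random.default_rng(0).normal(size=(10, 6))
        a = forward(p, X, hp, training=True, rng=np.random.default_rng(1))
        b = forward(p, X, hp, training=False)
        np.testing.assert_array_equal(a["p"], b["p"])

    def test_zero_network_outputs_half(self):
        hp = HyperParams(dropout_rate=0.0)
        p = init_params(hp.layer_sizes(4), "glorot_normal", 0)
        for w in p.weights:
            w[:] = 0
        X = np.random.default_rng(2).normal(size=(7, 4))
        np.testing.assert_array_equal(forward(p, X, hp)["p"], 0.5)

    def test_inverted_dropout_preserves_expectation(self):
        hp = HyperParams(dropout_rate=0.5, n_hidden_layers=1, hidden_width=50)
        p = init_params(hp.layer_sizes(5), "glorot_normal", 3)
        X = np.random.default_rng(4).normal(size=(4, 5))
        ref = np.maximum(X @ p.weights[0] + p.biases[0], 0.0)
        rng = np.random.default_rng(5)
        reps = 10_000
        acc = np.zeros_like(ref)
        for _ in range(reps):
            acc += forward(p, X, hp, training=True, rng=rng)["h"][1]
        mean = acc / reps
        # per-unit Monte-Carlo SE of the inverted-dropout mean
        se = np.abs(ref) / np.sqrt(reps)  # Var(mask) = (1-q)/q with q=0.5 -> sd = |a|
        active = ref > 0
        assert np.all(np.abs(mean - ref)[active] < 4 * se[active] + 1e-12)

    def test_shape_mismatch_names_layer(self):
        hp = HyperParams()
        p = init_params(hp.layer_sizes(6), "glorot_normal", 0)
        with pytest.raises(DimensionError, match="layer 0"):
            forward(p, np.zeros((3, 5)), hp)


class TestLoss:
    def test_perfect_predictions_near_zero(self):
        hp = HyperParams(l1=0, l2=0)
        p = init_params([2, 1], "normal", 0)
        y = np.array([0.0, 1.0, 1.0])
        assert loss(y, y, hp, p) < 1e-6

    def test_uninformative_predictions_ln2(self):
        hp = HyperParams(l1=0, l2=0)
        p = init_params([2, 1], "normal", 0)
        assert loss(np.array([0, 1, 0, 1]), np.full(4, 0.5), hp, p) == pytest.approx(np.log(2))

    def test_l2_penalty_adds_exactly(self):
        p = init_params([3, 2, 1], "normal", 1)
        ssq = sum(float(np.sum(w * w)) for w in p.weights)
        y = np.array([0, 1.0])
        probs = np.array([0.3, 0.7])
        base = loss(y, probs, HyperParams(l1=0, l2=0), p)
        with_l2 = loss(y, probs, HyperParams(l1=0, l2=0.1), p)
        assert with_l2 - base == pytest.approx(0.1 * ssq, rel=1e-12)

    def test_length_mismatch_rejected(self):
        p = init_params([2, 1], "normal", 0)
        with pytest.raises(DimensionError):
            loss(np.array([0, 1]), np.array([0.5]), HyperParams(), p)


class TestBackward:
    def test_single_layer_sigmoid_equals_logistic_regression(self):
        # one affine layer + sigmoid: grad = X^T (p - y) / n
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20).astype(float)
        w = rng.normal(size=(3, 1))
        params = NetworkParams([w.copy()], [np.array([0.1])])
        hp = HyperParams(l1=0, l2=0, dropout_rate=0)
        cache = {"z": [X @ w + 0.1], "h": [X], "masks": [],
                 "p": activate(X @ w + 0.1, "sigmoid")}
        gw, gb = backward(params, cache, y, hp)
        p = cache["p"].ravel()
        np.testing.assert_allclose(gw[0], (X.T @ (p - y)).reshape(3, 1) / 20, rtol=1e-10)
        np.testing.assert_allclose(gb[0], [(p - y).mean()], rtol=1e-10)

    def test_gradient_matches_finite_differences(self):
        worst = 0.0
        for params, X, y, hp in random_small_configs(8, seed=3):
            cache = forward(params, X, hp)
            gw, gb = backward(params, cache, y, hp)
            nw, nb = numerical_gradients(params, X, y, hp)
            worst = max(worst, max_relative_error(gw, gb, nw, nb))
        assert worst < 1e-5

    def test_dropout_mask_reapplied_on_backward(self):
        hp = HyperParams(dropout_rate=0.5, n_hidden_layers=1, hidden_width=6,
                         l1=0, l2=0)
        p = init_params(hp.layer_sizes(4), "glorot_normal", 7)
        X = np.random.default_rng(8).normal(size=(5, 4))
        y = np.random.default_rng(9).integers(0, 2, 5).astype(float)
        cache = forward(p, X, hp, training=True, rng=np.random.default_rng(10))
        gw, _ = backward(p, cache, y, hp)
        dropped = cache["masks"][0].sum(axis=0) == 0  # unit dropped in every case
        assert np.all(gw[0][:, dropped] == 0)


class TestSgdUpdate:
    def _one_param(self, w0):
        return NetworkParams([np.array([[w0]])], [np.zeros(1)])

    def test_vanilla_step_without_momentum_or_decay(self):
        p = self._one_param(1.0)
        hp = HyperParams(momentum=0.0, decay=0.0, learning_rate=0.1)
        sgd_update(p, [np.array([[2.0]])], [np.zeros(1)], hp, iteration=0)
        assert p.weights[0][0, 0] == pytest.approx(1.0 - 0.1 * 2.0)

    def test_decay_schedule_values(self):
        hp = HyperParams(learning_rate=0.1, decay=0.01)
        assert effective_lr(hp, 0) == pytest.approx(0.1)
        assert effective_lr(hp, 100) == pytest.approx(0.05)

    def test_momentum_accumulates_velocity(self):
        p = self._one_param(0.0)
        hp = HyperParams(momentum=0.9, decay=0.0, learning_rate=0.1)
        g = [np.array([[1.0]])]
        zb = [np.zeros(1)]
        sgd_update(p, g, zb, hp, 0)
        first = p.weights[0][0, 0]
        sgd_update(p, g, zb, hp, 1)
        second = p.weights[0][0, 0] - first
        assert first == pytest.approx(-0.1)
        assert second == pytest.approx(1.9 * -0.1)  # v = 0.9*(-0.1) - 0.1

    def test_non_finite_gradient_raises(self):
        from fnnsweep.fnn import DivergenceError
        p = self._one_param(0.0)
        with pytest.raises(DivergenceError):
            sgd_update(p, [np.array([[np.inf]])], [np.zeros(1)], HyperParams(), 0)


class TestTrain:
    def test_deterministic_end_to_end(self, small_dataset, fast_hp):
        X, y = small_dataset.features, small_dataset.labels
        p1, h1 = train(X, y, fast_hp, seed=11)
        p2, h2 = train(X, y, fast_hp, seed=11)
        assert all(np.array_equal(a, b) for a, b in zip(p1.weights, p2.weights))
        assert h1.losses == h2.losses

    def test_separable_toy_loss_decreases(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1],
                      [3, 3], [3, 4], [4, 3], [4, 4]], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        hp = HyperParams(epochs=200, learning_rate=0.1, batch_size=8,
                         momentum=0.0, decay=0.0, dropout_rate=0.0, l2=0.0,
                         n_hidden_layers=1, hidden_width=4)
        _, hist = train(X, y, hp, seed=1)
        assert hist.losses[-1] < hist.losses[0]

    def test_memorizes_pure_noise(self, noise_dataset):
        # enough capacity + epochs drives training AUC toward 1 even though
        # the true AUC ceiling is 0.5 — overfitting is inducible
        hp = HyperParams(epochs=2000, batch_size=32, learning_rate=0.01,
                         momentum=0.9, decay=0.0, dropout_rate=0.0,
                         l1=0.0, l2=0.0, n_hidden_layers=2, hidden_width=32)
        X, y = noise_dataset.features, noise_dataset.labels
        params, _ = train(X, y, hp, seed=2)
        assert roc_auc(y, predict(params, X, hp)) > 0.95

    def test_effective_lr_trace_non_increasing(self, small_dataset):
        hp = HyperParams(epochs=5, decay=0.01, batch_size=16, hidden_width=4,
                         n_hidden_layers=1, dropout_rate=0.0)
        _, hist = train(small_dataset.features, small_dataset.labels, hp, seed=0)
        assert all(a >= b for a, b in zip(hist.effective_lr, hist.effective_lr[1:]))

    def test_zero_decay_lr_constant(self, small_dataset):
        hp = HyperParams(epochs=4, decay=0.0, batch_size=32, hidden_width=4,
                         n_hidden_layers=1, dropout_rate=0.0)
        _, hist = train(small_dataset.features, small_dataset.labels, hp, seed=0)
        assert len(set(hist.effective_lr)) == 1

    def test_l2_shrinks_weights(self, small_dataset):
        X, y = small_dataset.features, small_dataset.labels
        norms = []
        for l2 in (0.0, 0.01, 0.1):
            hp = HyperParams(epochs=10, batch_size=16, l2=l2, dropout_rate=0.0,
                             hidden_width=8, n_hidden_layers=1, decay=0.0)
            params, _ = train(X, y, hp, seed=3)
            norms.append(params.sum_sq_weights())
        assert norms[0] > norms[1] > norms[2]

    def test_oversized_batch_clamped_with_warning(self, small_dataset, fast_hp, caplog):
        hp = fast_hp.with_(batch_size=10_000, epochs=1)
        with caplog.at_level("WARNING", logger="fnnsweep.fnn"):
            train(small_dataset.features, small_dataset.labels, hp, seed=0)
        assert any("clamped" in r.message for r in caplog.records)

    def test_empty_training_set_rejected(self, fast_hp):
        with pytest.raises(ValueError, match="empty"):
            train(np.empty((0, 3)), np.empty(0), fast_hp, seed=0)

    def test_epoch_decay_mode_counts_epochs(self, small_dataset):
        hp = HyperParams(epochs=3, decay=0.5, batch_size=16, hidden_width=4,
                         n_hidden_layers=1, dropout_rate=0.0, decay_mode="epoch")
        _, hist = train(small_dataset.features, small_dataset.labels, hp, seed=0)
        expected = [0.005 / (1 + 0.5 * t) for t in range(3)]
        np.testing.assert_allclose(hist.effective_lr, expected)


class TestPredict:
    def test_values_in_unit_interval(self, small_dataset, fast_hp):
        params, _ = train(small_dataset.features, small_dataset.labels, fast_hp, 0)
        p = predict(params, small_dataset.features, fast_hp)
        assert np.all((p >= 0) & (p <= 1))

    def test_monotone_in_positive_weight_input(self):
        w = np.array([[2.0]])
        params = NetworkParams([w], [np.zeros(1)])
        hp = HyperParams()
        outs = predict(params, np.array([[0.0], [1.0], [2.0]]), hp)
        assert outs[0] < outs[1] < outs[2]

    def test_inference_ignores_dropout(self, small_dataset):
        hp = HyperParams(dropout_rate=0.9, epochs=2, batch_size=32,
                         hidden_width=8, n_hidden_layers=1)
        params, _ = train(small_dataset.features, small_dataset.labels, hp, 1)
        a = predict(params, small_dataset.features, hp)
        b = predict(params, small_dataset.features, hp)
        np.testing.assert_array_equal(a, b)


class TestCheckpoint:
    def test_exact_round_trip(self, tmp_path, small_dataset, fast_hp):
        params, _ = train(small_dataset.features, small_dataset.labels, fast_hp, 5)
        path = tmp_path / "model.json"
        save_checkpoint(params, fast_hp, path)
        loaded, hp2 = load_checkpoint(path)
        assert hp2 == fast_hp
        for a, b in zip(params.weights, loaded.weights):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(params.biases, loaded.biases):
            np.testing.assert_array_equal(a, b)
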