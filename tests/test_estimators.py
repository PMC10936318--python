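"""Linear regression, model construction, training engine, prediction."""

import numpy as np
import pytest

import sockgait as sg
from sockgait import nn


class TestFitLinear:
    def test_exact_recovery_and_r2_one(self, rng):
        X = rng.standard_normal((500, 12))
        W = rng.standard_normal((12, 2))
        b = np.array([1.5, -0.5])
        Y = b + X @ W
        model = sg.fit_linear(X, Y)
        np.testing.assert_allclose(model.coef[0], b, atol=1e-8)
        np.testing.assert_allclose(model.coef[1:], W, atol=1e-8)
        m = sg.metrics(Y, model.predict(X))
        np.testing.assert_allclose(m["r2"], 1.0, atol=1e-12)

    def test_independent_noise_targets_r2_near_zero(self, rng):
        X = rng.standard_normal((10_000, 12))
        Y = rng.standard_normal((10_000, 2))
        Xte = rng.standard_normal((10_000, 12))
        Yte = rng.standard_normal((10_000, 2))
        model = sg.fit_linear(X, Y)
        m = sg.metrics(Yte, model.predict(Xte))
        assert np.all(np.abs(m["r2"]) < 0.05)

    def test_matches_lstsq_oracle_on_random_problems(self, rng):
        for _ in range(5):
            X = rng.standard_normal((50, 6))
            Y = rng.standard_normal((50, 2))
            model = sg.fit_linear(X, Y)
            D = np.hstack([np.ones((50, 1)), X])
            oracle, *_ = np.linalg.lstsq(D, Y, rcond=None)
            np.testing.assert_allclose(model.coef, oracle, atol=1e-8)

    def test_rank_deficiency_names_collinear_channel(self, rng):
        X = rng.standard_normal((100, 4))
        X[:, 3] = 2.0 * X[:, 1]  # exact collinearity
        with pytest.raises(sg.RankDeficientError) as exc:
            sg.fit_linear(X, rng.standard_normal((100, 2)),
                          feature_names=("a", "b", "c", "twice_b"))
        assert any(ch in {"b", "twice_b"} for ch in exc.value.channels)

    def test_too_few_rows_raise(self, rng):
        with pytest.raises(sg.ConfigError):
            sg.fit_linear(rng.standard_normal((10, 12)), rng.standard_normal((10, 2)))


class TestBuildModel:
    def test_base_lstm_layer_sequence(self):
        model = sg.build_model(sg.lstm_base_spec(60))
        kinds = [type(l).__name__ for l in model.layers]
        assert kinds == ["LSTM", "LSTM", "Dropout", "Dense"]
        assert model.layers[0].units == 128 and model.layers[0].return_sequences
        assert model.layers[1].units == 64 and not model.layers[1].return_sequences
        assert model.layers[2].rate == 0.3
        assert model.layers[3].units == 2

    def test_best_lstm_units(self):
        model = sg.build_model(sg.lstm_best_spec(90))
        assert [model.layers[0].units, model.layers[1].units] == [64, 32]
        assert model.layers[2].rate == 0.2

    def test_base_cnn_layer_sequence(self):
        model = sg.build_model(sg.cnn_base_spec(60))
        kinds = [type(l).__name__ for l in model.layers]
        assert kinds == ["ConvTime", "ConvTime", "MaxPoolTime", "ConvTime",
                         "ConvTime", "Flatten", "Dense", "Dense"]
        assert [l.filters for l in model.layers if isinstance(l, nn.ConvTime)] == \
            [50, 50, 100, 100]
        assert model.layers[-1].units == 2

    def test_param_count_pure_function_of_spec(self):
        a = sg.build_model(sg.lstm_best_spec(40), seed=0)
        b = sg.build_model(sg.lstm_best_spec(40), seed=99)
        assert a.num_params() == b.num_params() > 0

    def test_dense_param_count_formula(self):
        spec = sg.ModelSpec("cnn", (
            {"flatten": True}, {"dense": 7, "activation": "relu"}, {"dense": 2},
        ), input_n=5)
        model = sg.build_model(spec)
        assert model.num_params() == (5 * 12 + 1) * 7 + (7 + 1) * 2

    def test_oversized_kernel_names_layer(self):
        spec = sg.ModelSpec("cnn", (
            {"conv": 4, "kernel": 9}, {"flatten": True}, {"dense": 2},
        ), input_n=5)
        with pytest.raises(sg.ModelShapeError, match="layer0"):
            sg.build_model(spec)

    def test_output_layer_must_be_size_two(self):
        with pytest.raises(sg.ConfigError):
            sg.ModelSpec("lstm", ({"lstm": 8}, {"dense": 3}), input_n=10)


class TestEngineGradients:
    """Analytic backprop against central finite differences (L2 surrogate)."""

    @pytest.mark.parametrize("stack", ["lstm", "cnn"])
    def test_gradients_match_numerical(self, stack, rng):
        if stack == "lstm":
            model = nn.Sequential(
                [nn.LSTM(5, return_sequences=True), nn.LSTM(4), nn.Dense(2)],
                (8, 12), seed=1,
            )
        else:
            model = nn.Sequential(
                [nn.ConvTime(6, 3), nn.MaxPoolTime(2),
                 nn.ConvTime(4, 3, activation="leaky_relu"), nn.Flatten(),
                 nn.Dense(5, activation="relu"), nn.Dense(2)],
                (8, 12), seed=2,
            )
        x = rng.standard_normal((4, 8, 12))
        y = rng.standard_normal((4, 2))
        model.backward(model.forward(x) - y)
        for li, k, p in model.parameters():
            g = model.layers[li].grads[k]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp = 0.5 * np.sum((model.forward(x) - y) ** 2)
            p[idx] = orig - eps
            lm = 0.5 * np.sum((model.forward(x) - y) ** 2)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTraining:
    def _toy_frames(self, rng, M=400, N=12):
        X = rng.standard_normal((M, 12, N))
        Y = np.stack([X[:, 0, -1], -X[:, 1, -1]], axis=1)
        return (X[:300], Y[:300]), (X[300:], Y[300:])

    def test_lr_schedule_endpoints(self):
        cfg = sg.TrainConfig(epochs=40)
        assert cfg.lr_at(0) == pytest.approx(0.05)
        assert cfg.lr_at(39) == pytest.approx(0.04)
        lrs = [cfg.lr_at(e) for e in range(40)]
        assert all(a >= b for a, b in zip(lrs[:-1], lrs[1:]))

    def test_checkpoint_keeps_min_validation_loss(self, rng):
        tr, va = self._toy_frames(rng)
        model = sg.build_model(
            sg.ModelSpec("lstm", ({"lstm": 8}, {"dense": 2}), input_n=12), seed=0
        )
        hist = sg.train(model, tr, va, sg.TrainConfig(epochs=5, seed=0))
        assert hist["best_val"] == min(hist["val_loss"])
        assert hist["lr"] == [sg.TrainConfig(epochs=5).lr_at(e) for e in range(5)]
        # restored weights reproduce the checkpointed validation loss
        pred = sg.predict(model, va[0])
        assert np.mean(np.abs(pred - va[1])) == pytest.approx(hist["best_val"], abs=1e-9)

    def test_training_beats_untrained_model(self, rng):
        tr, va = self._toy_frames(rng)
        model = sg.build_model(
            sg.ModelSpec("lstm", ({"lstm": 8}, {"dense": 2}), input_n=12), seed=0
        )
        before = float(np.mean(np.abs(sg.predict(model, va[0]) - va[1])))
        hist = sg.train(model, tr, va, sg.TrainConfig(epochs=6, seed=0))
        assert hist["best_val"] < before

    def test_training_is_seeded_reproducible(self, rng):
        tr, va = self._toy_frames(rng)
        outs = []
        for _ in range(2):
            model = sg.build_model(
                sg.ModelSpec("lstm", ({"lstm": 6}, {"dense": 2}), input_n=12), seed=3
            )
            sg.train(model, tr, va, sg.TrainConfig(epochs=3, seed=3))
            outs.append(sg.predict(model, va[0]))
        assert np.array_equal(outs[0], outs[1])

    def test_empty_partition_raises(self, rng):
        tr, _ = self._toy_frames(rng)
        model = sg.build_model(
            sg.ModelSpec("lstm", ({"lstm": 4}, {"dense": 2}), input_n=12)
        )
        with pytest.raises(sg.ConfigError):
            sg.train(model, tr, (tr[0][:0], tr[1][:0]), sg.TrainConfig(epochs=1))


class TestPredict:
    def test_bitwise_deterministic_with_dropout_layer(self, rng):
        model = sg.build_model(sg.lstm_best_spec(10), seed=1)
        X = rng.standard_normal((20, 12, 10))
        assert np.array_equal(sg.predict(model, X), sg.predict(model, X))

    def test_window_mismatch_raises(self, rng):
        model = sg.build_model(sg.lstm_best_spec(10), seed=1)
        with pytest.raises(sg.ConfigError):
            sg.predict(model, rng.standard_normal((4, 12, 11)))

    def test_denormalization_roundtrip(self, rng):
        y = rng.standard_normal((2, 50)) * 12 + 3
        sc = sg.ChannelScaler.fit([y], ("FLX", "INV"))
        z = sc.transform(y)
        np.testing.assert_allclose(sc.inverse(z), y, atol=1e-9)
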