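"""CNN+LSTM building blocks against closed forms and loop oracles."""

import numpy as np
import pytest

from deepchronnect._nn import Adam, ChronnectomeNetwork, softmax
from deepchronnect.model import (
    ChronnectomeClassifier,
    ChronnectomeRegressor,
    LstmParams,
    ModelSpec,
    _packed_to_named,
    conv_bank,
    forward,
    lstm_cell_step,
    lstm_stack,
    temporal_average_head,
    temporal_maxpool,
)


def scalar_lstm_params(w=1.0, u=0.0, b=0.0):
    return LstmParams(
        *[np.array([[w]])] * 4, *[np.array([[u]])] * 4, *[np.array([b])] * 4
    )


class TestLstmCell:
    def test_all_zero_weights_closed_form(self, rng):
        params = scalar_lstm_params(w=0.0)
        c_prev = rng.standard_normal(1)
        state = lstm_cell_step(np.array([0.3]), np.zeros(1), c_prev, params)
        assert state.f == pytest.approx(0.5)
        assert state.i == pytest.approx(0.5)
        assert state.o == pytest.approx(0.5)
        assert state.c_tilde == pytest.approx(0.0)
        assert state.c == pytest.approx(0.5 * c_prev)
        assert state.h == pytest.approx(0.5 * np.tanh(0.5 * c_prev))

    def test_hand_computed_scalar_step(self):
        # W* = 1, U* = 0, b* = 0, x = 0.5, C_prev = 0: every gate is
        # sigmoid(0.5), the candidate is tanh(0.5), and the cell/hidden
        # states follow by the gate equations (verified by hand arithmetic)
        state = lstm_cell_step(np.array([0.5]), np.zeros(1), np.zeros(1),
                               scalar_lstm_params())
        assert state.f[0] == pytest.approx(0.62245933, abs=1e-6)
        assert state.i[0] == pytest.approx(0.62245933, abs=1e-6)
        assert state.o[0] == pytest.approx(0.62245933, abs=1e-6)
        assert state.c_tilde[0] == pytest.approx(0.46211716, abs=1e-6)
        assert state.c[0] == pytest.approx(0.28764914, abs=1e-6)
        assert state.h[0] == pytest.approx(0.17426972, abs=1e-6)

    def test_gates_bounded_over_random_draws(self, rng):
        for _ in range(200):
            params = LstmParams(
                *[rng.standard_normal((2, 3)) for _ in range(4)],
                *[rng.standard_normal((2, 2)) for _ in range(4)],
                *[rng.standard_normal(2) for _ in range(4)],
            )
            s = lstm_cell_step(rng.standard_normal(3) * 2,
                               rng.standard_normal(2) * 2,
                               rng.standard_normal(2), params)
            for gate in (s.f, s.i, s.o):
                assert np.all(gate > 0) and np.all(gate < 1)
            # tanh is bounded by 1; float64 saturates to exactly 1.0 for
            # extreme pre-activations
            assert np.all(np.abs(s.c_tilde) <= 1.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            lstm_cell_step(np.ones(2), np.zeros(1), np.zeros(1),
                           scalar_lstm_params())


class TestLstmStack:
    def test_single_step_is_two_chained_cells(self, rng):
        p1 = LstmParams(*[rng.standard_normal((2, 3)) for _ in range(4)],
                        *[rng.standard_normal((2, 2)) for _ in range(4)],
                        *[rng.standard_normal(2) for _ in range(4)])
        p2 = LstmParams(*[rng.standard_normal((2, 2)) for _ in range(4)],
                        *[rng.standard_normal((2, 2)) for _ in range(4)],
                        *[rng.standard_normal(2) for _ in range(4)])
        x = rng.standard_normal((1, 3))
        out = lstm_stack(x, [p1, p2])
        s1 = lstm_cell_step(x[0], np.zeros(2), np.zeros(2), p1)
        s2 = lstm_cell_step(s1.h, np.zeros(2), np.zeros(2), p2)
        np.testing.assert_allclose(out[0], s2.h, atol=1e-12)

    def test_network_matches_stepwise_oracle(self, rng):
        net = ChronnectomeNetwork(n_edges=6, conv_kernels=(2,), conv_channels=3,
                                  pool_kernel=1, lstm_hidden=5, lstm_layers=2,
                                  dropout=0.0, dtype=np.float64, seed=7)
        x = rng.standard_normal((1, 8, 6))
        _, cache = net.forward(x, train=False)
        top = cache["lstm1_out"][0]
        oracle = lstm_stack(cache["pooled"][0],
                            [_packed_to_named(net, 0), _packed_to_named(net, 1)])
        np.testing.assert_allclose(top, oracle, atol=1e-10)

    def test_hidden_width(self, rng):
        net = ChronnectomeNetwork(n_edges=3, conv_kernels=(2,), conv_channels=2,
                                  pool_kernel=1, lstm_hidden=32, lstm_layers=2,
                                  dropout=0.0, dtype=np.float64, seed=0)
        _, cache = net.forward(rng.standard_normal((1, 6, 3)))
        assert cache["lstm1_out"].shape == (1, 6, 32)


class TestConvBank:
    def test_reference_feature_map_width(self, rng):
        # three scales x 32 channels concatenated on the feature axis,
        # window count preserved by 'same' padding
        net = ChronnectomeNetwork(n_edges=10, conv_kernels=(4, 8, 16),
                                  conv_channels=32, dropout=0.0, seed=0)
        feat = conv_bank(net, rng.standard_normal((230, 10)))
        assert feat.shape == (230, 96)

    def test_zero_weights_zero_output(self, rng):
        net = ChronnectomeNetwork(n_edges=4, conv_kernels=(3,), conv_channels=2,
                                  dropout=0.0, seed=0)
        net.params["conv3_w"][:] = 0.0
        net.params["conv3_b"][:] = 0.0
        feat = conv_bank(net, rng.standard_normal((20, 4)))
        assert np.all(feat == 0.0)

    def test_kernel_one_matches_scalar_loop(self, rng):
        net = ChronnectomeNetwork(n_edges=3, conv_kernels=(1,), conv_channels=1,
                                  dropout=0.0, dtype=np.float64, seed=1)
        x = rng.standard_normal((7, 3))
        feat = conv_bank(net, x)
        w = net.params["conv1_w"][:, 0, 0]
        b = net.params["conv1_b"][0]
        for t in range(7):
            expect = max(0.0, sum(x[t, e] * w[e] for e in range(3)) + b)
            assert feat[t, 0] == pytest.approx(expect, abs=1e-12)

    def test_too_few_windows_rejected(self, rng):
        net = ChronnectomeNetwork(n_edges=3, conv_kernels=(4, 8, 16), seed=0)
        with pytest.raises(ValueError, match="windows"):
            conv_bank(net, rng.standard_normal((10, 3)))


class TestMaxPool:
    def test_reference_downsampling(self, rng):
        out = temporal_maxpool(rng.standard_normal((230, 96)), 5)
        assert out.shape == (46, 96)

    def test_kernel_one_identity(self, rng):
        x = rng.standard_normal((9, 4))
        np.testing.assert_array_equal(temporal_maxpool(x, 1), x)

    def test_remainder_dropped_vs_loop_oracle(self, rng):
        x = rng.standard_normal((17, 3))
        out = temporal_maxpool(x, 5)
        assert out.shape == (3, 3)
        for blk in range(3):
            for f in range(3):
                assert out[blk, f] == max(x[blk * 5 + k, f] for k in range(5))

    def test_too_short_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            temporal_maxpool(rng.standard_normal((3, 2)), 5)


class TestHeadAndForward:
    def test_constant_outputs_give_head_of_constant(self, rng):
        w = rng.standard_normal((4, 2))
        b = rng.standard_normal(2)
        const = rng.standard_normal(4)
        out = temporal_average_head(np.tile(const, (6, 1)), w, b)
        np.testing.assert_allclose(out, const @ w + b, atol=1e-12)

    def test_softmax_simplex(self, rng):
        out = temporal_average_head(rng.standard_normal((5, 3)),
                                    rng.standard_normal((3, 2)),
                                    rng.standard_normal(2), apply_softmax=True)
        assert np.all(out > 0) and np.all(out < 1)
        assert out.sum() == pytest.approx(1.0)

    def test_matches_mean_affine_oracle(self, rng):
        h = rng.standard_normal((7, 4))
        w = rng.standard_normal((4, 1))
        b = rng.standard_normal(1)
        got = temporal_average_head(h, w, b)
        expect = np.array([sum(h[:, k].sum() / 7 * w[k, 0] for k in range(4)) + b[0]])
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_inference_deterministic_despite_dropout_config(self, rng):
        net = ChronnectomeNetwork(n_edges=6, conv_kernels=(2, 3), conv_channels=4,
                                  pool_kernel=2, lstm_hidden=4, dropout=0.5, seed=3)
        x = rng.standard_normal((2, 12, 6))
        p1 = forward(net, x)
        p2 = forward(net, x)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (2, 2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_errors_name_the_stage(self, rng):
        net = ChronnectomeNetwork(n_edges=6, seed=0)
        with pytest.raises(ValueError, match="conv bank"):
            net.forward(rng.standard_normal((2, 30, 5)))


class TestOptimization:
    def test_tiny_net_overfits_four_samples(self, rng):
        # optimization sanity: 200 Adam steps drive a tiny net to 100%
        # training accuracy on 4 samples
        net = ChronnectomeNetwork(n_edges=6, conv_kernels=(2, 3), conv_channels=4,
                                  pool_kernel=2, lstm_hidden=8, dropout=0.0,
                                  dtype=np.float64, seed=11)
        X = rng.standard_normal((4, 20, 6))
        y = np.array([0, 0, 1, 1])
        X[y == 1] += 0.5
        opt = Adam(net.params, lr=5e-3)
        for _ in range(200):
            out, cache = net.forward(X, train=True,
                                     dropout_rng=np.random.default_rng(0))
            p = softmax(out)
            d = p.copy()
            d[np.arange(4), y] -= 1
            net_grads = net.backward(cache, d / 4)
            opt.step(net.params, net_grads)
        out, _ = net.forward(X)
        assert np.mean(out.argmax(1) == y) == 1.0


class TestEstimators:
    def _toy(self, rng, n=24):
        X = rng.standard_normal((n, 20, 6))
        y = np.tile([0, 1], n // 2)
        X[y == 1, :, :2] += 0.8
        return X, y

    def test_classifier_fits_separable_toy(self, rng):
        X, y = self._toy(rng)
        est = ChronnectomeClassifier(conv_kernels=(2, 4), conv_channels=4,
                                     lstm_hidden=8, dropout=0.0, learning_rate=5e-3,
                                     lr_decay=1.0, batch_size=8, max_epochs=40,
                                     patience=40, random_state=0)
        est.fit(X, y)
        assert (est.predict(X) == y).mean() == 1.0
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_fixed_seed_reproducible_history(self, rng):
        X, y = self._toy(rng, n=12)
        kw = dict(conv_kernels=(2,), conv_channels=3, lstm_hidden=4, dropout=0.5,
                  max_epochs=4, patience=4, batch_size=4, random_state=42)
        h1 = ChronnectomeClassifier(**kw).fit(X, y).history_
        h2 = ChronnectomeClassifier(**kw).fit(X, y).history_
        assert h1 == h2

    def test_early_stopping_on_plateau(self, rng):
        # zero learning rate: the monitored loss can never improve after
        # the first epoch, so patience=1 stops after exactly 2 epochs
        X, y = self._toy(rng, n=8)
        est = ChronnectomeClassifier(conv_kernels=(2,), conv_channels=2,
                                     lstm_hidden=3, dropout=0.0,
                                     learning_rate=1e-30, max_epochs=10,
                                     patience=1, random_state=0)
        est.fit(X, y)
        assert len(est.history_["train_loss"]) == 2

    def test_more_than_two_classes_rejected(self, rng):
        X = rng.standard_normal((6, 20, 4))
        with pytest.raises(ValueError, match="2 classes"):
            ChronnectomeClassifier(conv_kernels=(2,), max_epochs=1).fit(
                X, np.array([0, 1, 2, 0, 1, 2])
            )

    def test_edge_count_checked_at_predict(self, rng):
        X, y = self._toy(rng, n=8)
        est = ChronnectomeClassifier(conv_kernels=(2,), conv_channels=2,
                                     lstm_hidden=3, max_epochs=1, random_state=0)
        est.fit(X, y)
        with pytest.raises(ValueError, match="edges"):
            est.predict(rng.standard_normal((2, 20, 5)))

    def test_regressor_learns_mean_shift(self, rng):
        X = rng.standard_normal((24, 20, 6))
        y = X[:, :, 0].mean(axis=1) * 2.0
        est = ChronnectomeRegressor(conv_kernels=(2,), conv_channels=4,
                                    lstm_hidden=8, dropout=0.0, learning_rate=5e-3,
                                    lr_decay=1.0, batch_size=8, max_epochs=60,
                                    patience=60, random_state=0)
        est.fit(X, y)
        r = np.corrcoef(est.predict(X), y)[0, 1]
        assert r > 0.9

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = ChronnectomeClassifier(learning_rate=3e-3, batch_size=16)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(max_epochs=7)
        assert est.max_epochs == 7

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X, y = self._toy(rng, n=8)
        est = ChronnectomeClassifier(conv_kernels=(2,), conv_channels=2,
                                     lstm_hidden=3, max_epochs=2, random_state=0)
        est.fit(X, y)
        est.save(tmp_path / "model.npz")
        back = ChronnectomeClassifier.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.predict_proba(X), est.predict_proba(X))
        np.testing.assert_array_equal(back.classes_, est.classes_)

    def test_model_spec_validation(self):
        spec = ModelSpec(n_edges=190)
        assert spec.n_outputs == 2
        with pytest.raises(ValueError):
            ModelSpec(n_edges=10, head="ranking")
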