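"""Branch correctness: conv/LSTM oracles, quantization, pruning, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaptimu import models


# ---------------------------------------------------------------------------
# independent oracles


def oracle_depthwise_separable(h, Wd, Wp, stride, order):
    """Nested-loop reference for the separable convolution (same padding)."""
    T, _ = h.shape
    k = Wd.shape[0]
    out_len = -(-T // stride)
    total = max((out_len - 1) * stride + k - T, 0)
    left = total // 2

    def dconv(x):
        Tc, C = x.shape
        xp = np.zeros((Tc + total, C))
        xp[left:left + Tc] = x
        out = np.zeros((out_len, C))
        for t in range(out_len):
            for c in range(C):
                for j in range(k):
                    out[t, c] += Wd[j, c] * xp[t * stride + j, c]
        return out

    if order == "as_printed":
        out = dconv(h @ Wp)
    else:
        out = dconv(h) @ Wp
    return np.maximum(out, 0.0)


def oracle_lstm_cell(x, h, c, W, U, b, hdim):
    """By-hand single-cell arithmetic with explicit sigmoid/tanh."""
    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    gates = x @ W + h @ U + b
    i = sig(gates[:hdim])
    f = sig(gates[hdim:2 * hdim])
    g = np.tanh(gates[2 * hdim:3 * hdim])
    o = sig(gates[3 * hdim:])
    c_new = f * c + i * g
    return o * np.tanh(c_new), c_new


# ---------------------------------------------------------------------------
# depthwise-separable convolution


class TestSeparableConv:
    def test_identity_kernels_reproduce_input(self):
        """Identity pointwise + centered delta depthwise at stride 1 is the
        identity map on non-negative input."""
        rng = np.random.default_rng(0)
        h = np.abs(rng.standard_normal((10, 3)))
        Wp = np.eye(3)
        Wd = np.zeros((3, 3))
        Wd[1] = 1.0  # delta at the center tap
        out = models.depthwise_separable_conv(h, Wd, Wp, stride=1)
        np.testing.assert_allclose(out, h, atol=1e-12)

    def test_zero_input_zero_output(self):
        out = models.depthwise_separable_conv(
            np.zeros((12, 2)), np.ones((3, 4)), np.ones((2, 4)))
        assert out.shape == (6, 4)
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("order", ["as_printed", "conventional"])
    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_nested_loop_oracle(self, order, stride):
        rng = np.random.default_rng(42)
        for _ in range(5):
            h = rng.standard_normal((12, 2))
            if order == "as_printed":
                Wp, Wd = rng.standard_normal((2, 4)), rng.standard_normal((3, 4))
            else:
                Wp, Wd = rng.standard_normal((2, 4)), rng.standard_normal((3, 2))
            out = models.depthwise_separable_conv(h, Wd, Wp, stride, order)
            ref = oracle_depthwise_separable(h, Wd, Wp, stride, order)
            np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            models.depthwise_separable_conv(
                np.zeros((2, 2)), np.ones((5, 4)), np.ones((2, 4)))


class TestCnnForward:
    def test_shape_trace_40_20_10_5(self):
        params = models.init_cnn(6, seed=0)
        assert models.cnn_shape_trace(params) == [(20, 32), (10, 64), (5, 128)]

    @pytest.mark.parametrize("length", [5, 7, 23, 40, 64])
    def test_shape_conservation_ceil_rule(self, length):
        params = models.init_cnn(3, seed=1, input_len=length)
        X = np.random.default_rng(0).standard_normal((2, length, 3))
        logits, cache = models.cnn_forward_batch(X, params)
        t = length
        for bc in cache["blocks"]:
            t = -(-t // 2)
            assert bc["out"].shape[1] == t
        assert logits.shape == (2, 2)

    def test_wrong_window_length_rejected(self):
        params = models.init_cnn(6, seed=0)
        with pytest.raises(ValueError, match="length"):
            models.cnn_forward(np.zeros((39, 6)), params)

    def test_softmax_normalized(self):
        params = models.init_cnn(6, seed=0)
        p = models.predict_proba(
            np.random.default_rng(3).standard_normal((4, 40, 6)),
            params, "cnn")
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_quantized_vs_float_logit_gap(self):
        """int8 weights + calibrated int8 activations stay within 0.25
        logit units of the float path over 100 random windows."""
        rng = np.random.default_rng(7)
        params = models.init_cnn(6, seed=7)
        X = rng.standard_normal((100, 40, 6))
        models.cnn_forward_batch(X[:32], params, training=True)  # set BN stats
        models.calibrate_activation_scales(params, X[:32])
        qf = models.cnn_forward_quantized(X, params)
        ff, _ = models.cnn_forward_batch(X, params, training=False)
        assert np.max(np.abs(qf - ff)) < 0.25

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 12, 2))
        y = np.array([0, 1, 0])
        params = models.init_cnn(2, seed=1, input_len=12,
                                 kernels=(3, 3), channels=(4, 8))
        pdict = models._cnn_param_dict(params)
        logits, cache = models.cnn_forward_batch(X, params, training=True)
        _, dl = models.weighted_ce_loss(logits, y, None)
        grads = models.cnn_backward_batch(dl, cache, params)
        for name, arr in pdict.items():
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            eps, old = 1e-6, arr[idx]
            arr[idx] = old + eps
            lp, _ = models.weighted_ce_loss(
                models.cnn_forward_batch(X, params, training=True)[0], y, None)
            arr[idx] = old - eps
            lm, _ = models.weighted_ce_loss(
                models.cnn_forward_batch(X, params, training=True)[0], y, None)
            arr[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[name][idx]) < 1e-5 * max(1.0, abs(num))


# ---------------------------------------------------------------------------
# quantization


class TestQuantization:
    def test_all_zero_tensor_exact(self):
        qt = models.quantize_tensor(np.zeros((3, 3)))
        assert qt.scale == 1.0
        np.testing.assert_array_equal(qt.dequantize(), 0.0)

    def test_linspace_round_trip_bound(self):
        x = np.linspace(-1, 1, 101)
        qt = models.quantize_tensor(x)
        assert np.max(np.abs(qt.dequantize() - x)) <= (2 / 254) / 2 + 1e-12

    def test_idempotent_on_dequantized_values(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal(64) * rng.uniform(0.01, 100)
            once = models.quantize_tensor(x).dequantize()
            twice = models.quantize_tensor(once).dequantize()
            np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_round_trip_bound_property_1000_draws(self):
        """Elementwise |x - deq(q(x))| <= scale/2 on 1,000 random tensors."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            x = rng.standard_normal(rng.integers(1, 30)) * \
                10.0 ** rng.uniform(-3, 3)
            qt = models.quantize_tensor(x)
            assert np.max(np.abs(qt.dequantize() - x)) <= qt.scale / 2 + 1e-15

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_round_trip_bound_hypothesis(self, values):
        x = np.asarray(values)
        qt = models.quantize_tensor(x)
        assert np.max(np.abs(qt.dequantize() - x)) <= qt.scale / 2 + 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            models.quantize_tensor(np.array([1.0, np.inf]))


# ---------------------------------------------------------------------------
# LSTM


class TestLstm:
    def test_zero_weights_zero_hidden(self):
        params = models.init_lstm(3, hidden=(4, 2), seed=0)
        for layer in params.layers:
            layer.W[:] = 0
            layer.U[:] = 0
            layer.b[:] = 0
        h, state = models.lstm_forward(np.ones(3), None, params)
        np.testing.assert_array_equal(h, 0.0)
        h2, _ = models.lstm_forward(np.full(3, 9.0), state, params)
        np.testing.assert_array_equal(h2, 0.0)

    def test_single_cell_matches_hand_arithmetic(self):
        """One layer, scalar input/hidden: cell output equals an explicit
        sigmoid/tanh evaluation."""
        rng = np.random.default_rng(8)
        layer = models.LstmLayer(W=rng.standard_normal((1, 4)),
                                 U=rng.standard_normal((1, 4)),
                                 b=rng.standard_normal(4))
        params = models.LstmParams(layers=[layer],
                                   Wl=np.ones((1, 2)), bl=np.zeros(2))
        x = np.array([0.7])
        h, state = models.lstm_forward(x, None, params)
        h_ref, c_ref = oracle_lstm_cell(x, np.zeros(1), np.zeros(1),
                                        layer.W, layer.U, layer.b, 1)
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
        np.testing.assert_allclose(state[0][1], c_ref, atol=1e-10)

    def test_state_dims_validated(self):
        params = models.init_lstm(6, seed=0)
        bad_state = ((np.zeros(10), np.zeros(10)), (np.zeros(32), np.zeros(32)))
        with pytest.raises(ValueError, match="state"):
            models.lstm_forward(np.zeros(6), bad_state, params)

    def test_masked_weights_zero_in_forward(self):
        params = models.init_lstm(6, seed=0)
        pruned = models.magnitude_prune(params, 0.5)
        for layer in pruned.layers:
            eff_w = layer.W * layer.mask_W
            assert np.all(eff_w[layer.mask_W == 0] == 0)
        # forward with mask equals forward with explicitly zeroed weights
        x = np.random.default_rng(0).standard_normal((2, 40, 6))
        lo, _ = models.lstm_forward_seq(x, pruned)
        dense_zeroed = models.magnitude_prune(params, 0.5)
        for layer in dense_zeroed.layers:
            layer.W *= layer.mask_W
            layer.U *= layer.mask_U
            layer.mask_W = np.ones_like(layer.mask_W)
            layer.mask_U = np.ones_like(layer.mask_U)
        lo2, _ = models.lstm_forward_seq(x, dense_zeroed)
        np.testing.assert_allclose(lo, lo2, atol=1e-12)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 8, 2))
        y = np.array([1, 0, 1])
        params = models.init_lstm(2, hidden=(5, 4), seed=2, dropout=0.0)
        pdict = models._lstm_param_dict(params)
        logits, cache = models.lstm_forward_seq(X, params)
        _, dl = models.weighted_ce_loss(logits, y, np.array([1.0, 2.0]))
        grads = models.lstm_backward_seq(dl, cache, params)
        for name, arr in pdict.items():
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            eps, old = 1e-6, arr[idx]

            def loss_at(v):
                arr[idx] = v
                lo, _ = models.lstm_forward_seq(X, params)
                l, _ = models.weighted_ce_loss(lo, y, np.array([1.0, 2.0]))
                return l

            num = (loss_at(old + eps) - loss_at(old - eps)) / (2 * eps)
            arr[idx] = old
            assert abs(num - grads[name][idx]) < 1e-5 * max(1.0, abs(num))


# ---------------------------------------------------------------------------
# pruning


class TestMagnitudePrune:
    def test_hand_ranked_example(self):
        """ratio 0.4 on ten weights zeroes exactly the four smallest
        magnitudes {0.01, 0.05, 0.1, 0.15}."""
        w = np.array([0.5, -0.1, 0.3, -0.05, 0.2, 0.01, -0.4, 0.15, 0.25,
                      -0.3]).reshape(2, 5)
        mask = models.prune_mask(w, 0.4)
        zeroed = sorted(np.abs(w[mask == 0]))
        np.testing.assert_allclose(zeroed, [0.01, 0.05, 0.1, 0.15])

    def test_ratio_zero_identity(self):
        params = models.init_lstm(6, seed=0)
        pruned = models.magnitude_prune(params, 0.0)
        assert models.sparsity(pruned) == 0.0
        for a, b in zip(params.layers, pruned.layers):
            np.testing.assert_array_equal(a.W, b.W)

    def test_exact_zero_count_per_matrix(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((40, 25))  # 1,000 weights
        mask = models.prune_mask(w, 0.4)
        assert (mask == 0).sum() == 400

    @pytest.mark.parametrize("ratio", [0.1, 0.25, 0.4, 0.6, 0.8])
    def test_sparsity_within_floor_rounding(self, ratio):
        params = models.init_lstm(6, seed=3)
        pruned = models.magnitude_prune(params, ratio)
        n_min = min(l.W.size for l in params.layers)
        assert abs(models.sparsity(pruned) - ratio) <= 1.0 / n_min

    def test_ratio_one_rejected(self):
        with pytest.raises(ValueError):
            models.prune_mask(np.ones(10), 1.0)

    def test_reprune_from_dense_is_reversible(self):
        params = models.init_lstm(6, seed=4)
        p6 = models.magnitude_prune(params, 0.6)
        p4 = models.magnitude_prune(params, 0.4)
        assert models.sparsity(p6) == pytest.approx(0.6, abs=1e-3)
        assert models.sparsity(p4) == pytest.approx(0.4, abs=1e-3)


# ---------------------------------------------------------------------------
# training


def _separable_windows(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 40, 6)) * 0.3
    X[y == 1, :, 0] += 2.0   # class-1 windows offset on channel 0
    return X, y


class TestTrainBranch:
    @pytest.mark.parametrize("branch", ["cnn", "lstm"])
    def test_separable_toy_reaches_high_accuracy(self, branch):
        X, y = _separable_windows()
        cfg = models.TrainConfig(lr=3e-3, max_epochs=20, patience=20, seed=0)
        params, hist = models.train_branch(X, y, branch, cfg)
        p = models.predict_proba(X, params, branch)
        acc = np.mean(p.argmax(axis=1) == y)
        assert acc > 0.95
        assert len(hist["train_loss"]) <= 20

    def test_zero_learning_rate_leaves_params(self):
        X, y = _separable_windows(40)
        params = models.init_lstm(6, seed=1)
        before = [l.W.copy() for l in params.layers]
        cfg = models.TrainConfig(lr=0.0, max_epochs=2, seed=0)
        models.train_branch(X, y, "lstm", cfg, params=params)
        for b, layer in zip(before, params.layers):
            np.testing.assert_array_equal(b, layer.W)

    def test_seeded_rerun_identical_losses(self):
        X, y = _separable_windows(60)
        cfg = models.TrainConfig(lr=1e-3, max_epochs=3, seed=7)
        _, h1 = models.train_branch(X, y, "cnn", cfg)
        _, h2 = models.train_branch(X, y, "cnn", cfg)
        assert h1["train_loss"] == h2["train_loss"]

    def test_lstm_mask_survives_training(self):
        X, y = _separable_windows(60)
        params = models.magnitude_prune(models.init_lstm(6, seed=2), 0.4)
        cfg = models.TrainConfig(lr=1e-3, max_epochs=2, seed=0)
        trained, _ = models.train_branch(X, y, "lstm", cfg, params=params)
        for layer in trained.layers:
            assert np.all(layer.W[layer.mask_W == 0] == 0)
        assert models.sparsity(trained) == pytest.approx(0.4, abs=1e-3)

    def test_single_class_rejected(self):
        X = np.zeros((10, 40, 6))
        with pytest.raises(ValueError, match="both classes"):
            models.train_branch(X, np.zeros(10, int), "cnn",
                                models.TrainConfig())
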