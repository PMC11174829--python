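"""Layer-level checks: brute-force oracles and finite-difference gradients.

All oracle comparisons run in float64 so the 1e-6 tolerances measure the
implementation, not the storage precision.
"""

import numpy as np
import pytest

from dualeeg import nn
from conftest import naive_conv1d, naive_conv2d, naive_lstm


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestConv1d:
    def test_matches_brute_force_cross_correlation(self, rng):
        layer = nn.Conv1d(2, 3, 3, pad=0, rng=rng, dtype=np.float64)
        x = rng.normal(size=(1, 2, 10))
        out = layer.forward(x)
        w = layer.params["W"].reshape(3, 2, 3)
        ref = naive_conv1d(x[0], w, layer.params["b"])
        np.testing.assert_allclose(out[0], ref, atol=1e-6)

    def test_identity_kernel_is_identity(self, rng):
        layer = nn.Conv1d(1, 1, 3, rng=rng, dtype=np.float64)
        layer.params["W"][:] = [[0.0, 1.0, 0.0]]
        layer.params["b"][:] = 0.0
        x = rng.normal(size=(1, 1, 12))
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-12)

    def test_zero_input_broadcasts_bias(self, rng):
        layer = nn.Conv1d(2, 4, 3, rng=rng, dtype=np.float64)
        layer.params["b"][:] = [1.0, -2.0, 0.5, 0.0]
        out = layer.forward(np.zeros((1, 2, 9)))
        np.testing.assert_allclose(out[0], np.tile([[1.0], [-2.0], [0.5], [0.0]],
                                                   (1, 9)), atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="expected"):
            nn.Conv1d(2, 3, 3, rng=rng).forward(np.zeros((1, 5, 10)))

    def test_gradients_match_finite_differences(self, rng):
        layer = nn.Conv1d(2, 3, 3, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 2, 7))
        dout = rng.normal(size=(2, 3, 7))

        def loss():
            return float(np.sum(layer.forward(x.copy()) * dout))

        layer.forward(x.copy())
        dx = layer.backward(dout)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-6)
        np.testing.assert_allclose(layer.grads["W"],
                                   numeric_grad(loss, layer.params["W"]),
                                   atol=1e-6)
        np.testing.assert_allclose(layer.grads["b"],
                                   numeric_grad(loss, layer.params["b"]),
                                   atol=1e-6)


class TestConv2d:
    def test_matches_brute_force_cross_correlation(self, rng):
        layer = nn.Conv2d(2, 3, (3, 3), pad=(0, 0), rng=rng, dtype=np.float64)
        x = rng.normal(size=(1, 2, 8, 8))
        out = layer.forward(x)
        w = layer.params["W"].reshape(3, 2, 3, 3)
        ref = naive_conv2d(x[0], w, layer.params["b"])
        np.testing.assert_allclose(out[0], ref, atol=1e-6)

    def test_identity_center_kernel(self, rng):
        layer = nn.Conv2d(1, 1, (3, 3), rng=rng, dtype=np.float64)
        layer.params["W"][:] = 0.0
        layer.params["W"][0, 4] = 1.0  # centre tap of the 3x3 kernel
        layer.params["b"][:] = 0.0
        x = rng.normal(size=(1, 1, 6, 5))
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-12)

    def test_valid_1x2_kernel_shrinks_width_only(self, rng):
        layer = nn.Conv2d(4, 4, (1, 2), pad=(0, 0), rng=rng, dtype=np.float64)
        out = layer.forward(rng.normal(size=(1, 4, 11, 19)))
        assert out.shape == (1, 4, 11, 18)

    def test_gradients_match_finite_differences(self, rng):
        layer = nn.Conv2d(2, 2, (3, 3), rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 2, 5, 4))
        dout = rng.normal(size=(2, 2, 5, 4))

        def loss():
            return float(np.sum(layer.forward(x.copy()) * dout))

        layer.forward(x.copy())
        dx = layer.backward(dout)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-6)
        np.testing.assert_allclose(layer.grads["W"],
                                   numeric_grad(loss, layer.params["W"]),
                                   atol=1e-6)


class TestBatchNorm:
    def test_normalizes_per_channel(self, rng):
        bn = nn.BatchNorm(3, dtype=np.float64)
        x = rng.normal(2.0, 5.0, size=(8, 3, 20))
        out = bn.forward(x)
        np.testing.assert_allclose(out.mean(axis=(0, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=(0, 2)), 1.0, rtol=1e-3)

    def test_eval_mode_uses_running_stats(self, rng):
        bn = nn.BatchNorm(2, dtype=np.float64)
        for _ in range(50):
            bn.forward(rng.normal(3.0, 2.0, size=(16, 2, 10)))
        bn.training = False
        out = bn.forward(np.full((1, 2, 10), 3.0))
        np.testing.assert_allclose(out, 0.0, atol=0.2)

    def test_gradients_match_finite_differences(self, rng):
        bn = nn.BatchNorm(2, dtype=np.float64)
        x = rng.normal(size=(4, 2, 6))
        dout = rng.normal(size=(4, 2, 6))

        def loss():
            return float(np.sum(bn.forward(x.copy()) * dout))

        bn.forward(x.copy())
        dx = bn.backward(dout)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-5)
        np.testing.assert_allclose(bn.grads["gamma"],
                                   numeric_grad(loss, bn.params["gamma"]),
                                   atol=1e-5)


class TestChannelAttention:
    def test_output_is_channelwise_scaling(self, rng):
        att = nn.ChannelAttention(8, reduction=4, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 8, 5, 3)) + 0.5
        out = att.forward(x)
        ratio = out / x
        for b in range(2):
            for c in range(8):
                vals = ratio[b, c].ravel()
                np.testing.assert_allclose(vals, vals[0], rtol=1e-10)

    def test_gates_live_in_open_unit_interval(self, rng):
        att = nn.ChannelAttention(16, reduction=4, rng=rng, dtype=np.float64)
        g = att.gates(rng.normal(size=(3, 16, 7)))
        assert np.all(g > 0) and np.all(g < 1)

    def test_saturated_gates_pass_input_through(self, rng):
        att = nn.ChannelAttention(4, reduction=2, rng=rng, dtype=np.float64)
        att.params["W1"][:] = 0.0
        att.params["W2"][:] = 0.0
        att.params["b2"][:] = 30.0   # sigmoid(30) ~ 1
        x = rng.normal(size=(1, 4, 6))
        np.testing.assert_allclose(att.forward(x), x, rtol=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        att = nn.ChannelAttention(4, reduction=2, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 4, 5))
        dout = rng.normal(size=(2, 4, 5))

        def loss():
            return float(np.sum(att.forward(x.copy()) * dout))

        att.forward(x.copy())
        dx = att.backward(dout)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-6)
        for k in ("W1", "b1", "W2", "b2"):
            np.testing.assert_allclose(att.grads[k],
                                       numeric_grad(loss, att.params[k]),
                                       atol=1e-6)


class TestMaxPool:
    def test_three_by_one_pooling(self, rng):
        pool = nn.MaxPool2d((3, 1))
        x = rng.normal(size=(2, 4, 33, 19))
        out = pool.forward(x)
        assert out.shape == (2, 4, 11, 19)
        assert out[0, 0, 0, 0] == x[0, 0, :3, 0].max()

    def test_backward_routes_to_argmax(self, rng):
        pool = nn.MaxPool2d((3, 1))
        x = rng.normal(size=(1, 1, 6, 2))
        out = pool.forward(x)
        dx = pool.backward(np.ones_like(out))
        assert dx.sum() == out.size
        assert np.all((dx == 0) | (dx == 1))
        for g in range(2):
            for w in range(2):
                winner = g * 3 + int(x[0, 0, g * 3:(g + 1) * 3, w].argmax())
                assert dx[0, 0, winner, w] == 1.0


class TestLSTM:
    def test_zero_parameters_give_zero_hidden_states(self):
        lstm = nn.LSTM(3, 2, dtype=np.float64)
        for k in lstm.params:
            lstm.params[k][:] = 0.0
        out = lstm.forward(np.random.default_rng(0).normal(size=(2, 5, 3)))
        np.testing.assert_array_equal(out, np.zeros((2, 5, 2)))

    def test_single_step_hand_evaluation(self):
        """D=H=1, all input weights 1, recurrents and biases 0, x=1."""
        lstm = nn.LSTM(1, 1, dtype=np.float64)
        lstm.params["Wx"][:] = 1.0
        lstm.params["Wh"][:] = 0.0
        lstm.params["b"][:] = 0.0
        out = lstm.forward(np.ones((1, 1, 1)))
        s1 = 1.0 / (1.0 + np.exp(-1.0))
        c1 = s1 * np.tanh(1.0)
        h1 = s1 * np.tanh(c1)
        assert out[0, 0, 0] == pytest.approx(h1, abs=1e-12)

    def test_matches_scalar_recurrence_oracle(self, rng):
        lstm = nn.LSTM(3, 4, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 5, 3))
        out = lstm.forward(x)
        for b in range(2):
            ref = naive_lstm(x[b], lstm.params["Wx"], lstm.params["Wh"],
                             lstm.params["b"])
            np.testing.assert_allclose(out[b], ref, atol=1e-6)

    def test_nonfinite_parameters_rejected(self, rng):
        lstm = nn.LSTM(2, 2, rng=rng, dtype=np.float64)
        lstm.params["Wx"][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            lstm.forward(np.zeros((1, 3, 2)))

    def test_gradients_match_finite_differences(self, rng):
        lstm = nn.LSTM(2, 3, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 4, 2))
        dout = rng.normal(size=(2, 4, 3))

        def loss():
            return float(np.sum(lstm.forward(x.copy()) * dout))

        lstm.forward(x.copy())
        dx = lstm.backward(dout)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-6)
        for k in ("Wx", "Wh", "b"):
            np.testing.assert_allclose(lstm.grads[k],
                                       numeric_grad(loss, lstm.params[k]),
                                       atol=1e-6)


class TestLossAndSoftmax:
    def test_softmax_shift_invariance_and_normalization(self, rng):
        logits = rng.normal(size=(6, 2))
        p = nn.softmax(logits)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(nn.softmax(logits + 7.3), p, atol=1e-12)

    def test_equal_logits_give_half_half(self):
        np.testing.assert_allclose(nn.softmax(np.zeros((1, 2))),
                                   [[0.5, 0.5]], atol=1e-15)

    def test_cross_entropy_gradient_is_softmax_minus_onehot(self, rng):
        logits = rng.normal(size=(4, 2))
        labels = np.array([0, 1, 1, 0])
        loss, dl = nn.cross_entropy(logits, labels)
        p = nn.softmax(logits)
        onehot = np.eye(2)[labels]
        np.testing.assert_allclose(dl, (p - onehot) / 4, atol=1e-12)
        assert loss == pytest.approx(
            -np.mean(np.log(p[np.arange(4), labels])), abs=1e-12)


class TestAdam:
    def test_reduces_quadratic_loss(self, rng):
        lin = nn.Linear(3, 1, rng=rng, dtype=np.float64)
        opt = nn.Adam([lin], lr=0.05)
        x = rng.normal(size=(32, 3))
        target = x @ np.array([[1.0], [-2.0], [0.5]])
        first = None
        for _ in range(200):
            out = lin.forward(x)
            err = out - target
            loss = float(np.mean(err ** 2))
            first = first if first is not None else loss
            lin.backward(2 * err / err.size)
            opt.step()
        assert loss < 1e-3 * first
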