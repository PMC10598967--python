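"""Engine-level tests: finite-difference gradient checks, the dilated
convolution brute-force oracle, dense-block connectivity counting, and the
residual squeeze-excitation algebra."""

import numpy as np
import pytest

from m6amstack.nn import autograd as ag
from m6amstack.nn.autograd import Tensor, conv1d
from m6amstack.nn.layers import BiGRU, BiLSTM, DenseBlock, SEBlock
from m6amstack.nn.recurrent import gru_forward, lstm_forward

rng = np.random.default_rng(7)


def T(*shape, scale=0.5):
    return Tensor(rng.standard_normal(shape) * scale, requires_grad=True)


def finite_diff_check(fn, tensors, eps=1e-5, tol=2e-4):
    out = fn(*tensors)
    (out * out).sum().backward()
    for t in tensors:
        analytic = t.grad
        numeric = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = t.data[idx]
            t.data[idx] = orig + eps
            up = float((fn(*tensors).data ** 2).sum())
            t.data[idx] = orig - eps
            down = float((fn(*tensors).data ** 2).sum())
            t.data[idx] = orig
            numeric[idx] = (up - down) / (2 * eps)
        rel = np.abs(numeric - analytic).max() / (np.abs(numeric).max() + 1e-8)
        assert rel < tol, f"gradient mismatch {rel:.2e}"


# ---------------------------------------------------------------------
# dilated convolution
# ---------------------------------------------------------------------

def brute_force_dilated_conv(x, w, b, k):
    """y_i = sum_n x[i + k*n] * w[n] + b over valid i (index-arithmetic loop)."""
    N = len(w)
    L = len(x)
    span = k * (N - 1)
    return np.array([
        sum(x[i + k * n] * w[n] for n in range(N)) + b
        for i in range(L - span)
    ])


class TestDilatedConv:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_100_instances(self, k):
        local = np.random.default_rng(100 + k)
        for _ in range(100):
            L = int(local.integers(8, 20))
            N = int(local.integers(1, 4))
            if k * (N - 1) >= L:
                continue
            x = local.standard_normal(L)
            w = local.standard_normal(N)
            b = float(local.standard_normal())
            expected = brute_force_dilated_conv(x, w, b, k)
            got = conv1d(Tensor(x.reshape(1, L, 1)),
                         Tensor(w.reshape(N, 1, 1)), Tensor(np.array([b])),
                         dilation=k, padding="valid")
            np.testing.assert_allclose(got.data.ravel(), expected, atol=1e-10)

    def test_k1_equals_standard_convolution(self):
        local = np.random.default_rng(5)
        x = local.standard_normal(12)
        w = local.standard_normal(3)
        # standard correlation oracle via numpy
        expected = np.correlate(x, w[::-1], mode="valid")[::1]
        got = conv1d(Tensor(x.reshape(1, 12, 1)), Tensor(w.reshape(3, 1, 1)),
                     dilation=1, padding="valid")
        # numpy correlate applies the kernel without flipping when reversed
        np.testing.assert_allclose(got.data.ravel(),
                                   np.convolve(x, w[::-1], "valid"), atol=1e-10)

    def test_worked_example_k2(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        got = conv1d(Tensor(x.reshape(1, 6, 1)),
                     Tensor(np.ones((2, 1, 1))), dilation=2, padding="valid")
        # hand loop: y_i = x_{i} + x_{i+2} for i = 0..3 (0-based taps 0 and 2)
        np.testing.assert_allclose(got.data.ravel(), [4, 6, 8, 10])

    def test_zero_weights_zero_output(self):
        x = T(2, 9, 3)
        w = Tensor(np.zeros((3, 3, 2)))
        out = conv1d(x, w, dilation=2)
        assert np.all(out.data == 0)

    def test_same_padding_preserves_length(self):
        for k in (1, 2, 3):
            out = conv1d(T(2, 41, 4), T(3, 4, 8), dilation=k, padding="same")
            assert out.shape == (2, 41, 8)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_gradients(self, k):
        x, w, b = T(2, 10, 3), T(3, 3, 4), T(4)
        finite_diff_check(
            lambda x, w, b: conv1d(x, w, b, dilation=k), [x, w, b])


# ---------------------------------------------------------------------
# gradient checks for the remaining primitives
# ---------------------------------------------------------------------

class TestGradients:
    def test_elementwise_and_matmul(self):
        x, y = T(4, 5), T(4, 5)
        finite_diff_check(lambda a, b: a * b + a - b, [x, y])
        a, b = T(3, 4), T(4, 2)
        finite_diff_check(lambda a, b: a @ b, [a, b])

    def test_activations(self):
        for name in ("relu", "elu", "sigmoid", "tanh"):
            x = T(4, 6)
            finite_diff_check(lambda x: getattr(x, name)(), [x])

    def test_pooling(self):
        x = T(2, 9, 3)
        finite_diff_check(lambda x: ag.max_pool1d(x, 2), [x])
        x = T(2, 9, 3)
        finite_diff_check(lambda x: ag.avg_pool1d(x, 3), [x])

    def test_concat_and_mean(self):
        a, b = T(2, 5, 2), T(2, 5, 3)
        finite_diff_check(lambda a, b: ag.concat([a, b], -1), [a, b])
        x = T(3, 4, 5)
        finite_diff_check(lambda x: x.mean_axis(1), [x])

    def test_lstm(self):
        H = 4
        args = [T(2, 6, 3), T(3, 4 * H), T(H, 4 * H), T(4 * H)]
        finite_diff_check(lstm_forward, args, tol=5e-4)

    def test_gru(self):
        H = 4
        args = [T(2, 6, 3), T(3, 3 * H), T(H, 3 * H), T(3 * H)]
        finite_diff_check(gru_forward, args, tol=5e-4)


# ---------------------------------------------------------------------
# dense connectivity
# ---------------------------------------------------------------------

class TestDenseBlock:
    @pytest.mark.parametrize("X", [1, 2, 3, 4, 5, 6])
    def test_connection_count_formula(self, X):
        block = DenseBlock(in_ch=2, n_layers=X, growth=3, kernel=3,
                           rng=np.random.default_rng(0))
        block(Tensor(rng.standard_normal((2, 8, 2))))
        assert block.connection_count() == X * (X + 1) // 2

    def test_channel_bookkeeping(self):
        # with growth g, output channel count after layer i equals in + i*g
        for i in range(1, 5):
            block = DenseBlock(in_ch=1, n_layers=i, growth=1, kernel=1,
                               rng=np.random.default_rng(0))
            out = block(Tensor(rng.standard_normal((1, 6, 1))))
            assert out.shape[-1] == i + 1

    def test_gradients_flow(self):
        block = DenseBlock(in_ch=2, n_layers=3, growth=2, kernel=3,
                           rng=np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, 8, 2)), requires_grad=True)
        (block(x) * block(x)).sum().backward()
        for p in block.parameters():
            assert p.grad is not None


# ---------------------------------------------------------------------
# squeeze-excitation block
# ---------------------------------------------------------------------

class TestSEBlock:
    def _block(self, channels=6):
        return SEBlock(channels, reduction=2, rng=np.random.default_rng(0))

    def test_output_shape_preserved(self):
        se = self._block()
        x = Tensor(rng.standard_normal((3, 10, 6)))
        assert se(x).shape == x.shape

    def test_zero_gates_residual_identity(self):
        se = self._block()
        se.fc2.w.data[:] = 0.0
        se.fc2.b.data[:] = -1e9  # sigmoid -> 0 gates
        x = Tensor(rng.standard_normal((2, 5, 6)))
        np.testing.assert_allclose(se(x).data, x.data)

    def test_saturated_gates_double_input(self):
        se = self._block()
        se.fc2.w.data[:] = 0.0
        se.fc2.b.data[:] = 1e9  # sigmoid -> 1 gates
        x = Tensor(rng.standard_normal((2, 5, 6)))
        np.testing.assert_allclose(se(x).data, 2 * x.data, rtol=1e-6)

    def test_gates_in_open_unit_interval(self):
        se = self._block()
        g = se.gates(Tensor(rng.standard_normal((4, 7, 6))))
        assert np.all(g.data > 0) and np.all(g.data < 1)

    def test_squeeze_of_constant_channel(self):
        x = np.zeros((1, 5, 6))
        x[0, :, 2] = 3.7
        squeezed = ag.global_avg_pool(Tensor(x))
        assert squeezed.data[0, 2] == pytest.approx(3.7)

    def test_without_residual_zero_gates_give_zero_map(self):
        # confirms the residual term is what keeps the identity path alive
        se = self._block()
        se.fc2.w.data[:] = 0.0
        se.fc2.b.data[:] = -1e9
        x = Tensor(rng.standard_normal((2, 5, 6)))
        gated_only = x * se.gates(x).reshape(2, 1, 6)
        np.testing.assert_allclose(gated_only.data, 0, atol=1e-12)


class TestRecurrentLayers:
    def test_bilstm_shape(self):
        layer = BiLSTM(3, 5, np.random.default_rng(0))
        out = layer(Tensor(rng.standard_normal((2, 7, 3))))
        assert out.shape == (2, 7, 10)

    def test_bigru_shape(self):
        layer = BiGRU(3, 4, np.random.default_rng(0))
        out = layer(Tensor(rng.standard_normal((2, 7, 3))))
        assert out.shape == (2, 7, 8)

    def test_direction_symmetry(self):
        # reversing the input sequence swaps the two directional halves
        layer = BiLSTM(3, 4, np.random.default_rng(0))
        # tie the two directions' weights so the symmetry is exact
        layer.wx_b.data = layer.wx_f.data.copy()
        layer.wh_b.data = layer.wh_f.data.copy()
        layer.b_b.data = layer.b_f.data.copy()
        x = rng.standard_normal((1, 6, 3))
        out_fwd = layer(Tensor(x)).data
        out_rev = layer(Tensor(x[:, ::-1, :].copy())).data
        np.testing.assert_allclose(out_fwd[:, :, :4],
                                   out_rev[:, ::-1, 4:], atol=1e-6)
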