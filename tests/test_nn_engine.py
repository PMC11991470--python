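"""Autograd engine: analytic gradients vs numerical differentiation,
primitive forwards vs naive NumPy oracles, optimizer behavior."""

import numpy as np
import pytest
from scipy.special import log_softmax as scipy_log_softmax

from bandfuse.nn import (Adam, BatchNorm, Conv2d, Conv3d, DepthwiseConv2d,
                         LayerNorm, Linear, SGD, StepLR, Tensor,
                         TransformerEncoderLayer, adaptive_avg_pool_hw,
                         concat, cross_entropy, maxpool2d, maxpool2d_3x3s1,
                         maxpool_hw, softmax)

rng = np.random.default_rng(0)


def numerical_grad(f, x, eps=1e-3):
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x.data[i]
        x.data[i] = orig + eps
        fp = float(f().data)
        x.data[i] = orig - eps
        fm = float(f().data)
        x.data[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(f, params, tol=5e-2):
    for p in params:
        p.grad = None
    f().backward()
    for p in params:
        num = numerical_grad(f, p)
        scale = max(np.abs(num).max(), 1e-4)
        assert np.abs(num - p.grad).max() / scale < tol


class TestGradients:
    def test_conv2d_chain(self):
        x = Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
        conv = Conv2d(3, 4, 3, rng, stride=2, padding=1)
        lin = Linear(4 * 4 * 4, 5, rng)
        y = np.array([1, 3])

        def f():
            h = conv(x).relu().reshape(2, -1)
            return cross_entropy(lin(h), y)

        assert_grad_matches(f, [x, conv.weight, conv.bias, lin.weight])

    def test_conv3d_tanh_pool(self):
        x = Tensor(rng.normal(size=(2, 1, 4, 6, 6)), requires_grad=True)
        conv = Conv3d(1, 2, 3, rng, padding=1)

        def f():
            h = conv(x).tanh()
            return (adaptive_avg_pool_hw(h, (2, 2)) ** 2.0).mean()

        assert_grad_matches(f, [x, conv.weight, conv.bias])

    def test_depthwise_conv(self):
        x = Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        dw = DepthwiseConv2d(3, 3, rng, stride=2, padding=1)
        assert_grad_matches(lambda: (dw(x) ** 2.0).mean(),
                            [x, dw.weight, dw.bias])

    @pytest.mark.parametrize("pool", [
        lambda x: maxpool_hw(x, 2),
        maxpool2d_3x3s1,
        lambda x: maxpool2d(x, 3, stride=2, padding=1),
    ])
    def test_max_pools(self, pool):
        # distinct, well-gapped values: no near-ties for the finite
        # differencing to split across
        local = np.random.default_rng(42)
        vals = local.permutation(np.linspace(-1.0, 1.0, 144)).reshape(2, 2, 6, 6)
        x = Tensor(vals, requires_grad=True)
        w = Tensor(np.array([1.7]))
        assert_grad_matches(lambda: (pool(x) * w).sum(), [x], tol=5e-2)

    def test_batchnorm_train_mode(self):
        x = Tensor(rng.normal(size=(4, 3, 5, 5)), requires_grad=True)
        bn = BatchNorm(3)
        assert_grad_matches(lambda: (bn(x) ** 3.0).mean(),
                            [x, bn.gamma, bn.beta])

    def test_layernorm(self):
        x = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
        ln = LayerNorm(4)
        assert_grad_matches(lambda: (ln(x) ** 3.0).mean(),
                            [x, ln.gamma, ln.beta])

    def test_concat(self):
        a = Tensor(rng.normal(size=(2, 2, 3, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 3, 3, 3)), requires_grad=True)
        assert_grad_matches(lambda: (concat([a, b], axis=1) ** 2.0).mean(),
                            [a, b])

    def test_encoder_directional_derivative(self):
        # full-layer check along the analytic gradient direction (float32
        # elementwise differencing is too noisy for a normalized output)
        x = Tensor(rng.normal(size=(2, 4, 8)), requires_grad=True)
        enc = TransformerEncoderLayer(8, 2, 16, rng)
        w = Tensor(rng.normal(size=(2, 4, 8)))

        def loss():
            return (enc(x) * w).sum()

        loss().backward()
        g = x.grad.copy()
        d = g / np.linalg.norm(g)
        eps = 1e-2
        orig = x.data.copy()
        x.data = orig + eps * d
        fp = float(loss().data)
        x.data = orig - eps * d
        fm = float(loss().data)
        x.data = orig
        assert abs((fp - fm) / (2 * eps) - float((g * d).sum())) < 1e-2 * abs(
            float((g * d).sum()))


class TestForwardOracles:
    def test_softmax_rows_sum_to_one(self):
        x = Tensor(rng.normal(size=(5, 7)) * 10)
        s = softmax(x, axis=-1)
        np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_cross_entropy_matches_scipy(self):
        logits = rng.normal(size=(6, 4)) * 5
        y = rng.integers(0, 4, size=6)
        ours = float(cross_entropy(Tensor(logits), y).data)
        ref = -scipy_log_softmax(logits, axis=1)[np.arange(6), y].mean()
        assert abs(ours - ref) < 1e-5

    def test_maxpool_matches_naive_loop(self):
        x = rng.normal(size=(1, 2, 7, 7)).astype(np.float32)
        out = maxpool2d(Tensor(x), 3, stride=2, padding=0).data
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    assert out[0, c, i, j] == x[0, c, 2*i:2*i+3, 2*j:2*j+3].max()

    def test_adaptive_pool_uneven_bins(self):
        x = rng.normal(size=(1, 1, 10, 10)).astype(np.float32)
        out = adaptive_avg_pool_hw(Tensor(x), (3, 3)).data
        # bin 0 of a length-10 axis at output 3 covers rows 0..3 inclusive
        assert np.isclose(out[0, 0, 0, 0], x[0, 0, 0:4, 0:4].mean())
        assert np.isclose(out[0, 0, 2, 2], x[0, 0, 6:10, 6:10].mean())


class TestOptim:
    def _problem(self):
        x = rng.normal(size=(16, 4)).astype(np.float32)
        y = (x[:, 0] > 0).astype(np.int64)
        lin = Linear(4, 2, np.random.default_rng(1))
        return x, y, lin

    @pytest.mark.parametrize("make_opt", [
        lambda p: SGD(p, lr=0.1),
        lambda p: Adam(p, lr=0.05),
    ])
    def test_loss_decreases(self, make_opt):
        x, y, lin = self._problem()
        opt = make_opt(lin.parameters())
        losses = []
        for _ in range(30):
            loss = cross_entropy(lin(Tensor(x)), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < 0.5 * losses[0]

    def test_step_scheduler_halves_lr(self):
        _, _, lin = self._problem()
        opt = Adam(lin.parameters(), lr=1e-3)
        sched = StepLR(opt, step_size=5, gamma=0.5)
        for _ in range(5):
            sched.step()
        assert np.isclose(opt.lr, 5e-4)
        for _ in range(5):
            sched.step()
        assert np.isclose(opt.lr, 2.5e-4)
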