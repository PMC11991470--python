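"""Architecture contracts: shapes, branch arithmetic, activation ranges,
gradient flow, and single-step trainability."""

import numpy as np
import pytest

from bandfuse.networks import (Catt, CattSpec, Cres, CresSpec, NetworkConfig,
                               build_backbone, build_catt, build_cres,
                               build_network, build_tinycnn)
from bandfuse.nn import Tensor, cross_entropy
from bandfuse.nn.layers import sinusoidal_positional_encoding

rng = np.random.default_rng(0)


def _batch(n, c, h, w):
    return Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))


class TestCres:
    def test_preflatten_map_is_512x4x4(self):
        net = build_cres(None, NetworkConfig("cres", 13, 10, (64, 64)), 1)
        f = net.forward_features(_batch(2, 13, 64, 64))
        assert f.shape == (2, 512, 4, 4)

    def test_single_band_input_accepted(self):
        net = build_cres(None, NetworkConfig("cres", 1, 4, (32, 32)), 1)
        assert net(_batch(2, 1, 32, 32)).shape == (2, 4)

    def test_branch_filter_arithmetic(self):
        net = build_cres(None, NetworkConfig("cres", 3, 5, (64, 64)), 1)
        for block, f in zip(net.blocks[::2], (128, 256, 512)):
            inc = block.inception
            outs = [inc.branch1.layers[0].weight.shape[0],
                    inc.branch2.layers[1].layers[0].weight.shape[0],
                    inc.branch3.layers[1].layers[0].weight.shape[0],
                    inc.branch4.layers[0].weight.shape[0]]
            assert outs == [f // 4] * 4
            assert block.residual.weight.shape[0] == f

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            build_cres(None, NetworkConfig("cres", 3, 5, (50, 50)), 1)

    def test_channel_doubling_enforced(self):
        with pytest.raises(ValueError, match="double"):
            CresSpec(filters_per_block=(128, 128, 512))


class TestCatt:
    @pytest.mark.parametrize("size", [32, 64])
    def test_pooled_map_fixed_at_8x8(self, size):
        net = build_catt(None, NetworkConfig("catt", 10, 17, (size, size)), 1)
        pooled = net.forward_pooled(_batch(2, 10, size, size))
        assert pooled.shape == (2, 128, 8, 8)

    def test_head_independent_of_input_size(self):
        spec = CattSpec()
        n32 = build_catt(spec, NetworkConfig("catt", 10, 17, (32, 32)), 1)
        n64 = build_catt(spec, NetworkConfig("catt", 10, 17, (64, 64)), 1)
        assert n32.head.weight.shape == n64.head.weight.shape
        assert n32.n_parameters() == n64.n_parameters()

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            build_catt(None, NetworkConfig("catt", 4, 3, (6, 6)), 1)

    def test_conv_block_activations_bounded(self):
        net = build_catt(None, NetworkConfig("catt", 6, 3, (32, 32)), 1)
        x = Tensor(rng.normal(size=(2, 1, 6, 32, 32)).astype(np.float32) * 50)
        for block in (net.block1, net.block2, net.block3):
            x = block(x)
            assert np.abs(x.data).max() <= 1.0 + 1e-6
            from bandfuse.nn import maxpool_hw
            if x.shape[-1] > 8:
                x = maxpool_hw(x, 2)

    def test_attention_rows_sum_to_one(self):
        net = build_catt(None, NetworkConfig("catt", 6, 3, (32, 32)), 1)
        net(_batch(2, 6, 32, 32))
        for enc in net.encoders:
            attn = enc.attn.last_attn
            assert attn.shape[-2:] == (64, 64)
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)

    def test_positional_encoding_closed_form(self):
        pe = sinusoidal_positional_encoding(64, 256)
        np.testing.assert_allclose(pe[0, 0::2], 0.0, atol=1e-7)
        np.testing.assert_allclose(pe[0, 1::2], 1.0, atol=1e-7)
        # pos=1, i=0: sin(1), cos(1)
        assert np.isclose(pe[1, 0], np.sin(1.0), atol=1e-6)
        assert np.isclose(pe[1, 1], np.cos(1.0), atol=1e-6)


class TestBackbones:
    @pytest.mark.parametrize("arch", ["resnet50", "densenet201", "mobilenetv2"])
    def test_output_shape(self, arch):
        net = build_backbone(NetworkConfig(arch, 3, 7, (64, 64)), 1)
        net.eval()
        assert net(_batch(2, 3, 64, 64)).shape == (2, 7)

    @pytest.mark.parametrize("arch", ["resnet50", "densenet201", "mobilenetv2"])
    def test_head_swap_preserves_trunk(self, arch):
        a = build_backbone(NetworkConfig(arch, 3, 7, (64, 64)), 1)
        b = build_backbone(NetworkConfig(arch, 3, 23, (64, 64)), 1)
        head_a = a.head.weight.data.size + a.head.bias.data.size
        head_b = b.head.weight.data.size + b.head.bias.data.size
        assert a.n_parameters() - head_a == b.n_parameters() - head_b

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ValueError, match="3-channel"):
            NetworkConfig("resnet50", 13, 7, (64, 64))

    def test_eval_mode_deterministic(self):
        net = build_backbone(NetworkConfig("mobilenetv2", 3, 5, (32, 32)), 1)
        net.eval()
        x = _batch(2, 3, 32, 32)
        np.testing.assert_array_equal(net(x).data, net(x).data)


class TestTinyCNN:
    def test_shape_and_size(self):
        net = build_tinycnn(NetworkConfig("tinycnn", 3, 9, (32, 32)), 1)
        assert net(_batch(4, 3, 32, 32)).shape == (4, 9)
        assert net.n_parameters() < 50_000

    def test_all_parameters_receive_gradient(self):
        net = build_tinycnn(NetworkConfig("tinycnn", 3, 4, (32, 32)), 1)
        loss = cross_entropy(net(_batch(8, 3, 32, 32)),
                             np.array([0, 1, 2, 3] * 2))
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


SHAPE_CASES = [(c, s) for c in (1, 3, 10, 13, 16) for s in (32, 64)]


@pytest.mark.parametrize("arch", ["tinycnn", "cres", "catt"])
@pytest.mark.parametrize("in_channels,size", SHAPE_CASES)
def test_multichannel_shape_contracts(arch, in_channels, size):
    cfg = NetworkConfig(arch, in_channels, 6, (size, size))
    net = build_network(cfg, 1)
    net.eval()
    assert net(_batch(2, in_channels, size, size)).shape == (2, 6)


ONE_STEP_CASES = [
    ("tinycnn", 5, 32), ("cres", 5, 32), ("catt", 5, 32),
    ("resnet50", 3, 32), ("densenet201", 3, 32), ("mobilenetv2", 3, 32),
]


@pytest.mark.parametrize("arch,c,size", ONE_STEP_CASES)
def test_one_sgd_step_decreases_batch_loss(arch, c, size):
    """The backward pass yields a descent direction: some small step
    along the negative gradient strictly lowers the batch loss.  (The
    usable step scale varies by architecture — batch-norm at batch 4
    makes the deep nets sharply curved — so a small grid is probed.)"""
    cfg = NetworkConfig(arch, c, 4, (size, size))
    net = build_network(cfg, 3)
    x = Tensor(np.random.default_rng(5).normal(
        size=(4, c, size, size)).astype(np.float32))
    y = np.array([0, 1, 2, 3])
    loss0 = cross_entropy(net(x), y)
    loss0.backward()
    params = net.parameters()
    w0 = [p.data.copy() for p in params]
    decreased = False
    for lr in (1e-3, 1e-5, 1e-7, 3e-8, 1e-8):
        for p, w in zip(params, w0):
            p.data = w - lr * p.grad
        if float(cross_entropy(net(x), y).data) < float(loss0.data):
            decreased = True
            break
    assert decreased


@pytest.mark.parametrize("arch,c,size", ONE_STEP_CASES)
def test_every_parameter_tensor_gets_gradient(arch, c, size):
    cfg = NetworkConfig(arch, c, 4, (size, size))
    net = build_network(cfg, 3)
    x = Tensor(np.random.default_rng(5).normal(
        size=(4, c, size, size)).astype(np.float32))
    cross_entropy(net(x), np.array([0, 1, 2, 3])).backward()
    for name, p in net.named_parameters():
        assert p.grad is not None, name
        assert np.any(p.grad != 0), name
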