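"""Architecture contracts: shapes, attention gate, parameters, gradients."""

import numpy as np
import pytest

from somaseg.losses import branch_loss_grad
from somaseg.nn.model import (
    AttentionGate,
    MultiTaskUNet3D,
    NetworkConfig,
    build_network,
    count_parameters,
)


@pytest.fixture(scope="module")
def tiny_net():
    return MultiTaskUNet3D(
        NetworkConfig(root_features=2, levels=2, convs_per_block=1), seed=0
    )


class TestShapes:
    def test_output_matches_input_spatial_shape(self, tiny_net):
        x = np.random.default_rng(0).normal(size=(16, 16, 16)).astype(np.float32)
        soma, bou = tiny_net.forward(x)
        assert soma.shape == bou.shape == x.shape
        assert (soma >= 0).all() and (soma <= 1).all()
        assert (bou >= 0).all() and (bou <= 1).all()

    def test_indivisible_shape_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="divisible"):
            tiny_net.forward(np.zeros((10, 16, 16), np.float32))

    def test_eval_mode_is_deterministic(self, tiny_net):
        x = np.random.default_rng(1).normal(size=(8, 8, 8)).astype(np.float32)
        a = tiny_net.forward(x)
        b = tiny_net.forward(x)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_zeroed_heads_give_half_everywhere(self):
        net = MultiTaskUNet3D(
            NetworkConfig(root_features=2, levels=1, convs_per_block=1), seed=0
        )
        for head in (net.head_soma, net.head_boundary):
            head.weight.value[:] = 0
            head.bias.value[:] = 0
        soma, bou = net.forward(np.random.default_rng(2).normal(
            size=(8, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(soma, 0.5, atol=1e-7)
        np.testing.assert_allclose(bou, 0.5, atol=1e-7)

    def test_no_nan_for_extreme_inputs(self, tiny_net):
        x = np.full((8, 8, 8), 50.0, np.float32)
        soma, bou = tiny_net.forward(x)
        assert np.isfinite(soma).all() and np.isfinite(bou).all()

    def test_invalid_config_named_error(self):
        with pytest.raises(ValueError, match="root_features"):
            NetworkConfig(root_features=0)
        with pytest.raises(ValueError, match="levels"):
            NetworkConfig(levels=0)


class TestAttentionGate:
    def _gate(self, seed=0):
        rng = np.random.default_rng(seed)
        return AttentionGate(skip_channels=1, gate_channels=2, rng=rng), rng

    def test_saturated_positive_bias_passes_skip_through(self):
        gate, rng = self._gate()
        gate.psi.bias.value[:] = 50.0
        skip = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        gating = rng.normal(size=(1, 2, 2, 2, 2)).astype(np.float32)
        out = gate.forward_pair(skip, gating)
        np.testing.assert_allclose(out, skip, atol=1e-5)

    def test_saturated_negative_bias_suppresses(self):
        gate, rng = self._gate()
        gate.psi.bias.value[:] = -50.0
        skip = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        gating = rng.normal(size=(1, 2, 2, 2, 2)).astype(np.float32)
        out = gate.forward_pair(skip, gating)
        np.testing.assert_allclose(out, 0.0, atol=1e-5)

    def test_hand_computed_small_tensor(self):
        """2x2x2 skip, 1 channel: replicate the coefficient formula with
        plain numpy on the gate's own weights."""
        gate, rng = self._gate(seed=3)
        skip = rng.normal(size=(1, 1, 2, 2, 2)).astype(np.float32)
        gating = rng.normal(size=(1, 2, 1, 1, 1)).astype(np.float32)
        out = gate.forward_pair(skip, gating)

        wx = gate.wx.weight.value[:, :, 0, 0, 0]   # (2, 1)
        bx = gate.wx.bias.value
        wg = gate.wg.weight.value[:, :, 0, 0, 0]   # (2, 2)
        bg = gate.wg.bias.value
        wpsi = gate.psi.weight.value[:, :, 0, 0, 0]  # (1, 2)
        bpsi = gate.psi.bias.value
        skip_down = skip[0, :, 0, 0, 0]  # stride-2 1x1x1 conv samples voxel 0
        merged = wx @ skip_down + bx + wg @ gating[0, :, 0, 0, 0] + bg
        a = np.maximum(merged, 0)
        alpha = 1.0 / (1.0 + np.exp(-(wpsi @ a + bpsi)))
        expected = skip * alpha  # nearest-upsampled scalar coefficient
        np.testing.assert_allclose(out, expected, rtol=1e-5)
        assert 0.0 <= alpha[0] <= 1.0

    def test_resolution_mismatch_rejected(self):
        gate, rng = self._gate()
        with pytest.raises(ValueError, match="resolution"):
            gate.forward_pair(
                np.zeros((1, 1, 4, 4, 4), np.float32),
                np.zeros((1, 2, 3, 3, 3), np.float32),
            )


class TestParameters:
    def test_micro_network_hand_tally(self):
        """root 1, 1 level, 1 conv/block, no attention, no BN: sum the 3^3
        and 1^3 kernels and biases by hand."""
        net = MultiTaskUNet3D(
            NetworkConfig(root_features=1, levels=1, convs_per_block=1,
                          use_attention=False, use_batchnorm=False),
            seed=0,
        )
        expected = (
            (27 * 1 * 1 + 1)      # enc0 conv 1->1
            + (8 * 1 * 2 + 2)     # down0 2^3 stride-2 conv 1->2
            + (27 * 2 * 2 + 2)    # bottleneck conv 2->2
            + (8 * 2 * 1 + 1)     # up0 deconv 2->1
            + (27 * 2 * 1 + 1)    # dec0 conv (1+1)->1
            + 2 * (1 * 1 + 1)     # two 1x1x1 heads
        )
        assert count_parameters(net) == expected

    def test_doubling_root_features_roughly_quadruples(self):
        small = count_parameters(
            MultiTaskUNet3D(NetworkConfig(root_features=8), seed=0)
        )
        big = count_parameters(
            MultiTaskUNet3D(NetworkConfig(root_features=16), seed=0)
        )
        assert 3.5 < big / small < 4.5

    def test_default_config_near_one_million(self):
        n = count_parameters(build_network(NetworkConfig()))
        assert 700_000 <= n <= 1_200_000


class TestGradients:
    def test_every_block_updates_after_one_step(self, rng):
        net = MultiTaskUNet3D(
            NetworkConfig(root_features=2, levels=2, convs_per_block=1), seed=0
        )
        opt = net.make_optimizer(lr=0.01)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        y = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float32)
        before = {
            g: [p.value.copy() for p in ps]
            for g, ps in net.param_groups().items()
        }
        soma, bou = net.forward(x, training=True)
        opt.zero_grad()
        net.backward(branch_loss_grad(soma, y), branch_loss_grad(bou, y))
        opt.step()
        for g, ps in net.param_groups().items():
            changed = any(
                not np.array_equal(old, p.value)
                for old, p in zip(before[g], ps)
            )
            assert changed, f"no parameter changed in block {g}"

    def test_attention_off_ablation_builds_and_trains(self, rng):
        net = MultiTaskUNet3D(
            NetworkConfig(root_features=2, use_attention=False), seed=0
        )
        assert all(a is None for a in net.att)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        y = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float32)
        opt = net.make_optimizer()
        soma, bou = net.forward(x, training=True)
        opt.zero_grad()
        net.backward(branch_loss_grad(soma, y), branch_loss_grad(bou, y))
        opt.step()
        soma2, _ = net.forward(x)
        assert soma2.shape == (1, 8, 8, 8)


class TestStateDict:
    def test_round_trip_reproduces_outputs(self, rng):
        cfg = NetworkConfig(root_features=2, levels=1)
        a = MultiTaskUNet3D(cfg, seed=1)
        x = rng.normal(size=(8, 8, 8)).astype(np.float32)
        expected = a.forward(x)
        b = MultiTaskUNet3D(cfg, seed=99)
        b.load_state_dict(a.state_dict())
        got = b.forward(x)
        np.testing.assert_array_equal(expected[0], got[0])
        np.testing.assert_array_equal(expected[1], got[1])
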