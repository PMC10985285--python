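"""Convolution primitives, attention block, backbone and training contracts."""

import numpy as np
import pytest
from scipy.signal import correlate
from scipy.special import expit

from degenmhc.nn import (
    ConvNeXtMHCNet,
    ModelConfig,
    SimpleCNN,
    depthwise_conv,
    fit_network,
    init_attention_weights,
    pointwise_stack,
    transfer_weights,
)
from degenmhc.nn.net import AttentionBlock, DivergenceError


def brute_force_depthwise(x, kernels):
    C, K, L = kernels.shape
    H, W, _ = x.shape
    out = np.zeros((H - K + 1, W - L + 1, C))
    for i in range(H - K + 1):
        for j in range(W - L + 1):
            for c in range(C):
                for k in range(K):
                    for l in range(L):
                        out[i, j, c] += kernels[c, k, l] * x[i + k, j + l, c]
    return out


class TestConvPrimitives:
    def test_1x1_identity_kernel(self, rng):
        x = rng.normal(size=(4, 5, 3))
        k = np.ones((3, 1, 1))
        assert np.allclose(depthwise_conv(x, k), x)

    def test_all_ones_2x2_on_2x2(self):
        x = np.arange(4.0).reshape(2, 2, 1)
        out = depthwise_conv(x, np.ones((1, 2, 2)))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == 6.0

    def test_matches_quadruple_loop_oracle(self, rng):
        x = rng.normal(size=(5, 5, 3))
        k = rng.normal(size=(3, 2, 3))
        assert np.abs(depthwise_conv(x, k) - brute_force_depthwise(x, k)).max() < 1e-6

    def test_matches_scipy_correlate(self, rng):
        x = rng.normal(size=(6, 7, 2))
        k = rng.normal(size=(2, 3, 3))
        ours = depthwise_conv(x, k)
        for c in range(2):
            ref = correlate(x[:, :, c], k[c], mode="valid")
            assert np.allclose(ours[:, :, c], ref, atol=1e-10)

    def test_channel_independence(self, rng):
        x = rng.normal(size=(5, 5, 3))
        k = rng.normal(size=(3, 2, 2))
        base = depthwise_conv(x, k)
        x2 = x.copy()
        x2[:, :, 1] += rng.normal(size=(5, 5))
        out = depthwise_conv(x2, k)
        assert np.allclose(out[:, :, 0], base[:, :, 0])
        assert np.allclose(out[:, :, 2], base[:, :, 2])
        assert not np.allclose(out[:, :, 1], base[:, :, 1])

    def test_kernel_larger_than_input_errors(self, rng):
        with pytest.raises(ValueError, match="larger than input"):
            depthwise_conv(rng.normal(size=(2, 2, 1)), np.ones((1, 3, 3)))

    def test_pointwise_stack_identity_and_sum_mix(self, rng):
        x = rng.normal(size=(4, 4, 2))
        ident = np.ones((2, 1, 1))
        assert np.allclose(pointwise_stack(x, ident, mix=np.eye(2)), x)
        summed = pointwise_stack(x, ident, mix=np.array([[1.0], [1.0]]))
        assert np.allclose(summed[:, :, 0], x.sum(axis=2))

    def test_pointwise_spatial_extent_matches_depthwise(self, rng):
        x = rng.normal(size=(5, 6, 3))
        k = rng.normal(size=(3, 2, 2))
        assert pointwise_stack(x, k, mix=rng.normal(size=(3, 4))).shape[:2] \
            == depthwise_conv(x, k).shape[:2]


class TestAttentionInit:
    def test_uniform_frequencies_fall_back_to_ones(self):
        w = init_attention_weights(np.full(20, 0.05))
        assert np.all(w == 1.0)

    def test_minmax_endpoints(self):
        f = np.full(20, (1 - 0.11 - 0.01) / 18)
        f[0], f[1] = 0.11, 0.01
        w = init_attention_weights(f)
        assert w[0] == 1.0 and w[1] == 0.0

    def test_midpoint_value(self):
        f = np.full(20, 0.0, dtype=float)
        f[0], f[1], f[2] = 0.01, 0.11, 0.06
        f[3:] = (1 - f[:3].sum()) / 17
        w = init_attention_weights(f)
        assert w[2] == pytest.approx((0.06 - 0.01) / (0.11 - 0.01), abs=1e-12)

    def test_invalid_frequencies(self):
        bad = np.full(20, 0.05)
        bad[0] = -0.01
        bad[1] = 0.11
        with pytest.raises(ValueError):
            init_attention_weights(bad)


class TestAttentionBlock:
    def test_zero_weights_zero_init_gives_half(self, rng):
        blk = AttentionBlock("a", 20, 9, 21, 3, np.zeros(20))
        x = rng.random((4, 20, 9, 21))
        assert np.allclose(blk.scores(x), 0.5)

    def test_zero_weights_unit_init_gives_logistic_one(self, rng):
        blk = AttentionBlock("a", 20, 9, 21, 3, np.ones(20))
        x = rng.random((4, 20, 9, 21))
        assert np.allclose(blk.scores(x), expit(1.0), atol=1e-6)
        assert np.allclose(blk.scores(x), 0.7310585786300049, atol=1e-6)

    def test_scores_strictly_inside_unit_interval(self, rng):
        blk = AttentionBlock("a", 20, 9, 21, 3, rng.random(20))
        blk.params["U"] = rng.normal(size=blk.params["U"].shape).astype(np.float32)
        s = blk.scores(rng.random((8, 20, 9, 21)))
        assert s.shape == (8, 20)
        assert np.all((s > 0) & (s < 1))

    def test_forward_is_per_row_scaling(self, rng):
        blk = AttentionBlock("a", 20, 9, 21, 3, rng.random(20).astype(np.float32))
        blk.params["U"] = rng.normal(scale=0.3, size=blk.params["U"].shape).astype(np.float32)
        x = rng.random((3, 20, 9, 21)).astype(np.float32)
        out = blk.forward(x)
        a = blk.scores(x)
        assert np.allclose(out, x * a[:, :, None, None], atol=1e-6)

    def test_apply_attention_edge_cases(self, rng):
        # scores of exactly 1 (resp. 0) leave the input unchanged (resp. zero it)
        x = rng.random((2, 20, 9, 21))
        assert np.allclose(x * np.ones((2, 20))[:, :, None, None], x)
        assert np.allclose(x * np.zeros((2, 20))[:, :, None, None], 0.0)

    def test_linearity_in_input_for_fixed_scores(self, rng):
        x = rng.random((2, 20, 9, 21))
        a = rng.random((2, 20))
        mixed = (2.0 * x + 0.5 * x) * a[:, :, None, None]
        assert np.allclose(mixed, 2.5 * x * a[:, :, None, None])


class TestGradients:
    """Analytic backward passes agree with central finite differences."""

    @pytest.mark.parametrize("layer_name", ["attn", "block", "cnn_conv"])
    def test_finite_difference_check(self, layer_name, rng):
        from degenmhc.nn.net import Conv2DValid, ConvNeXtBlock

        if layer_name == "attn":
            layer = AttentionBlock("a", 5, 9, 4, 3, np.linspace(0, 1, 5))
            x = rng.random((2, 5, 9, 4))
        elif layer_name == "block":
            layer = ConvNeXtBlock("b", 3, (3, 3), rng)
            x = rng.random((2, 6, 7, 3))
        else:
            layer = Conv2DValid("c", 2, 3, (3, 3), rng)
            x = rng.random((2, 6, 7, 2))
        # float64 copies of parameters for a tight numeric check
        def set_params(layer):
            layers = layer.sublayers if hasattr(layer, "sublayers") else [layer]
            for l in layers:
                for k in l.params:
                    l.params[k] = l.params[k].astype(np.float64)
        set_params(layer)
        g = rng.random(layer.forward(x).shape)
        dx = layer.backward(g)
        eps = 1e-6
        idxs = [tuple(rng.integers(0, s) for s in x.shape) for _ in range(12)]
        for idx in idxs:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = ((layer.forward(xp) * g).sum() - (layer.forward(xm) * g).sum()) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=1e-4, abs=1e-6)


class TestBackbone:
    def test_forward_output_in_unit_interval_and_deterministic(self, rng):
        net = ConvNeXtMHCNet(ModelConfig(head="ap", seed=3))
        x = rng.random((6, 20, 9, 21)).astype(np.float32)
        p1, p2 = net.predict(x), net.predict(x)
        assert np.all((p1 > 0) & (p1 < 1))
        assert np.array_equal(p1, p2)

    def test_param_count_stable_for_fixed_config(self):
        n1 = ConvNeXtMHCNet(ModelConfig(seed=0)).count_params()
        n2 = ConvNeXtMHCNet(ModelConfig(seed=99)).count_params()
        assert n1 == n2 > 0

    def test_save_load_round_trip(self, tmp_path, rng):
        net = ConvNeXtMHCNet(ModelConfig(head="ba", seed=1))
        x = rng.random((3, 20, 9, 21)).astype(np.float32)
        net.save(tmp_path / "model")
        clone = ConvNeXtMHCNet.load(tmp_path / "model")
        assert np.array_equal(net.predict(x), clone.predict(x))
        assert clone.config.head == "ba"

    def test_column_shuffle_changes_output(self, rng):
        # spatial awareness: permuting ILA columns moves the prediction
        net = ConvNeXtMHCNet(ModelConfig(seed=0))
        x = rng.random((1, 20, 9, 21)).astype(np.float32)
        y = rng.integers(0, 2, 1).astype(np.float32)
        fit_network(net, np.repeat(x, 8, 0), np.repeat(y, 8), loss="bce", epochs=3, seed=0)
        shuffled = x[:, :, rng.permutation(9), :]
        assert not np.allclose(net.predict(x), net.predict(shuffled))


class TestTraining:
    def _data(self, rng, n=96):
        x = rng.random((n, 20, 9, 21)).astype(np.float32)
        y = (x[:, 0, 0, 1] > 0.5).astype(np.float32)
        return x, y

    def test_zero_epochs_leaves_parameters_unchanged(self, rng):
        net = ConvNeXtMHCNet(ModelConfig(seed=0))
        before = net.state_dict()
        x, y = self._data(rng)
        fit_network(net, x, y, loss="bce", epochs=0, seed=0)
        after = net.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_fixed_seed_reproducibility(self, rng):
        x, y = self._data(rng)
        losses = []
        for _ in range(2):
            net = ConvNeXtMHCNet(ModelConfig(seed=5))
            h = fit_network(net, x, y, loss="bce", epochs=2, seed=5)
            losses.append(h["train_loss"][-1])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_loss_decreases_on_learnable_signal(self, rng):
        x, y = self._data(rng, n=256)
        net = ConvNeXtMHCNet(ModelConfig(seed=0))
        h = fit_network(net, x, y, loss="bce", epochs=3, seed=0)
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_divergence_raises(self, rng):
        x, y = self._data(rng)
        net = ConvNeXtMHCNet(ModelConfig(seed=0))
        with pytest.raises(DivergenceError):
            fit_network(net, x, y, loss="bce", epochs=2, learning_rate=1e12, seed=0)


class TestTransfer:
    def test_backbone_copied_head_reinitialized(self, rng):
        src = ConvNeXtMHCNet(ModelConfig(head="ap", seed=0))
        x, y = rng.random((64, 20, 9, 21)).astype(np.float32), rng.integers(0, 2, 64).astype(np.float32)
        fit_network(src, x, y, loss="bce", epochs=1, seed=0)
        tgt = transfer_weights(src, target_head="ba")
        s, t = src.state_dict(), tgt.state_dict()
        for k in s:
            if k.startswith("head/"):
                continue
            assert np.array_equal(s[k], t[k]), k
        assert tgt.config.head == "ba"
        assert tgt.transfer_source == src.state_hash()

    def test_architecture_mismatch_errors(self):
        src = ConvNeXtMHCNet(ModelConfig(stage_widths=(16, 32)))
        other = ConvNeXtMHCNet(ModelConfig(stage_widths=(8, 16)))
        with pytest.raises((ValueError, KeyError)):
            other.load_state_dict(src.state_dict())


class TestSimpleCNN:
    def test_accepts_flat_baseline_shapes(self, rng):
        net = SimpleCNN((43, 21, 1), seed=0)
        x = rng.random((4, 43, 21, 1)).astype(np.float32)
        p = net.predict(x)
        assert p.shape == (4,)
        assert np.all((p > 0) & (p < 1))

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            SimpleCNN((2, 9, 21))
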