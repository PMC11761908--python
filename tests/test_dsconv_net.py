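import numpy as np
import pytest

from dsunet._nn import softmax_cross_entropy
from dsunet.dsconv_net import (DSConvBlock, DSUNetClassifier, ModelConfig,
                               classify_head, concat_skip, count_parameters,
                               downsample_avgpool, dsconv_block,
                               dsconv_param_count, load_checkpoint,
                               save_checkpoint, standard_conv_param_count,
                               upsample_bilinear)
from dsunet.errors import ShapeError


def brute_force_dsconv(x, dw_kernel, pw_kernel):
    """Direct nested-summation depthwise + pointwise convolution oracle.

    x: (H, W, Cin); dw_kernel: (Cin, 3, 3); pw_kernel: (Cin, Cout).
    Stride 1, zero padding 1.
    """
    H, W, cin = x.shape
    cout = pw_kernel.shape[1]
    xp = np.zeros((H + 2, W + 2, cin))
    xp[1:-1, 1:-1] = x
    xd = np.zeros((H, W, cin))
    for h in range(H):
        for w in range(W):
            for c in range(cin):
                for i in range(3):
                    for j in range(3):
                        xd[h, w, c] += xp[h + i, w + j, c] * dw_kernel[c, i, j]
    z = np.zeros((H, W, cout))
    for h in range(H):
        for w in range(W):
            for k in range(cout):
                for c in range(cin):
                    z[h, w, k] += xd[h, w, c] * pw_kernel[c, k]
    return z


def identity_block(channels):
    """DSConv block wired as the identity-then-ReLU map."""
    block = DSConvBlock(channels, channels)
    block.depthwise.kernel.value[...] = 0.0
    block.depthwise.kernel.value[:, 1, 1] = 1.0
    block.pointwise.kernel.value[...] = np.eye(channels)
    block.bn.eps = 1e-12
    return block


class TestDSConvBlock:
    def test_identity_composition_gives_relu(self, rng):
        x = rng.standard_normal((6, 6, 3))
        block = identity_block(3)
        out = dsconv_block(x, block, training=False)
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-6)

    @pytest.mark.parametrize("shape,cout", [((5, 5, 2), 3), ((8, 8, 4), 4),
                                            ((4, 7, 3), 2)])
    def test_matches_brute_force_oracle(self, shape, cout, rng):
        x = rng.standard_normal(shape)
        block = DSConvBlock(shape[2], cout, rng=np.random.default_rng(1))
        # bypass BN/ReLU: identity normalization
        block.bn.eps = 1e-12
        dw = block.depthwise.kernel.value
        pw = block.pointwise.kernel.value
        expected = brute_force_dsconv(x, dw, pw)
        got = block.pointwise.forward(
            block.depthwise.forward(np.transpose(x, (2, 0, 1))[None]))
        got = np.transpose(got[0], (1, 2, 0))
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_parameter_count_formula(self):
        block = DSConvBlock(3, 16)
        assert sum(p.value.size for p in block.params()) == 107
        assert dsconv_param_count(3, 16) == 3 * 9 + 3 * 16 + 2 * 16 == 107

    def test_channel_mismatch_rejected(self, rng):
        block = DSConvBlock(3, 8)
        with pytest.raises(ShapeError):
            block.forward(rng.standard_normal((1, 4, 8, 8)))


class TestPoolingAndUpsampling:
    def test_avgpool_direct_values(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        np.testing.assert_allclose(downsample_avgpool(x), [[[2.5]]])

    def test_avgpool_constant(self):
        x = np.full((8, 8, 2), 3.25)
        out = downsample_avgpool(x)
        assert out.shape == (4, 4, 2)
        np.testing.assert_allclose(out, 3.25)

    def test_avgpool_ramp_matches_blockwise_mean(self):
        x = np.arange(16, dtype=float).reshape(4, 4)[:, :, None]
        out = downsample_avgpool(x)
        expected = np.array([[x[0:2, 0:2].mean(), x[0:2, 2:4].mean()],
                             [x[2:4, 0:2].mean(), x[2:4, 2:4].mean()]])
        np.testing.assert_allclose(out[:, :, 0], expected)

    def test_avgpool_odd_dimension_rejected(self):
        with pytest.raises((ShapeError, ValueError)):
            downsample_avgpool(np.zeros((5, 4, 1)))

    def test_upsample_constant_and_shape(self):
        x = np.full((8, 8, 4), 2.5)
        out = upsample_bilinear(x)
        assert out.shape == (16, 16, 4)
        np.testing.assert_allclose(out, 2.5)

    def test_upsample_matches_reference(self, rng):
        from test_io_preprocess import reference_bilinear
        x = rng.standard_normal((2, 2, 1))
        out = upsample_bilinear(x)
        np.testing.assert_allclose(out, reference_bilinear(x, 4, 4), atol=1e-12)


class TestConcatAndHead:
    def test_concat_channels_add_and_order(self, rng):
        up = rng.standard_normal((32, 32, 16))
        enc = rng.standard_normal((32, 32, 8))
        out = concat_skip(up, enc)
        assert out.shape == (32, 32, 24)
        np.testing.assert_array_equal(out[:, :, :16], up)
        np.testing.assert_array_equal(out[:, :, 16:], enc)

    def test_concat_spatial_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            concat_skip(rng.random((32, 32, 4)), rng.random((16, 16, 4)))

    def test_head_constant_channels(self):
        ydec = np.stack([np.full((4, 4), 3.0), np.full((4, 4), 3.0)], axis=2)
        out = classify_head(ydec, np.eye(2), np.zeros(2))
        np.testing.assert_allclose(out, [3.0, 3.0])

    def test_head_zero_weight_returns_bias(self, rng):
        ydec = rng.standard_normal((4, 4, 3))
        out = classify_head(ydec, np.zeros((3, 2)), np.array([1.5, -2.0]))
        np.testing.assert_allclose(out, [1.5, -2.0])

    def test_head_matches_direct_computation(self, rng):
        ydec = rng.standard_normal((5, 7, 3))
        W, b = rng.standard_normal((3, 2)), rng.standard_normal(2)
        expected = ydec.mean(axis=(0, 1)) @ W + b
        np.testing.assert_allclose(classify_head(ydec, W, b), expected)


class TestFullModel:
    def test_output_shape_at_multiple_sizes(self, rng):
        model = DSUNetClassifier(ModelConfig(base_channels=4, input_size=64))
        for size in (64, 32):
            out = model.forward(rng.random((1, 3, size, size)))
            assert out.shape == (1, 2)

    def test_exactly_nine_dsconv_layers(self):
        for c0 in (4, 16):
            model = DSUNetClassifier(ModelConfig(base_channels=c0, input_size=64))
            assert len(model.dsconv_blocks()) == 9
            assert len(model.encoder) == 4 and len(model.decoder) == 4

    def test_channel_schedule(self):
        model = DSUNetClassifier(ModelConfig(base_channels=16))
        assert model.encoder_channels() == [16, 32, 64, 128]
        assert model.bottleneck.c_out == 256
        assert [b.c_out for b in model.decoder] == [128, 64, 32, 16]

    def test_spatial_dims_halve_and_restore(self, rng):
        model = DSUNetClassifier(ModelConfig(base_channels=2, input_size=32))
        x = rng.random((1, 3, 32, 32))
        sizes = []
        for block, pool in zip(model.encoder, model.pools):
            x = block.forward(x, training=False)
            sizes.append(x.shape[2])
            x = pool.forward(x)
        assert sizes == [32, 16, 8, 4]
        assert x.shape[2] == 2

    def test_invalid_size_rejected(self, rng):
        model = DSUNetClassifier(ModelConfig(base_channels=2, input_size=32))
        with pytest.raises(ShapeError):
            model.forward(rng.random((1, 3, 24, 24)))

    def test_gradients_match_finite_differences(self, rng):
        model = DSUNetClassifier(ModelConfig(base_channels=2, input_size=16), seed=3)
        x = rng.random((2, 3, 16, 16))
        y = np.array([0, 1])
        for p in model.params():
            p.zero_grad()
        loss, dlogits = softmax_cross_entropy(model.forward(x, training=True), y)
        model.backward(dlogits)
        eps = 1e-6
        checks = [model.encoder[0].depthwise.kernel,
                  model.bottleneck.pointwise.kernel,
                  model.decoder[3].bn.beta, model.head.weight]
        for p in checks:
            idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.grad.shape)
            analytic = p.grad[idx]
            p.value[idx] += eps
            l1, _ = softmax_cross_entropy(model.forward(x, training=True), y)
            p.value[idx] -= 2 * eps
            l2, _ = softmax_cross_entropy(model.forward(x, training=True), y)
            p.value[idx] += eps
            assert analytic == pytest.approx((l1 - l2) / (2 * eps), rel=1e-4, abs=1e-8)


class TestParameterCounting:
    def test_enumeration_equals_closed_form(self):
        cfg = ModelConfig(base_channels=16)
        model = DSUNetClassifier(cfg)
        c0 = cfg.base_channels
        enc = [cfg.in_channels, c0, 2 * c0, 4 * c0]
        enc_out = [c0, 2 * c0, 4 * c0, 8 * c0]
        closed = sum(dsconv_param_count(i, o) for i, o in zip(enc, enc_out))
        closed += dsconv_param_count(8 * c0, 16 * c0)
        dec_in = [16 * c0 + 8 * c0, 8 * c0 + 4 * c0, 4 * c0 + 2 * c0, 2 * c0 + c0]
        dec_out = [8 * c0, 4 * c0, 2 * c0, c0]
        closed += sum(dsconv_param_count(i, o) for i, o in zip(dec_in, dec_out))
        closed += c0 * cfg.num_classes + cfg.num_classes
        assert count_parameters(model) == closed

    def test_single_block_count(self):
        assert dsconv_param_count(3, 16) == 107

    def test_fewer_params_than_standard_convs(self):
        c0 = 16
        pairs = ([(3, c0), (c0, 2 * c0), (2 * c0, 4 * c0), (4 * c0, 8 * c0),
                  (8 * c0, 16 * c0), (24 * c0, 8 * c0), (12 * c0, 4 * c0),
                  (6 * c0, 2 * c0), (3 * c0, c0)])
        ds = sum(dsconv_param_count(i, o) for i, o in pairs)
        std = sum(standard_conv_param_count(i, o) for i, o in pairs)
        assert ds < std

    def test_multiply_cost_ratio(self):
        # depthwise-separable / standard multiply count = 1/Cout + 1/K^2
        H = W = 10
        for cin, cout in [(8, 16), (16, 32), (4, 4)]:
            ds_mults = H * W * cin * 9 + H * W * cin * cout
            std_mults = H * W * cin * cout * 9
            assert ds_mults / std_mults == pytest.approx(1 / cout + 1 / 9)


def test_checkpoint_round_trip(tmp_path, rng):
    model = DSUNetClassifier(ModelConfig(base_channels=2, input_size=32), seed=5)
    x = rng.random((2, 3, 32, 32))
    model.forward(x, training=True)  # populate running BN stats
    before = model.forward(x, training=False)
    save_checkpoint(model, tmp_path / "ckpt.npz", seed=5)
    loaded = load_checkpoint(tmp_path / "ckpt.npz")
    after = loaded.forward(x, training=False)
    np.testing.assert_array_equal(before, after)
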