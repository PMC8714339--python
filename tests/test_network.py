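"""Architecture: pooling/unpooling round trips, pyramid module, gradients."""

import numpy as np
import pytest

from gbseg import nn, network
from gbseg.network import (NetworkConfig, SegNet, ShapeError, ConfigurationError,
                           max_pool_with_indices, max_unpool, pyramid_pool, relu)

RNG = np.random.default_rng(1234)


def brute_force_pool(x):
    """Exhaustive 2x2 window maxima with argmax positions (single 2-D map)."""
    h, w = x.shape
    out = np.zeros((h // 2, w // 2), dtype=x.dtype)
    pos = np.zeros((h // 2, w // 2), dtype=np.int64)
    for i in range(h // 2):
        for j in range(w // 2):
            window = x[2 * i:2 * i + 2, 2 * j:2 * j + 2]
            k = int(window.argmax())
            out[i, j] = window.flat[k]
            pos[i, j] = (2 * i + k // 2) * w + (2 * j + k % 2)
    return out, pos


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(3, 3), (-2, 0), (0, 0)])
    def test_scalar_branches(self, x, expected):
        assert relu(x) == expected

    def test_idempotent(self):
        v = RNG.normal(size=(5, 7))
        assert np.array_equal(relu(relu(v)), relu(v))


class TestMaxPool:
    def test_matches_bruteforce(self):
        for shape in [(4, 4), (6, 8), (16, 16)]:
            x = RNG.permutation(np.arange(shape[0] * shape[1], dtype=np.float32)
                                ).reshape(shape)  # distinct values
            pooled, idx = max_pool_with_indices(x)
            ref_out, ref_pos = brute_force_pool(x)
            assert np.array_equal(pooled, ref_out)
            assert np.array_equal(idx.indices, ref_pos)

    def test_constant_map(self):
        pooled, idx = max_pool_with_indices(np.full((8, 8), 2.5, dtype=np.float32))
        assert pooled.shape == (4, 4)
        assert (pooled == 2.5).all()
        assert idx.indices.min() >= 0 and idx.indices.max() < 64

    def test_shape_contract_batched(self):
        x = RNG.normal(size=(2, 3, 8, 12)).astype(np.float32)
        pooled, idx = max_pool_with_indices(x)
        assert pooled.shape == (2, 3, 4, 6)
        assert idx.input_hw == (8, 12)

    def test_odd_dims_rejected(self):
        with pytest.raises(ShapeError):
            max_pool_with_indices(np.zeros((5, 6), dtype=np.float32))


class TestMaxUnpool:
    def test_roundtrip_scatter(self):
        """unpool(pool(x)) has the windowwise maxima at their original
        positions and zeros elsewhere, per the brute-force oracle."""
        x = RNG.normal(size=(10, 14)).astype(np.float32)
        pooled, idx = max_pool_with_indices(x)
        restored = max_unpool(pooled, idx)
        ref_out, ref_pos = brute_force_pool(x)
        expected = np.zeros(x.size, dtype=np.float32)
        expected[ref_pos.ravel()] = ref_out.ravel()
        assert np.array_equal(restored, expected.reshape(x.shape))

    def test_value_conservation(self):
        x = RNG.normal(size=(1, 4, 8, 8)).astype(np.float32)
        pooled, idx = max_pool_with_indices(x)
        restored = max_unpool(pooled, idx)
        assert restored.sum() == pytest.approx(pooled.sum(), abs=1e-4)

    def test_zero_map(self):
        x = RNG.normal(size=(6, 6)).astype(np.float32)
        pooled, idx = max_pool_with_indices(x)
        assert (max_unpool(np.zeros_like(pooled), idx) == 0).all()

    def test_out_of_range_indices_rejected(self):
        x = RNG.normal(size=(8, 8)).astype(np.float32)
        pooled, idx = max_pool_with_indices(x)
        with pytest.raises(ShapeError):
            max_unpool(pooled, idx, out_size=(2, 2))


class TestPyramid:
    def test_block_means_match_exhaustive(self):
        """Pre-projection branch content: adaptive pooling of a 6x6 map equals
        block means computed by exhaustive summation."""
        x = RNG.normal(size=(1, 1, 6, 6)).astype(np.float32)
        for b in (1, 2, 3, 6):
            got = nn.adaptive_avg_pool2d(x, b)[0, 0]
            step = 6 // b
            for i in range(b):
                for j in range(b):
                    block = x[0, 0, i * step:(i + 1) * step, j * step:(j + 1) * step]
                    assert got[i, j] == pytest.approx(block.sum() / step ** 2, rel=1e-5)

    def test_global_branch_is_mean(self):
        x = RNG.normal(size=(2, 3, 8, 8)).astype(np.float32)
        got = nn.adaptive_avg_pool2d(x, 1)
        assert np.allclose(got[..., 0, 0], x.mean(axis=(2, 3)), atol=1e-6)

    def test_spatial_size_preserved(self):
        x = RNG.normal(size=(1, 8, 12, 12)).astype(np.float32)
        out = pyramid_pool(x, [1, 2, 3, 6], seed=0)
        assert out.shape == x.shape

    def test_bin_larger_than_map_rejected(self):
        x = RNG.normal(size=(1, 4, 4, 4)).astype(np.float32)
        with pytest.raises(ConfigurationError):
            pyramid_pool(x, [6])

    def test_channel_count_increases_before_fusion(self):
        cfg = NetworkConfig(encoder_widths=(8,), pyramid_bins=(1, 2))
        model = SegNet(cfg, seed=0)
        x = RNG.normal(size=(1, 8, 8, 8)).astype(np.float32)
        branches = [x]
        for pool, proj in zip(model.pyramid.pools, model.pyramid.projs):
            branches.append(proj.forward(pool.forward(x)))
        assert sum(b.shape[1] for b in branches) > x.shape[1]


class TestForward:
    def test_output_shape(self):
        cfg = NetworkConfig(encoder_widths=(4, 8), pyramid_bins=(1, 2), n_classes=5)
        model = SegNet(cfg, seed=0)
        out = model.forward(RNG.uniform(size=(16, 16)))
        assert out.shape == (5, 16, 16)
        out = model.forward(RNG.uniform(size=(3, 16, 16)))
        assert out.shape == (3, 5, 16, 16)

    def test_indivisible_size_names_required_multiple(self):
        model = SegNet(NetworkConfig(encoder_widths=(4, 8, 8), pyramid_bins=()), seed=0)
        with pytest.raises(ShapeError, match="divisible by 8"):
            model.forward(RNG.uniform(size=(20, 20)))

    def test_ablation_has_fewer_parameters(self):
        base = dict(encoder_widths=(4, 8), n_classes=3)
        plain = SegNet(NetworkConfig(pyramid_bins=(), **base), seed=0)
        pyr = SegNet(NetworkConfig(pyramid_bins=(1, 2, 3, 6), **base), seed=0)
        assert plain.n_parameters() < pyr.n_parameters()
        assert plain.pyramid is None

    def test_eval_forward_is_pure(self):
        model = SegNet(NetworkConfig(encoder_widths=(4, 8), pyramid_bins=(1, 2)), seed=0)
        model.eval()
        x = RNG.uniform(size=(2, 16, 16))
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_decoder_restores_input_size_at_every_depth(self):
        for widths in [(4,), (4, 8), (4, 8, 8)]:
            model = SegNet(NetworkConfig(encoder_widths=widths, pyramid_bins=()), seed=0)
            out = model.forward(RNG.uniform(size=(32, 32)))
            assert out.shape[-2:] == (32, 32)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = SegNet(NetworkConfig(encoder_widths=(4, 8), pyramid_bins=(1, 2)), seed=3)
        model.eval()
        x = RNG.uniform(size=(16, 16))
        ref = model.forward(x)
        model.save(tmp_path / "ckpt.npz")
        loaded = SegNet.load(tmp_path / "ckpt.npz")
        loaded.eval()
        assert np.array_equal(loaded.forward(x), ref)
        assert loaded.config == model.config


class TestGradients:
    def test_every_parameter_receives_gradient(self):
        cfg = NetworkConfig(encoder_widths=(4, 8), pyramid_bins=(1, 2), n_classes=3)
        model = SegNet(cfg, seed=0)
        x = RNG.uniform(size=(2, 1, 16, 16)).astype(np.float32)
        y = RNG.integers(0, 3, size=(2, 16, 16))
        logits = model.forward(x)
        _, grad = nn.softmax_cross_entropy(logits, y)
        model.backward(grad)
        for i, p in enumerate(model.parameters()):
            assert np.any(p.grad != 0), f"parameter {i} got no gradient"

    def test_conv_numeric_gradient(self):
        """Central-difference check of the convolution backward pass."""
        rng = np.random.default_rng(0)
        layer = nn.Conv2d(2, 3, 3, rng)
        x = rng.normal(size=(1, 2, 5, 5)).astype(np.float64).astype(np.float32)
        out = layer.forward(x)
        up = rng.normal(size=out.shape).astype(np.float32)
        gx = layer.backward((out * 0 + up))
        eps = 1e-2
        for flat_idx in [0, 17, 33]:
            xp = x.copy(); xp.flat[flat_idx] += eps
            xm = x.copy(); xm.flat[flat_idx] -= eps
            num = ((layer.forward(xp) * up).sum() - (layer.forward(xm) * up).sum()) / (2 * eps)
            assert gx.flat[flat_idx] == pytest.approx(num, rel=5e-2, abs=1e-3)

    def test_batchnorm_numeric_gradient(self):
        rng = np.random.default_rng(0)
        layer = nn.BatchNorm2d(2)
        x = rng.normal(size=(2, 2, 3, 3)).astype(np.float32)
        out = layer.forward(x)
        up = rng.normal(size=out.shape).astype(np.float32)
        gx = layer.backward(up)
        eps = 1e-2
        for flat_idx in [0, 9, 20]:
            xp = x.copy(); xp.flat[flat_idx] += eps
            xm = x.copy(); xm.flat[flat_idx] -= eps
            num = ((layer.forward(xp) * up).sum() - (layer.forward(xm) * up).sum()) / (2 * eps)
            assert gx.flat[flat_idx] == pytest.approx(num, rel=5e-2, abs=2e-3)
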