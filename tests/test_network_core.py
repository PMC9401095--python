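"""Unit tests for the encoder/attention/pyramid blocks and the assembled
model."""

import numpy as np
import pytest

from ratcapsnet.config import ConfigError, NetworkConfig
from ratcapsnet.network import (
    ConvBlock,
    PFEBlock,
    RatCapsNet,
    VAMBlock,
    assemble_ratcapsnet,
    channel_rule,
    conv_block,
    count_parameters,
    decision_forward,
    encoder_forward,
    extract_attention_maps,
    global_average_pool,
    pfe_forward,
    vam_forward,
)
from ratcapsnet.nn import Dense
from ratcapsnet.nn.losses import softmax_cross_entropy
from ratcapsnet.types import FeatureMap, FeatureVector


class TestChannelRule:
    def test_rgb_maps_to_base_width(self):
        assert channel_rule(3, base_width_n=32) == 32

    def test_doubling_branch(self):
        assert channel_rule(32) == 64
        assert channel_rule(256) == 512

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            channel_rule(0)


class TestConvBlock:
    def test_same_padding_preserves_dims(self, rng):
        out = conv_block(FeatureMap(rng.random((8, 8, 3))), 32, 3, 1)
        assert out.shape == (8, 8, 32)

    def test_stride_halves_even_dims(self, rng):
        out = conv_block(FeatureMap(rng.random((8, 8, 32))), 16, 3, 2)
        assert out.shape == (4, 4, 16)

    def test_zero_weights_give_zero_output(self, rng):
        block = ConvBlock(3, 4, 3, 1)
        block.params["W"][...] = 0.0
        block.params["b"][...] = 0.0
        out = conv_block(FeatureMap(rng.random((8, 8, 3))), 4, 3, block=block)
        assert np.allclose(out.values, 0.0)


class TestVAM:
    def test_mask_shape_and_range(self, rng):
        x_r = FeatureMap(rng.standard_normal((32, 32, 64)))
        f, mask = vam_forward(x_r, seed=3)
        assert mask.shape == (32, 32, 1)
        assert f.shape == (32, 32, 64)
        assert mask.values.min() >= 0.0 and mask.values.max() <= 1.0

    def test_strongly_negative_bias_makes_identity(self, rng):
        x_r = FeatureMap(rng.standard_normal((8, 8, 4)))
        block = VAMBlock(4, rng=np.random.default_rng(0))
        block.up.params["W"][...] = 0.0
        block.up.params["b"][...] = -200.0
        f, mask = vam_forward(x_r, block=block)
        assert np.abs(mask.values).max() < 1e-6
        assert np.allclose(f.values, x_r.values, atol=1e-5)

    def test_enhancement_identity(self, rng):
        # f = x_r * (1 + mask) entrywise, for arbitrary seeded weights
        for seed in range(5):
            x_r = FeatureMap(np.random.default_rng(seed).standard_normal((8, 8, 4)))
            f, mask = vam_forward(x_r, seed=seed + 100)
            expected = x_r.values * (1.0 + mask.values)
            assert np.abs(f.values - expected).max() < 1e-6

    def test_rejects_odd_dims(self, rng):
        with pytest.raises(ValueError, match="even"):
            vam_forward(FeatureMap(rng.random((7, 8, 4))))

    def test_rejects_odd_channels(self, rng):
        with pytest.raises(ValueError, match="channel"):
            vam_forward(FeatureMap(rng.random((8, 8, 3))))


class TestEncoder:
    def test_stage1_shapes(self, rng):
        x = FeatureMap(rng.random((64, 64, 3)))
        y, x_r, mask = encoder_forward(x, base_width_n=32)
        assert x_r.shape == (64, 64, 32)
        assert y.shape == (32, 32, 32)
        assert mask.shape == (64, 64, 1)

    def test_stage5_shapes(self, rng):
        x = FeatureMap(rng.random((16, 16, 256)))
        y, x_r, mask = encoder_forward(x, base_width_n=32)
        assert x_r.shape == (16, 16, 512)
        assert y.shape == (8, 8, 512)

    def test_rejects_indivisible_dims(self, rng):
        with pytest.raises(ValueError):
            encoder_forward(FeatureMap(rng.random((17, 17, 3))))


class TestPFE:
    def test_output_channels_and_dims(self, rng):
        p = pfe_forward(FeatureMap(rng.random((16, 16, 64))), pfe_width_rho=16)
        assert p.shape == (16, 16, 32)

    def test_pair_concatenations_have_2rho_channels(self, rng):
        block = PFEBlock(8, rho=4, rng=np.random.default_rng(0))
        x = rng.random((1, 8, 8, 8)).astype(np.float32)
        r = [b.forward(x) for b in block.branches]
        for j in range(3):
            pair = np.concatenate([r[j], r[j + 1]], axis=1)
            assert pair.shape[1] == 2 * 4

    def test_branch_kernels_are_1357(self):
        block = PFEBlock(8, rho=4)
        assert [b.conv.k for b in block.branches] == [1, 3, 5, 7]
        assert [f.conv.k for f in block.fusions] == [8, 9, 10]
        assert block.final.conv.k == 11

    def test_zero_weights_propagate_zero(self, rng):
        block = PFEBlock(4, rho=2, rng=np.random.default_rng(0))
        for key in block.params:
            block.params[key][...] = 0.0
        p = pfe_forward(FeatureMap(rng.random((8, 8, 4))), block=block)
        assert np.allclose(p.values, 0.0)


class TestGlobalAveragePool:
    def test_vector_length_is_channel_count(self, rng):
        vec = global_average_pool(FeatureMap(rng.random((8, 8, 512))))
        assert len(vec) == 512

    def test_constant_map(self):
        vec = global_average_pool(FeatureMap(np.full((4, 4, 3), 2.5)))
        assert np.allclose(vec.values, 2.5)

    def test_small_example(self):
        vec = global_average_pool(
            FeatureMap(np.array([[1.0, 2.0], [3.0, 4.0]])[..., None]))
        assert np.isclose(vec.values[0], 2.5)

    def test_matches_brute_force_loops(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal((5, 7, 3))
            vec = global_average_pool(FeatureMap(x))
            for c in range(3):
                total = 0.0
                for i in range(5):
                    for j in range(7):
                        total += x[i, j, c]
                assert np.isclose(vec.values[c], total / 35.0)


class TestDecision:
    def test_default_concat_length(self):
        # 16C + |pfe_stages| * 2 rho = 512 + 4*32 = 640
        cfg = NetworkConfig(num_classes=3)
        assert cfg.head_input_size == 640

    def test_softmax_sums_to_one(self, rng):
        cfg = NetworkConfig(base_width_n=4, pfe_width_rho=2, num_stages=2,
                            pfe_stages=(2,), dense_sizes=(8, 6), num_classes=3,
                            input_hw=(8, 8))
        y5 = FeatureVector(rng.standard_normal(cfg.stage_channels(2)))
        p = [FeatureVector(rng.standard_normal(4))]
        probs = decision_forward(y5, p, config=cfg)
        assert len(probs) == 3
        assert abs(probs.values.sum() - 1.0) < 1e-6

    def test_sigmoid_binary_single_unit(self, rng):
        cfg = NetworkConfig(base_width_n=4, pfe_width_rho=2, num_stages=2,
                            pfe_stages=(2,), dense_sizes=(8, 6), num_classes=2,
                            input_hw=(8, 8), head_mode="sigmoid_binary")
        y5 = FeatureVector(rng.standard_normal(8))
        p = [FeatureVector(rng.standard_normal(4))]
        probs = decision_forward(y5, p, config=cfg)
        assert len(probs) == 1
        assert 0.0 <= probs.values[0] <= 1.0

    def test_length_mismatch_raises(self, rng):
        cfg = NetworkConfig(num_classes=3)
        with pytest.raises(ValueError, match="features"):
            decision_forward(FeatureVector(rng.standard_normal(100)), [],
                             config=cfg)


class TestAssembledModel:
    def test_forward_contract(self, tiny_config, rng):
        model = assemble_ratcapsnet(tiny_config)
        probs = model.predict_proba(rng.random((1, 3, 8, 8)).astype(np.float32))
        assert probs.shape == (1, 3)
        assert np.isclose(probs.sum(), 1.0, atol=1e-6)

    def test_invalid_config_names_invariant(self):
        with pytest.raises(ConfigError, match="divisible"):
            NetworkConfig(input_hw=(100, 100))
        with pytest.raises(ConfigError, match="pfe_stages"):
            NetworkConfig(pfe_stages=(1, 2))

    def test_parameter_count_input_size_invariant(self):
        kw = dict(base_width_n=8, pfe_width_rho=4, num_stages=5,
                  dense_sizes=(64, 32), num_classes=2)
        small = assemble_ratcapsnet(NetworkConfig(input_hw=(64, 64), **kw))
        large = assemble_ratcapsnet(NetworkConfig(input_hw=(256, 256), **kw))
        assert count_parameters(small) == count_parameters(large)

    def test_single_dense_param_count(self):
        assert Dense(640, 512).n_params() == 640 * 512 + 512

    def test_single_conv_param_count(self, rng):
        from ratcapsnet.nn import Conv2d
        assert Conv2d(3, 32, 3).n_params() == 3 * 3 * 3 * 32 + 32

    def test_gradients_nonzero_everywhere(self, tiny_config, rng):
        model = assemble_ratcapsnet(tiny_config)
        x = rng.random((4, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 2, 0])
        model.zero_grad()
        _, dlogits = softmax_cross_entropy(model.forward(x), y)
        model.backward(dlogits)
        for name, mod in model.modules().items():
            for key, g in mod.grads.items():
                assert np.any(g != 0.0), f"zero gradient in {name}.{key}"

    def test_zero_weight_network_uniform_softmax(self, tiny_config, rng):
        model = assemble_ratcapsnet(tiny_config)
        state = {k: np.zeros_like(v) for k, v in model.state_dict().items()}
        model.load_state_dict(state)
        probs = model.predict_proba(rng.random((2, 3, 8, 8)).astype(np.float32))
        assert np.allclose(probs, 1.0 / 3.0, atol=1e-7)

    def test_checkpoint_roundtrip(self, tiny_config, rng, tmp_path):
        model = assemble_ratcapsnet(tiny_config)
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        before = model.forward(x)
        np.savez(tmp_path / "m.npz", **model.state_dict())
        clone = assemble_ratcapsnet(tiny_config)
        with np.load(tmp_path / "m.npz") as data:
            clone.load_state_dict({k: data[k] for k in data.files})
        assert np.allclose(clone.forward(x), before)


class TestExtractAttentionMaps:
    def test_mask_resolutions_and_range(self, rng):
        cfg = NetworkConfig(base_width_n=4, pfe_width_rho=2, num_stages=3,
                            pfe_stages=(2, 3), dense_sizes=(8, 6),
                            num_classes=2, input_hw=(32, 32))
        model = assemble_ratcapsnet(cfg)
        img = rng.random((32, 32, 3))
        masks, pfe_maps = extract_attention_maps(model, img)
        assert [m.shape[:2] for _, m in masks] == [(32, 32), (16, 16), (8, 8)]
        for _, m in masks:
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0
        assert [l for l, _ in pfe_maps] == [2, 3]
        for _, p in pfe_maps:
            assert p.shape[2] == 2 * cfg.pfe_width_rho

    def test_shape_mismatch_raises(self, tiny_config, rng):
        model = assemble_ratcapsnet(tiny_config)
        with pytest.raises(ValueError, match="dims"):
            extract_attention_maps(model, rng.random((16, 16, 3)))


class TestShapeContractChain:
    def test_tap_and_pool_resolutions(self, rng):
        """Stage l tap at (H/2^{l-1}, W/2^{l-1}); pooled at (H/2^l, W/2^l);
        channels 4, 8, 16 for n=4."""
        cfg = NetworkConfig(base_width_n=4, pfe_width_rho=2, num_stages=3,
                            pfe_stages=(2, 3), dense_sizes=(8, 6),
                            num_classes=2, input_hw=(32, 32))
        model = assemble_ratcapsnet(cfg)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        _, taps, masks, _ = model.forward_full(x)
        for l in (1, 2, 3):
            assert taps[l].shape[2:] == (32 >> (l - 1), 32 >> (l - 1))
            assert taps[l].shape[1] == 4 * 2 ** (l - 1)
            assert masks[l].shape[1] == 1

    def test_mask_range_on_many_seeded_inputs(self):
        cfg = NetworkConfig(base_width_n=4, pfe_width_rho=2, num_stages=2,
                            pfe_stages=(2,), dense_sizes=(8, 6),
                            num_classes=2, input_hw=(8, 8), seed=5)
        model = assemble_ratcapsnet(cfg)
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal((1, 3, 8, 8))
            _, _, masks, _ = model.forward_full(x.astype(np.float32))
            for m in masks.values():
                assert m.min() >= 0.0 and m.max() <= 1.0
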