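"""ES-UNet architecture contracts: shapes, routing, attention, supervision."""

import numpy as np
import pytest

from esunet.losses import total_loss_grad
from esunet.network import (
    ESUNet,
    NetworkConfig,
    VARIANTS,
    build_network,
    encoder_forward,
    fuse_predictions,
)
from esunet.nn.layers import ChannelAttention


def toy_cfg(**kw):
    base = dict(n_levels=4, in_channels=2, base_channels=4, path_channels=4, seed=1)
    base.update(kw)
    return NetworkConfig(**base)


@pytest.fixture(scope="module")
def toy_net():
    return build_network(toy_cfg())


@pytest.fixture(scope="module")
def toy_input():
    return np.random.default_rng(0).standard_normal((2, 16, 16, 16)).astype(np.float32)


class TestEncoder:
    def test_toy_schedule(self):
        feats = encoder_forward(np.zeros((1, 16, 16, 16), np.float32),
                                toy_cfg(in_channels=1))
        assert [f.shape for f in feats] == [
            (4, 16, 16, 16), (8, 8, 8, 8), (16, 4, 4, 4), (32, 2, 2, 2)]

    def test_channels_double_and_dims_halve_per_level(self):
        for base in (2, 4, 6):
            cfg = toy_cfg(base_channels=base, path_channels=base)
            feats = encoder_forward(np.zeros((2, 16, 16, 16), np.float32), cfg)
            for i in range(1, len(feats)):
                assert feats[i].shape[0] == 2 * feats[i - 1].shape[0]
                assert all(
                    a == 2 * b for a, b in zip(feats[i - 1].shape[1:], feats[i].shape[1:])
                )

    def test_indivisible_input_names_divisor(self):
        net = build_network(toy_cfg())
        with pytest.raises(ValueError, match="divisible by 8"):
            net.forward(np.zeros((2, 50, 50, 50), np.float32))


class TestChannelAttention:
    def test_bottleneck_width_from_ratio(self):
        rng = np.random.default_rng(0)
        att = ChannelAttention(32, 0.25, rng)
        assert att.hidden == 8
        x = rng.standard_normal((32, 4, 4, 4)).astype(np.float32)
        assert att.forward(x).shape == x.shape

    def test_saturated_gate_is_identity(self, rng):
        att = ChannelAttention(4, 0.5, rng)
        att.b2.value[...] = 50.0  # sigmoid saturates at 1
        x = rng.standard_normal((4, 4, 4, 4)).astype(np.float32)
        assert np.allclose(att.forward(x), x, atol=1e-5)

    def test_closed_gate_zeroes_output(self, rng):
        att = ChannelAttention(4, 0.5, rng)
        att.b2.value[...] = -50.0
        x = rng.standard_normal((4, 4, 4, 4)).astype(np.float32)
        assert np.allclose(att.forward(x), 0.0, atol=1e-5)


class TestSkipRouting:
    """Shape arithmetic of the four path cases, via the built network."""

    def test_path_shapes_in_full_variant(self, toy_net, toy_input):
        toy_net.set_training(False)
        toy_net.forward(toy_input)
        # enc level 1 (4ch @16) -> dec 3 must arrive at (C=4, 4^3)
        sizes = {}
        for j, paths in toy_net.paths.items():
            for p in paths:
                out = None
                sizes[(p.source, p.src_level, j)] = p
        assert sizes[("encoder", 1, 3)].body.modules[1].s == 4  # pool 2^(3-1)
        assert sizes[("decoder", 4, 2)].body.modules[0].factor == 4  # trilinear 2^(4-2)

    def test_encoder_paths_carry_attention_decoder_paths_do_not(self, toy_net):
        for j, paths in toy_net.paths.items():
            for p in paths:
                has_att = any(isinstance(m, ChannelAttention) for m in p.body.modules)
                assert has_att == (p.source == "encoder")

    def test_invalid_routing_rejected(self):
        from esunet.network import _SkipPath
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            _SkipPath(3, 2, "encoder", 8, toy_cfg(), rng)
        with pytest.raises(ValueError):
            _SkipPath(2, 2, "decoder", 8, toy_cfg(), rng)


class TestDecoder:
    def test_full_variant_every_decoder_gets_n_paths(self, toy_net):
        n = toy_net.cfg.n_levels
        for j in range(1, n + 1):
            assert len(toy_net.paths[j]) == n
            assert toy_net.decoders[j].out_channels == n * toy_net.cfg.path_channels

    def test_deepest_decoder_receives_only_encoder_paths(self, toy_net):
        assert all(p.source == "encoder" for p in toy_net.paths[4])

    def test_base_variant_path_bookkeeping(self):
        net = build_network(toy_cfg(variant="base"))
        n, c = net.cfg.n_levels, net.cfg.path_channels
        for j in range(1, n):
            srcs = [(p.source, p.src_level) for p in net.paths[j]]
            assert srcs == [("encoder", j), ("decoder", j + 1)]
            assert net.decoders[j].out_channels == 2 * c
        assert [(p.source, p.src_level) for p in net.paths[n]] == [("encoder", n)]

    def test_enc_only_and_dec_only_topologies(self):
        enc = build_network(toy_cfg(variant="enc_only"))
        assert [(p.source, p.src_level) for p in enc.paths[3]] == [
            ("encoder", 1), ("encoder", 2), ("encoder", 3), ("decoder", 4)]
        dec = build_network(toy_cfg(variant="dec_only"))
        assert [(p.source, p.src_level) for p in dec.paths[1]] == [
            ("encoder", 1), ("decoder", 2), ("decoder", 3), ("decoder", 4)]


class TestAuxHeadsAndFusion:
    def test_head_upsampling_factor_and_range(self, toy_net, toy_input):
        toy_net.set_training(False)
        fused, heads = toy_net.forward(toy_input)
        assert set(heads) == {1, 2, 3, 4}
        for j, h in heads.items():
            assert h.shape == toy_input.shape[1:]
            assert h.min() >= 0.0 and h.max() <= 1.0
        assert toy_net.heads[3].body.modules[1].factor == 4  # 2^(3-1)

    def test_zeroed_head_outputs_half_everywhere(self, toy_input):
        net = build_network(toy_cfg())
        head = net.heads[1]
        conv = head.body.modules[0]
        conv.weight.value[...] = 0.0
        conv.bias.value[...] = 0.0
        net.set_training(False)
        _, heads = net.forward(toy_input)
        assert np.allclose(heads[1], 0.5)

    def test_fuse_is_arithmetic_mean(self):
        maps = [np.full((4, 4, 4), v) for v in (0.2, 0.4, 0.6, 0.8)]
        assert np.allclose(fuse_predictions(maps), 0.5)
        assert np.allclose(fuse_predictions([maps[0]] * 4), maps[0])
        assert np.array_equal(fuse_predictions([maps[2]]), maps[2])

    def test_fuse_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_predictions([np.zeros((4, 4, 4)), np.zeros((2, 2, 2))])

    def test_deep_supervision_off_single_head(self, toy_input):
        net = build_network(toy_cfg(deep_supervision=False))
        net.set_training(False)
        fused, heads = net.forward(toy_input)
        assert list(heads) == [1]
        assert np.array_equal(fused, heads[1])


class TestBuildNetwork:
    def test_forward_contract(self, toy_net, toy_input):
        toy_net.set_training(False)
        fused, _ = toy_net.forward(toy_input)
        assert fused.shape == toy_input.shape[1:]
        assert fused.min() >= 0.0 and fused.max() <= 1.0

    def test_full_variant_has_more_parameters_than_base(self):
        counts = {v: build_network(toy_cfg(variant=v)).n_parameters() for v in VARIANTS}
        assert counts["both"] > counts["base"]
        assert counts["enc_only"] > counts["base"]
        assert counts["dec_only"] > counts["base"]

    def test_invalid_variant_lists_options(self):
        with pytest.raises(ValueError, match="base"):
            NetworkConfig(variant="full")

    def test_gradient_reaches_every_parameter_group(self, toy_input):
        net = build_network(toy_cfg())
        net.set_training(True)
        fused, heads = net.forward(toy_input)
        y = (np.random.default_rng(1).uniform(size=fused.shape) < 0.05).astype(float)
        net.zero_grad()
        net.backward({j: total_loss_grad(y, heads[j]) / len(heads) for j in heads})
        for p in net.params():
            assert np.abs(p.grad).max() > 0, p.name

    def test_predict_mask_is_binary_and_thresholded(self, toy_net, toy_input):
        mask = toy_net.predict_mask(toy_input)
        proba = toy_net.predict_proba(toy_input)
        assert set(np.unique(mask)) <= {0, 1}
        assert np.array_equal(mask, (proba >= toy_net.cfg.threshold).astype(np.int8))
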