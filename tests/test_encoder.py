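"""Encoder customizations: patch-embed expansion, adapter, fusion, injection."""

import numpy as np
import pytest

from gliotask import nn
from gliotask.encoder import (DGCB, Encoder, EncoderConfig, MVAdapter,
                              PatchEmbed, expand_patch_embed, inject_qkv,
                              load_checkpoint, load_pretrained,
                              save_checkpoint)
from gliotask.nn import Tensor

rng = np.random.default_rng(0)

TEST_CFG = EncoderConfig(in_channels=5, input_size=32, patch_size=4,
                         embed_dim=48, n_blocks=2, n_heads=6)
TINY_CFG = EncoderConfig(in_channels=5, input_size=16, patch_size=4,
                         embed_dim=16, n_blocks=1, n_heads=2)


class TestExpandPatchEmbed:
    def test_shape_expansion(self):
        base = np.random.default_rng(1).standard_normal(
            (384, 1, 16, 16, 16)).astype(np.float32)
        out = expand_patch_embed(base, 5)
        assert out.shape == (384, 5, 16, 16, 16)

    def test_identical_channels_reproduce_single_channel_response(self):
        cfg = EncoderConfig(in_channels=1, input_size=8, patch_size=2,
                            embed_dim=8, n_blocks=1, n_heads=2)
        pe1 = PatchEmbed(cfg, np.random.default_rng(2))
        x1 = np.random.default_rng(3).standard_normal(
            (2, 1, 8, 8, 8)).astype(np.float32)
        ref = pe1(Tensor(x1)).data

        cfg5 = EncoderConfig(in_channels=5, input_size=8, patch_size=2,
                             embed_dim=8, n_blocks=1, n_heads=2)
        pe5 = PatchEmbed(cfg5, np.random.default_rng(4))
        pe5.weight.data = expand_patch_embed(pe1.weight.data, 5)
        pe5.bias.data = pe1.bias.data.copy()
        x5 = np.repeat(x1, 5, axis=1)
        np.testing.assert_allclose(pe5(Tensor(x5)).data, ref, atol=1e-5)

    def test_zero_input_bias_only_before_and_after(self):
        cfg = EncoderConfig(in_channels=1, input_size=8, patch_size=2,
                            embed_dim=8, n_blocks=1, n_heads=2)
        pe = PatchEmbed(cfg, np.random.default_rng(5))
        pe.bias.data[:] = np.arange(8, dtype=np.float32)
        before = pe(Tensor(np.zeros((1, 1, 8, 8, 8)))).data
        pe.weight.data = expand_patch_embed(pe.weight.data, 5)
        cfg5 = EncoderConfig(in_channels=5, input_size=8, patch_size=2,
                             embed_dim=8, n_blocks=1, n_heads=2)
        pe5 = PatchEmbed(cfg5, np.random.default_rng(6))
        pe5.weight.data, pe5.bias.data = pe.weight.data, pe.bias.data
        after = pe5(Tensor(np.zeros((1, 5, 8, 8, 8)))).data
        np.testing.assert_allclose(before, after, atol=1e-6)

    def test_multichannel_base_rejected(self):
        with pytest.raises(ValueError, match="single-input-channel"):
            expand_patch_embed(np.zeros((8, 3, 2, 2, 2)))


class TestPatchEmbed:
    def test_token_grid_shape_test_scale(self):
        pe = PatchEmbed(TEST_CFG, rng)
        x = Tensor(np.random.default_rng(7).standard_normal((2, 5, 32, 32, 32)))
        tokens = pe(x)
        assert tokens.shape == (2, 8 ** 3, 48)
        assert TEST_CFG.n_tokens == 512

    def test_indivisible_dims_rejected(self):
        pe = PatchEmbed(TEST_CFG, rng)
        with pytest.raises(ValueError, match="divisible"):
            pe(Tensor(np.zeros((1, 5, 30, 30, 30))))


class TestConfigValidation:
    def test_reference_scale_contracts(self):
        cfg = EncoderConfig()  # reference defaults
        assert (cfg.input_size, cfg.patch_size, cfg.embed_dim) == (128, 16, 384)
        assert cfg.grid == 8 and cfg.n_tokens == 512
        assert cfg.adapter_hidden == 48
        assert cfg.resolved_qkv_dim == 3 * 384 == 1152

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            EncoderConfig(input_size=100, patch_size=16)
        with pytest.raises(ValueError, match="n_heads"):
            EncoderConfig(embed_dim=384, n_heads=5)


class TestMVAdapter:
    def test_bottleneck_widths_at_reference_scale(self):
        cfg = EncoderConfig()
        adapter = MVAdapter(cfg, rng)
        assert adapter.fc_img.weight.shape == (48, 384)
        assert adapter.fc_tab.weight.shape == (48, 101)
        assert adapter.fc_tokens.weight.shape == (384, 384)
        assert adapter.bilinear.weight.shape == (384, 48, 48)

    def test_gate_in_unit_interval_and_shape_preserved(self):
        adapter = MVAdapter(TEST_CFG, rng)
        tokens = Tensor(np.random.default_rng(8).standard_normal((3, 512, 48)))
        tab = Tensor(np.random.default_rng(9).standard_normal((3, 101)))
        g = adapter.gate(tokens, tab).data
        assert g.shape == (3, 48)
        assert np.all(g > 0) and np.all(g < 1)
        assert adapter(tokens, tab).shape == tokens.shape

    def test_wrong_tabular_width_rejected(self):
        adapter = MVAdapter(TEST_CFG, rng)
        with pytest.raises(ValueError, match="tabular width"):
            adapter.gate(Tensor(np.zeros((1, 512, 48))),
                         Tensor(np.zeros((1, 77))))

    def test_gate_monotone_in_bilinear_logit(self):
        # bumping one bilinear bias logit increases that channel's gate and
        # therefore the gated channel magnitude, for fixed inputs
        adapter = MVAdapter(TINY_CFG, np.random.default_rng(10))
        adapter.eval()
        tokens = Tensor(np.random.default_rng(11).standard_normal((1, 64, 16)))
        tab = Tensor(np.random.default_rng(12).standard_normal((1, 101)))
        base = np.abs(adapter(tokens, tab).data[0, :, 3]).mean()
        adapter.bilinear.bias.data[3] += 2.0
        bumped = np.abs(adapter(tokens, tab).data[0, :, 3]).mean()
        assert bumped > base


class TestDGCB:
    def test_output_channels_test_scale(self):
        dgcb = DGCB(TEST_CFG, rng)
        tokens = Tensor(np.random.default_rng(13).standard_normal((1, 512, 48)))
        out = dgcb(tokens)
        assert out.shape == (1, 512, 144)  # 3 * 48

    def test_zero_input_gives_token_constant_output(self):
        dgcb = DGCB(TINY_CFG, rng)
        dgcb.eval()
        out = dgcb(Tensor(np.zeros((1, 64, 16)))).data
        np.testing.assert_allclose(
            out, np.broadcast_to(out[:, :1, :], out.shape), atol=1e-6)

    def test_group_divisibility_enforced(self):
        with pytest.raises(ValueError):
            # embed_dim 20 -> group count 2 ok, but 20/8 not integer
            EncoderConfig(input_size=16, patch_size=4, embed_dim=20, n_heads=2)


class TestInjectQKV:
    def test_addition_and_identity(self):
        qkv = Tensor(np.random.default_rng(14).standard_normal((1, 64, 48)))
        zero = Tensor(np.zeros((1, 64, 48)))
        np.testing.assert_array_equal(inject_qkv(zero, qkv).data, qkv.data)
        fusion = Tensor(np.random.default_rng(15).standard_normal((1, 64, 48)))
        out = inject_qkv(fusion, qkv)
        np.testing.assert_allclose(out.data - qkv.data, fusion.data, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            inject_qkv(Tensor(np.zeros((1, 64, 48))),
                       Tensor(np.zeros((1, 64, 40))))


class TestEncoder:
    def test_feature_vector_width_and_determinism(self):
        enc = Encoder(TINY_CFG, rng=np.random.default_rng(16))
        enc.eval()
        x = Tensor(np.random.default_rng(17).standard_normal((2, 5, 16, 16, 16)))
        tab = Tensor(np.random.default_rng(18).standard_normal((2, 101)))
        f1, f2 = enc(x, tab).data, enc(x, tab).data
        assert f1.shape == (2, 16)
        np.testing.assert_array_equal(f1, f2)

    def test_zero_adapter_equivalence(self):
        enc = Encoder(TINY_CFG, rng=np.random.default_rng(19))
        enc.eval()
        x = Tensor(np.random.default_rng(20).standard_normal((1, 5, 16, 16, 16)))
        tab = Tensor(np.random.default_rng(21).standard_normal((1, 101)))
        plain = enc(x, tab, use_adapters=False).data
        enc.zero_adapters()
        adapted = enc(x, tab, use_adapters=True).data
        np.testing.assert_allclose(adapted, plain, atol=1e-5)

    def test_freeze_backbone_keeps_backbone_bit_identical(self):
        enc = Encoder(TINY_CFG, rng=np.random.default_rng(22))
        frozen_before = {
            name: p.data.copy() for name, p in enc.named_parameters()
            if not p.requires_grad}
        assert frozen_before  # freezing is on by default
        opt = nn.Adam(enc.parameters(), lr=1e-2)
        x = Tensor(np.random.default_rng(23).standard_normal((2, 5, 16, 16, 16)))
        tab = Tensor(np.random.default_rng(24).standard_normal((2, 101)))
        opt.zero_grad()
        (enc(x, tab) ** 2).sum().backward()
        opt.step()
        for name, p in enc.named_parameters():
            if name in frozen_before:
                np.testing.assert_array_equal(p.data, frozen_before[name])
        # something must have trained
        assert any(p.grad is not None and np.any(p.grad != 0)
                   for p in enc.parameters() if p.requires_grad)


class TestCheckpoints:
    def test_roundtrip(self, tmp_path):
        enc = Encoder(TINY_CFG, rng=np.random.default_rng(25))
        path = tmp_path / "enc.npz"
        save_checkpoint(enc, path, config={"embed_dim": 16})
        enc2 = Encoder(TINY_CFG, rng=np.random.default_rng(99))
        load_checkpoint(enc2, path)
        for (n1, p1), (n2, p2) in zip(enc.named_parameters(),
                                      enc2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_load_pretrained_expands_single_channel_patch_embed(self, tmp_path):
        cfg1 = EncoderConfig(in_channels=1, input_size=16, patch_size=4,
                             embed_dim=16, n_blocks=1, n_heads=2)
        base = Encoder(cfg1, rng=np.random.default_rng(26))
        path = tmp_path / "base.npz"
        save_checkpoint(base, path)
        model = load_pretrained(path, TINY_CFG)
        assert model.patch_embed.weight.shape == (16, 5, 4, 4, 4)
        out = model(Tensor(np.zeros((1, 5, 16, 16, 16))),
                    Tensor(np.zeros((1, 101))))
        assert out.shape == (1, 16)

    def test_load_pretrained_reports_offending_tensors(self, tmp_path):
        big = Encoder(EncoderConfig(in_channels=5, input_size=16, patch_size=4,
                                    embed_dim=32, n_blocks=1, n_heads=2),
                      rng=np.random.default_rng(27))
        path = tmp_path / "big.npz"
        save_checkpoint(big, path)
        with pytest.raises(ValueError, match="patch_embed.weight"):
            load_pretrained(path, TINY_CFG)
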