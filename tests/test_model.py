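"""Architecture contracts: shapes through the U, windowed attention vs dense
attention, shift masking, merge/expand inverses, gradient flow."""

import dataclasses

import numpy as np
import pytest
from autograd import grad
import autograd.numpy as anp

import strawseg as ss
from strawseg.model import (
    SwinUNet, relative_position_index, shift_attention_mask, swin_block,
    window_attention,
)
from strawseg.training import tree_leaves

from conftest import DESK_SIZE


def _x(shape, seed=0):
    return np.random.default_rng(seed).normal(size=shape).astype(np.float32)


class TestConfig:
    def test_encoder_resolutions_halve_from_patch_grid(self):
        cfg = ss.ModelConfig()  # 224, patch 4, 4 stages
        assert [cfg.stage_resolution(i)[0] for i in range(4)] == [56, 28, 14, 7]

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ss.ConfigurationError, match="230"):
            ss.ModelConfig(image_size=(230, 224)).validate()

    def test_parameter_count_grows_with_embed_dim(self):
        small = ss.build_model(ss.tiny_config(DESK_SIZE))[1]
        big_cfg = dataclasses.replace(ss.tiny_config(DESK_SIZE), embed_dim=48)
        big = ss.build_model(big_cfg)[1]
        assert ss.num_parameters(big) > ss.num_parameters(small)


class TestWindowAttention:
    def _params(self, dim, heads, win_area, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "qkv_w": rng.normal(0, 0.1, (dim, 3 * dim)).astype(np.float32),
            "qkv_b": rng.normal(0, 0.1, 3 * dim).astype(np.float32),
            "proj_w": rng.normal(0, 0.1, (dim, dim)).astype(np.float32),
            "proj_b": np.zeros(dim, np.float32),
            "rpb_table": rng.normal(0, 0.1, ((2 * win_area - 1) ** 2, heads)
                                    ).astype(np.float32),
        }

    def test_output_shape_equals_input_shape(self):
        x = _x((2, 8, 8, 12))
        p = self._params(12, 3, 4)
        out = window_attention(x, p, num_heads=3, window=4)
        assert out.shape == x.shape

    def test_single_window_equals_dense_attention(self):
        """With one window spanning the map and no bias, windowed attention
        must equal a reference dense softmax-attention computation."""
        dim, heads, side = 8, 2, 4
        x = _x((1, side, side, dim), seed=3)
        p = self._params(dim, heads, side)
        p["rpb_table"][:] = 0.0
        out = window_attention(x, p, num_heads=heads, window=side)

        tok = x.reshape(-1, dim)
        qkv = tok @ p["qkv_w"] + p["qkv_b"]
        q, k, v = np.split(qkv, 3, axis=-1)
        hd = dim // heads
        ref = np.zeros_like(tok)
        for h in range(heads):
            sl = slice(h * hd, (h + 1) * hd)
            a = q[:, sl] @ k[:, sl].T / np.sqrt(hd)
            a = np.exp(a - a.max(-1, keepdims=True))
            a /= a.sum(-1, keepdims=True)
            ref[:, sl] = a @ v[:, sl]
        ref = (ref @ p["proj_w"] + p["proj_b"]).reshape(x.shape)
        assert np.allclose(out, ref, atol=1e-5)

    def test_shift_mask_zeroes_wrapped_pairs(self):
        """On an 8x8 map with window 4 and shift 2, attention probability
        between tokens wrapped across the cyclic boundary is exactly 0."""
        dim, heads, win, shift = 8, 2, 4, 2
        x = _x((1, 8, 8, dim), seed=1)
        p = self._params(dim, heads, win, seed=2)
        mask = shift_attention_mask(8, 8, win, win, shift)
        _, attn = window_attention(x, p, num_heads=heads, window=win,
                                   shift=shift, mask=mask, return_attn=True)
        blocked = np.broadcast_to(mask[None, :, None] < 0,
                                  (1, mask.shape[0], heads) + mask.shape[1:])
        blocked = blocked.reshape(attn.shape)
        assert blocked.any()
        assert np.all(attn[blocked] == 0.0)
        # rows still sum to 1 over the permitted tokens
        assert np.allclose(attn.sum(-1), 1.0, atol=1e-5)

    def test_window_larger_than_map_falls_back_to_global(self):
        x = _x((1, 4, 4, 8))
        p = self._params(8, 2, 4)
        out = window_attention(x, p, num_heads=2, window=16)
        assert out.shape == x.shape


class TestMergeExpand:
    def _merge_params(self, c, rng):
        return {"ln_g": np.ones(4 * c, np.float32), "ln_b": np.zeros(4 * c, np.float32),
                "w": rng.normal(0, 0.1, (4 * c, 2 * c)).astype(np.float32)}

    def _expand_params(self, c, rng):
        return {"w": rng.normal(0, 0.1, (2 * c, 4 * c)).astype(np.float32),
                "b": np.zeros(4 * c, np.float32),
                "ln_g": np.ones(c, np.float32), "ln_b": np.zeros(c, np.float32)}

    def test_merge_halves_resolution_doubles_channels(self):
        rng = np.random.default_rng(0)
        out = ss.patch_merge(_x((1, 56, 56, 8)), self._merge_params(8, rng))
        assert out.shape == (1, 28, 28, 16)

    def test_odd_resolution_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ss.ConfigurationError):
            ss.patch_merge(_x((1, 7, 7, 8)), self._merge_params(8, rng))

    @pytest.mark.parametrize("h,w,c", [(4, 4, 4), (8, 6, 8), (2, 10, 6),
                                       (12, 12, 10), (6, 4, 12), (16, 2, 4),
                                       (2, 2, 8), (10, 8, 6), (4, 12, 4),
                                       (14, 6, 8)])
    def test_expand_inverts_merge_shape(self, h, w, c):
        rng = np.random.default_rng(c)
        x = _x((2, h, w, c), seed=h * w)
        merged = ss.patch_merge(x, self._merge_params(c, rng))
        restored = ss.patch_expand(merged, self._expand_params(c, rng))
        assert restored.shape == x.shape


class TestForward:
    @pytest.mark.parametrize("side", [64, 96, 128])
    def test_shape_contract_sweep(self, side):
        net, params = ss.build_model(ss.tiny_config((side, side)))
        logits = net.forward(params, _x((2, side, side, 3)))
        assert logits.shape == (2, side, side, 3)
        assert np.isfinite(logits).all()

    def test_identical_inputs_give_identical_logits(self, tiny_net):
        net, params = tiny_net
        one = _x((1,) + DESK_SIZE + (3,), seed=5)
        batch = np.concatenate([one, one])
        logits = net.forward(params, batch)
        assert np.array_equal(logits[0], logits[1])

    def test_input_size_must_match_config(self, tiny_net):
        net, params = tiny_net
        with pytest.raises(ss.ConfigurationError):
            net.forward(params, _x((1, 96, 96, 3)))

    def test_adaptation_features_shape_and_determinism(self, tiny_net):
        net, params = tiny_net
        cfg = net.config
        one = _x((1,) + DESK_SIZE + (3,), seed=6)
        feats = net.extract_adaptation_features(params, np.concatenate([one, one]))
        # pooled bottleneck width = embed_dim * 2^(stages-1)
        assert feats.shape == (2, cfg.embed_dim * 2 ** (cfg.num_stages - 1))
        assert np.array_equal(feats[0], feats[1])

    def test_nan_parameters_surface_numeric_error(self, tiny_net):
        net, params = tiny_net
        import copy

        broken = copy.deepcopy(params)
        broken["head"]["w"] = np.full_like(broken["head"]["w"], np.nan)
        with pytest.raises(ss.NumericError, match="head"):
            net.predict(broken, _x((1,) + DESK_SIZE + (3,)))

    def test_gradient_reaches_every_parameter(self, tiny_net):
        """No detached branches: the joint loss moves every leaf."""
        net, params = tiny_net
        x = _x((2,) + DESK_SIZE + (3,), seed=8)
        y = np.random.default_rng(0).integers(0, 3, (2,) + DESK_SIZE)
        tx = _x((2,) + DESK_SIZE + (3,), seed=9)
        w = ss.LossWeights(rbf_bandwidths=(1.0,))

        def objective(p):
            logits, sf = net.forward(p, x, with_features=True)
            tf = net.forward(p, tx, features_only=True)
            return ss.joint_loss(logits, y, sf, tf, w)[0]

        grads = grad(objective)(params)
        for path, leaf in tree_leaves(grads):
            assert np.isfinite(leaf).all(), path
            assert np.abs(leaf).max() > 0, path


class TestRelativePositionIndex:
    def test_index_bounds_and_symmetry_of_diagonal(self):
        idx = relative_position_index(4, 4)
        assert idx.shape == (16, 16)
        assert idx.min() >= 0 and idx.max() < 7 * 7
        # all self-pairs share the (0, 0) relative offset
        assert len(set(np.diag(idx))) == 1
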