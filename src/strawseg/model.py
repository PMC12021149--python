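"""SwinUNet: a U-shaped segmenter built from shifted-window attention blocks.

The network follows the familiar Swin-UNet layout: a 4x4 patch embedding, a
hierarchical encoder whose stages alternate windowed (W-MSA) and shifted-
window (SW-MSA) multi-head self-attention, patch-merging downsampling between
stages, a bottleneck, and a mirrored decoder with patch-expanding upsampling
and one skip connection per resolution, closed by a 4x final expansion and a
per-pixel 3-class head.

It is implemented as pure functions over a nested dict of numpy parameter
arrays, differentiated with HIPS ``autograd`` — so a forward pass is ordinary
(traceable) numpy and the whole training objective is differentiable
end-to-end on a CPU.  Desk-scale presets (64x64 input, 24-channel embedding)
train in minutes; the full-scale preset mirrors the common Swin-T layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .errors import ConfigurationError, NumericError

NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    image_size: tuple[int, int] = (224, 224)
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    num_classes: int = 3
    mlp_ratio: float = 4.0
    activation: str = "relu"

    @property
    def num_stages(self) -> int:
        return len(self.depths)

    def stage_dim(self, i: int) -> int:
        return self.embed_dim * 2 ** i

    def stage_resolution(self, i: int) -> tuple[int, int]:
        h, w = self.image_size
        f = self.patch_size * 2 ** i
        return h // f, w // f

    @property
    def bottleneck_dim(self) -> int:
        return self.stage_dim(self.num_stages - 1)

    def validate(self) -> None:
        h, w = self.image_size
        div = self.patch_size * 2 ** (self.num_stages - 1)
        for name, d in (("height", h), ("width", w)):
            if d % div:
                raise ConfigurationError(
                    f"image {name} {d} not divisible by patch_size*2^(stages-1) = {div}"
                )
        if len(self.num_heads) != len(self.depths):
            raise ConfigurationError("num_heads and depths must have equal length")
        for i, nh in enumerate(self.num_heads):
            if self.stage_dim(i) % nh:
                raise ConfigurationError(
                    f"stage {i}: dim {self.stage_dim(i)} not divisible by {nh} heads"
                )
        if self.activation not in ("relu", "gelu"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        for i in range(self.num_stages):
            sh, sw = self.stage_resolution(i)
            if self.window_size < min(sh, sw) and (sh % self.window_size or sw % self.window_size):
                raise ConfigurationError(
                    f"stage {i}: window {self.window_size} neither divides "
                    f"resolution {sh}x{sw} nor covers it"
                )


def tiny_config(image_size: tuple[int, int] = (64, 64)) -> ModelConfig:
    """Desk-scale preset: 24-channel embedding, two stages, 4-pixel windows."""
    return ModelConfig(image_size=image_size, embed_dim=24, depths=(2, 2),
                       num_heads=(3, 6), window_size=4)


# ---------------------------------------------------------------------------
# Traced building blocks (autograd-compatible numpy)
# ---------------------------------------------------------------------------

def _layernorm(x, gain, bias, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps) * gain + bias


def _act(x, kind):
    if kind == "relu":
        return anp.maximum(x, 0.0)
    # tanh-approximate GELU
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608 * (x + 0.044715 * x ** 3)))


def _partition(x, wh, ww):
    """(B, H, W, C) -> (B*nW, wh*ww, C) non-overlapping windows."""
    b, h, w, c = x.shape
    x = anp.reshape(x, (b, h // wh, wh, w // ww, ww, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (-1, wh * ww, c))


def _unpartition(win, wh, ww, h, w):
    c = win.shape[-1]
    x = anp.reshape(win, (-1, h // wh, w // ww, wh, ww, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (-1, h, w, c))


def _softmax(x):
    x = x - anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=-1, keepdims=True)


def relative_position_index(wh: int, ww: int) -> np.ndarray:
    """Flat (N, N) index into a ((2wh-1)(2ww-1),) bias table, Swin-style."""
    coords = np.stack(np.meshgrid(np.arange(wh), np.arange(ww), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0)
    rel[:, :, 0] += wh - 1
    rel[:, :, 1] += ww - 1
    rel[:, :, 0] *= 2 * ww - 1
    return rel.sum(-1)


def shift_attention_mask(h: int, w: int, wh: int, ww: int, shift: int) -> np.ndarray:
    """(nW, N, N) additive mask: NEG_INF for token pairs wrapped across the
    cyclic-shift boundary, 0 elsewhere."""
    img = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, h - wh), slice(h - wh, h - shift), slice(h - shift, h)):
        for ws in (slice(0, w - ww), slice(w - ww, w - shift), slice(w - shift, w)):
            img[hs, ws] = cnt
            cnt += 1
    win = np.asarray(_partition(img[None, :, :, None], wh, ww))[:, :, 0]
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff != 0, NEG_INF, 0.0).astype(np.float32)


def window_attention(x, p, num_heads, window, shift=0, mask=None, rpb_index=None,
                     return_attn=False):
    """Multi-head self-attention within (possibly cyclically shifted) windows.

    ``x`` is (B, H, W, C); window may be an int or an (wh, ww) pair; when the
    window covers the whole map this degenerates to global attention over all
    tokens.  With ``shift > 0`` the map is rolled before partitioning and
    rolled back after, and ``mask`` blanks attention across wrapped borders.
    Output shape equals input shape.
    """
    b, h, w, c = x.shape
    wh, ww = (window, window) if np.isscalar(window) else window
    wh, ww = min(wh, h), min(ww, w)
    n = wh * ww
    if shift > 0:
        # one axis per call: autograd's roll VJP handles scalar shifts only
        x = anp.roll(anp.roll(x, -shift, axis=1), -shift, axis=2)
    tok = _partition(x, wh, ww)                       # (M, N, C)
    m = tok.shape[0]
    hd = c // num_heads
    qkv = anp.matmul(tok, p["qkv_w"]) + p["qkv_b"]    # (M, N, 3C)
    qkv = anp.reshape(qkv, (m, n, 3, num_heads, hd))
    qkv = anp.transpose(qkv, (2, 0, 3, 1, 4))         # (3, M, heads, N, hd)
    q, k, v = qkv[0], qkv[1], qkv[2]
    attn = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) * (hd ** -0.5)
    if rpb_index is None:
        rpb_index = relative_position_index(wh, ww)
    bias = anp.transpose(p["rpb_table"][rpb_index], (2, 0, 1))   # (heads, N, N)
    attn = attn + bias[None]
    if mask is not None:
        n_win = mask.shape[0]
        attn = anp.reshape(attn, (m // n_win, n_win, num_heads, n, n))
        attn = attn + mask[None, :, None]
        attn = anp.reshape(attn, (m, num_heads, n, n))
    attn = _softmax(attn)
    out = anp.matmul(attn, v)                          # (M, heads, N, hd)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (m, n, c))
    out = anp.matmul(out, p["proj_w"]) + p["proj_b"]
    out = _unpartition(out, wh, ww, h, w)
    if shift > 0:
        out = anp.roll(anp.roll(out, shift, axis=1), shift, axis=2)
    if return_attn:
        return out, np.asarray(attn)
    return out


def swin_block(x, p, num_heads, window, shift, mask, rpb_index, activation):
    """LN -> (S)W-MSA -> residual -> LN -> MLP -> residual."""
    y = _layernorm(x, p["ln1_g"], p["ln1_b"])
    x = x + window_attention(y, p, num_heads, window, shift, mask, rpb_index)
    y = _layernorm(x, p["ln2_g"], p["ln2_b"])
    y = _act(anp.matmul(y, p["fc1_w"]) + p["fc1_b"], activation)
    return x + anp.matmul(y, p["fc2_w"]) + p["fc2_b"]


def patch_merge(x, p):
    """2x2 neighborhood concat + LN + linear 4C -> 2C: resolution halves,
    channels double."""
    b, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ConfigurationError(f"patch_merge needs even resolution, got {h}x{w}")
    x = anp.reshape(x, (b, h // 2, 2, w // 2, 2, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (b, h // 2, w // 2, 4 * c))
    x = _layernorm(x, p["ln_g"], p["ln_b"])
    return anp.matmul(x, p["w"])


def patch_expand(x, p, factor=2):
    """Linear C -> factor^2 * C_out followed by pixel-shuffle: resolution
    scales by ``factor``; for factor 2, channels halve (inverse of merging)."""
    b, h, w, c = x.shape
    y = anp.matmul(x, p["w"]) + p["b"]
    c_out = y.shape[-1] // (factor * factor)
    y = anp.reshape(y, (b, h, w, factor, factor, c_out))
    y = anp.transpose(y, (0, 1, 3, 2, 4, 5))
    y = anp.reshape(y, (b, h * factor, w * factor, c_out))
    return _layernorm(y, p["ln_g"], p["ln_b"])


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _init_linear(rng, d_in, d_out):
    return {"w": rng.normal(0.0, 0.02, (d_in, d_out)).astype(np.float32),
            "b": np.zeros(d_out, dtype=np.float32)}


def _init_block(rng, dim, heads, win_area_table, mlp_hidden):
    return {
        "ln1_g": np.ones(dim, np.float32), "ln1_b": np.zeros(dim, np.float32),
        "qkv_w": rng.normal(0.0, 0.02, (dim, 3 * dim)).astype(np.float32),
        "qkv_b": np.zeros(3 * dim, np.float32),
        "proj_w": rng.normal(0.0, 0.02, (dim, dim)).astype(np.float32),
        "proj_b": np.zeros(dim, np.float32),
        "rpb_table": np.zeros((win_area_table, heads), np.float32),
        "ln2_g": np.ones(dim, np.float32), "ln2_b": np.zeros(dim, np.float32),
        "fc1_w": rng.normal(0.0, 0.02, (dim, mlp_hidden)).astype(np.float32),
        "fc1_b": np.zeros(mlp_hidden, np.float32),
        "fc2_w": rng.normal(0.0, 0.02, (mlp_hidden, dim)).astype(np.float32),
        "fc2_b": np.zeros(dim, np.float32),
    }


class SwinUNet:
    """Functional SwinUNet; parameters live in a nested dict of numpy arrays."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        # Per-stage window geometry, shift masks and relative-position indices
        # are fixed by the config, so precompute them once.
        self._stage_geom = []
        for i in range(config.num_stages):
            h, w = config.stage_resolution(i)
            if config.window_size >= min(h, w):
                wh, ww = min(config.window_size, h), min(config.window_size, w)
                multi = (h > wh) or (w > ww)
                if multi:  # window covers one axis only: still must divide
                    wh, ww = min(wh, h), min(ww, w)
            else:
                wh = ww = config.window_size
                multi = True
            shift = min(wh, ww) // 2 if multi else 0
            mask = shift_attention_mask(h, w, wh, ww, shift) if shift else None
            self._stage_geom.append({
                "res": (h, w), "win": (wh, ww), "shift": shift, "mask": mask,
                "rpb_index": relative_position_index(wh, ww),
                "table_size": (2 * wh - 1) * (2 * ww - 1),
            })

    # -- parameters ---------------------------------------------------------

    def init_params(self, seed: int = 0) -> dict:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E6]))
        patch_in = cfg.patch_size ** 2 * 3
        params: dict = {
            "patch_embed": {
                **_init_linear(rng, patch_in, cfg.embed_dim),
                "ln_g": np.ones(cfg.embed_dim, np.float32),
                "ln_b": np.zeros(cfg.embed_dim, np.float32),
            },
            "enc": [], "merge": [], "dec": [], "expand": [], "reduce": [],
        }

        def blocks(stage):
            dim, heads = cfg.stage_dim(stage), cfg.num_heads[stage]
            tbl = self._stage_geom[stage]["table_size"]
            return [_init_block(rng, dim, heads, tbl, int(dim * cfg.mlp_ratio))
                    for _ in range(cfg.depths[stage])]

        for i in range(cfg.num_stages):
            params["enc"].append(blocks(i))
            if i < cfg.num_stages - 1:
                dim = cfg.stage_dim(i)
                params["merge"].append({
                    "ln_g": np.ones(4 * dim, np.float32),
                    "ln_b": np.zeros(4 * dim, np.float32),
                    "w": rng.normal(0.0, 0.02, (4 * dim, 2 * dim)).astype(np.float32),
                })
        for i in range(cfg.num_stages - 2, -1, -1):
            dim = cfg.stage_dim(i)
            params["expand"].append({
                **_init_linear(rng, 2 * dim, 4 * dim),
                "ln_g": np.ones(dim, np.float32), "ln_b": np.zeros(dim, np.float32),
            })
            params["reduce"].append(_init_linear(rng, 2 * dim, dim))
            params["dec"].append(blocks(i))
        params["final_expand"] = {
            **_init_linear(rng, cfg.embed_dim, cfg.patch_size ** 2 * cfg.embed_dim),
            "ln_g": np.ones(cfg.embed_dim, np.float32),
            "ln_b": np.zeros(cfg.embed_dim, np.float32),
        }
        params["head"] = _init_linear(rng, cfg.embed_dim, cfg.num_classes)
        return params

    # -- forward ------------------------------------------------------------

    def _run_stage(self, x, stage_params, stage_idx):
        cfg = self.config
        g = self._stage_geom[stage_idx]
        for j, bp in enumerate(stage_params):
            shift = g["shift"] if j % 2 == 1 else 0
            mask = g["mask"] if shift else None
            x = swin_block(x, bp, cfg.num_heads[stage_idx], g["win"], shift, mask,
                           g["rpb_index"], cfg.activation)
        return x

    def forward(self, params, images, with_features=False, features_only=False,
                check_finite=False):
        """Images (B, H, W, 3) in [0, 1] -> per-pixel logits (B, H, W, classes).

        With ``with_features`` also returns the global-average-pooled
        bottleneck token features, one vector per image — the representation
        the domain-confusion (MMD) loss aligns across domains.
        """
        cfg = self.config
        b, h, w, _ = images.shape
        if (h, w) != cfg.image_size:
            raise ConfigurationError(
                f"input {h}x{w} does not match configured size {cfg.image_size}")
        ps = cfg.patch_size

        def chk(t, name):
            if check_finite and isinstance(t, np.ndarray) and not np.isfinite(t).all():
                raise NumericError(f"non-finite values after {name}")
            return t

        x = anp.reshape(images, (b, h // ps, ps, w // ps, ps, 3))
        x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
        x = anp.reshape(x, (b, h // ps, w // ps, ps * ps * 3))
        pe = params["patch_embed"]
        x = _layernorm(anp.matmul(x, pe["w"]) + pe["b"], pe["ln_g"], pe["ln_b"])
        chk(x, "patch_embed")

        skips = []
        for i in range(cfg.num_stages):
            x = self._run_stage(x, params["enc"][i], i)
            chk(x, f"encoder_stage{i}")
            if i < cfg.num_stages - 1:
                skips.append(x)
                x = patch_merge(x, params["merge"][i])

        feats = anp.mean(anp.reshape(x, (b, -1, cfg.bottleneck_dim)), axis=1)
        if features_only:
            return feats

        for di, i in enumerate(range(cfg.num_stages - 2, -1, -1)):
            x = patch_expand(x, params["expand"][di], factor=2)
            x = anp.concatenate([x, skips[i]], axis=-1)
            rp = params["reduce"][di]
            x = anp.matmul(x, rp["w"]) + rp["b"]
            x = self._run_stage(x, params["dec"][di], i)
            chk(x, f"decoder_stage{i}")

        x = patch_expand(x, params["final_expand"], factor=ps)
        hp = params["head"]
        logits = anp.matmul(x, hp["w"]) + hp["b"]
        chk(logits, "head")
        return (logits, feats) if with_features else logits

    def extract_adaptation_features(self, params, images):
        """Pooled bottleneck features (B, embed_dim * 2^(stages-1))."""
        return self.forward(params, images, features_only=True)

    def predict(self, params, images) -> np.ndarray:
        """Argmax class-index masks (B, H, W); raises NumericError on NaN/Inf."""
        logits = self.forward(params, np.asarray(images, dtype=np.float32),
                              check_finite=True)
        return np.argmax(logits, axis=-1)


def num_parameters(params) -> int:
    if isinstance(params, dict):
        return sum(num_parameters(v) for v in params.values())
    if isinstance(params, (list, tuple)):
        return sum(num_parameters(v) for v in params)
    return int(np.size(params))


def build_model(config: ModelConfig, seed: int = 0) -> tuple[SwinUNet, dict]:
    """Convenience constructor: validated network plus freshly initialized
    parameters."""
    net = SwinUNet(config)
    return net, net.init_params(seed)
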