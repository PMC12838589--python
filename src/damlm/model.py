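"""Hybrid 3D CNN-transformer encoder with classification and segmentation heads.

The encoder composes: a convolutional stem of multi-scale residual
blocks (parallel 3x3x3 and 5x5x5 branches summed before the residual
add, PReLU activation, joint batch normalization), a squeeze-excitation
style channel attention, tokenization with sinusoidal (or learned)
positional encodings, and a stack of pre-LayerNorm self-attention
layers.  Tokens are globally average-pooled into the embedding used by
the classifier and the domain-adaptation losses.  A mirrored
transposed-convolution decoder with skip connections provides voxel-wise
tumor-region probabilities for the Dice-based segmentation loss.

All computation runs on the float64 autograd engine in
:mod:`damlm.autograd`; forward passes are deterministic given weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .autograd import Tensor, concatenate, conv3d, conv_transpose3d

EPS_LOG = 1e-12   # probability clamp before log
N_REGIONS = 4     # background, edema, core, enhancing


# ------------------------------------------------------------------- modules
class Module:
    """Minimal parameter container with recursive traversal."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{key}.{i}."))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        bufs: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if name.startswith("running_") and isinstance(value, np.ndarray):
                bufs[key] = value
            elif isinstance(value, Module):
                bufs.update(value.named_buffers(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        bufs.update(item.named_buffers(f"{key}.{i}."))
        return bufs


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = np.sqrt(6.0 / fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        if zero_init:
            self.weight = Tensor(np.zeros((cout, cin, k, k, k)), requires_grad=True)
        else:
            self.weight = kaiming_uniform(rng, (cout, cin, k, k, k), fan_in)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose3d(Module):
    def __init__(self, cin: int, cout: int, k: int = 2, stride: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = kaiming_uniform(rng, (cin, cout, k, k, k), cin * k**3)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            self.weight = Tensor(np.zeros((cin, cout)), requires_grad=True)
        else:
            self.weight = kaiming_uniform(rng, (cin, cout), cin)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.alpha = Tensor(np.full((1, channels, 1, 1, 1), init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.prelu(self.alpha)


class BatchNorm3d(Module):
    """Joint batch statistics over the full (mixed-domain) batch.

    Training mode normalizes with the batch mean/variance (ddof=0,
    pooled over batch and spatial axes — never per-domain); running
    estimates are updated with momentum 0.9 and used in eval mode.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3, 4), keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data.ravel())
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1, 1))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return self.gamma * xhat + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return self.gamma * ((x - mu) / (var + self.eps).sqrt()) + self.beta


# -------------------------------------------------------------------- config
@dataclass(frozen=True)
class EncoderConfig:
    conv_depth: int = 4
    channels: int = 32
    transformer_depth: int = 2
    attention_heads: int = 1
    positional_encoding: str = "sinusoidal"   # or "learned"
    attention_scale: str = "sqrt_C"           # or "C"
    backbone_mode: str = "hybrid"             # hybrid | cnn_only | transformer_only
    in_channels: int = 4
    strided_blocks: tuple[int, ...] | None = None  # 1-based; None -> even blocks
    ffn_hidden_mult: int = 2

    def __post_init__(self):
        if self.channels % self.attention_heads:
            raise ValueError("channels must be divisible by attention_heads")
        if self.backbone_mode not in ("hybrid", "cnn_only", "transformer_only"):
            raise ValueError(f"unknown backbone_mode {self.backbone_mode!r}")

    @property
    def strided(self) -> tuple[int, ...]:
        if self.strided_blocks is not None:
            return tuple(self.strided_blocks)
        return tuple(b for b in range(2, self.conv_depth + 1, 2))

    @property
    def downsample_factor(self) -> int:
        return 2 ** len(self.strided)


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    class_count: int = 2
    segmentation: bool = False
    seed: int = 0


# --------------------------------------------------------------- stem blocks
class ResidualBlock(Module):
    """U + phi(W * U) with a multi-scale (3^3 + 5^3) convolution branch.

    When channels change or the block is strided, the residual path uses
    a 1x1x1 projection so shapes match.
    """

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.branch3 = Conv3d(cin, cout, 3, stride, rng)
        self.branch5 = Conv3d(cin, cout, 5, stride, rng)
        self.bn = BatchNorm3d(cout)
        self.act = PReLU(cout)
        self.proj = (None if (cin == cout and stride == 1)
                     else Conv3d(cin, cout, 1, stride, rng))

    def __call__(self, u: Tensor) -> Tensor:
        conv = self.bn(self.branch3(u) + self.branch5(u))
        res = u if self.proj is None else self.proj(u)
        return res + self.act(conv)


class ChannelAttention(Module):
    """s = sigmoid(W2 relu(W1 GAP(F0))); F0* = s (channel-wise) F0."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 2):
        hidden = max(channels // reduction, 1)
        self.w1 = Linear(channels, hidden, rng)
        self.w2 = Linear(hidden, channels, rng)

    def __call__(self, f0: Tensor):
        gap = f0.mean(axis=(2, 3, 4))                     # (B, C)
        s = self.w2(self.w1(gap).relu()).sigmoid()        # (B, C)
        b, c = s.shape
        refined = f0 * s.reshape(b, c, 1, 1, 1)
        return refined, s


# ------------------------------------------------------------- tokenization
def sinusoidal_positions(grid_shape, channels: int) -> np.ndarray:
    """Per-axis sinusoids over C/3 sub-bands, concatenated, fit to C.

    Token order matches :func:`grid_to_tokens` (x fastest).
    """
    per_axis = max(channels // 3, 2)
    if per_axis % 2:
        per_axis += 1
    cols = []
    coords = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    # flatten with x fastest
    flat = [c.transpose(2, 1, 0).reshape(-1).astype(float) for c in coords]
    for pos in flat:
        half = per_axis // 2
        freqs = 1.0 / (10000.0 ** (np.arange(half) / max(half, 1)))
        ang = pos[:, None] * freqs[None, :]
        cols.append(np.sin(ang))
        cols.append(np.cos(ang))
    P = np.concatenate(cols, axis=1)
    if P.shape[1] >= channels:
        return P[:, :channels]
    return np.pad(P, ((0, 0), (0, channels - P.shape[1])))


def grid_to_tokens(f: Tensor) -> Tensor:
    """(B, C, X, Y, Z) -> (B, N, C), token index runs x fastest."""
    b, c, x, y, z = f.shape
    return f.transpose(0, 4, 3, 2, 1).reshape(b, x * y * z, c)


def tokens_to_grid(t: Tensor, grid_shape) -> Tensor:
    b, n, c = t.shape
    x, y, z = grid_shape
    return t.reshape(b, z, y, x, c).transpose(0, 4, 3, 2, 1)


class TransformerLayer(Module):
    """Pre-LN self-attention followed by a 2-layer feed-forward, residual add."""

    def __init__(self, channels: int, heads: int, scale_mode: str,
                 ffn_hidden: int, rng: np.random.Generator):
        self.ln = LayerNorm(channels)
        self.wq = Linear(channels, channels, rng)
        self.wk = Linear(channels, channels, rng)
        self.wv = Linear(channels, channels, rng)
        self.ffn1 = Linear(channels, ffn_hidden, rng)
        self.ffn2 = Linear(ffn_hidden, channels, rng)
        self.heads = heads
        self.scale = channels ** 0.5 if scale_mode == "sqrt_C" else float(channels)

    def attention(self, z: Tensor) -> tuple[Tensor, Tensor]:
        zn = self.ln(z)
        q, k, v = self.wq(zn), self.wk(zn), self.wv(zn)
        if self.heads > 1:
            b, n, c = q.shape
            d = c // self.heads
            def split(t):
                return t.reshape(b, n, self.heads, d).transpose(0, 2, 1, 3)
            q, k, v = split(q), split(k), split(v)
            att = (q @ k.transpose(0, 1, 3, 2) * (1.0 / self.scale)).softmax(axis=-1)
            out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, c)
        else:
            att = (q @ k.transpose(0, 2, 1) * (1.0 / self.scale)).softmax(axis=-1)
            out = att @ v
        return out, att

    def __call__(self, z: Tensor) -> Tensor:
        attn_out, _ = self.attention(z)
        return z + self.ffn2(self.ffn1(attn_out).relu())


# ------------------------------------------------------------------ encoder
class Encoder(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        C = cfg.channels
        self.blocks: list[ResidualBlock] = []
        if cfg.backbone_mode != "transformer_only":
            cin = cfg.in_channels
            for b in range(1, cfg.conv_depth + 1):
                stride = 2 if b in cfg.strided else 1
                self.blocks.append(ResidualBlock(cin, C, stride, rng))
                cin = C
            self.channel_attention = ChannelAttention(C, rng)
        else:
            f = cfg.downsample_factor
            self.patch_embed = Linear(cfg.in_channels * f**3, C, rng)
        self.layers = [
            TransformerLayer(C, cfg.attention_heads, cfg.attention_scale,
                             cfg.ffn_hidden_mult * C, rng)
            for _ in range(cfg.transformer_depth)
        ] if cfg.backbone_mode != "cnn_only" else []
        self._learned_pos: dict[tuple, Tensor] = {}
        if cfg.positional_encoding == "learned":
            # lazily created per grid shape, zero-initialized
            pass

    # -- positional encodings ------------------------------------------------
    def positions(self, grid_shape) -> Tensor:
        if self.cfg.positional_encoding == "learned":
            key = tuple(grid_shape)
            if key not in self._learned_pos:
                n = int(np.prod(grid_shape))
                self._learned_pos[key] = Tensor(
                    np.zeros((n, self.cfg.channels)), requires_grad=True)
            return self._learned_pos[key]
        return Tensor(sinusoidal_positions(grid_shape, self.cfg.channels))

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params = super().named_parameters(prefix)
        for key, t in self._learned_pos.items():
            params[f"{prefix}pos_{'x'.join(map(str, key))}"] = t
        return params

    # -- forward -------------------------------------------------------------
    def stem_forward(self, x: Tensor):
        """Returns (F0, skip list at each resolution, incl. the input)."""
        skips = [x]
        f = x
        for block in self.blocks:
            f = block(f)
            skips.append(f)
        return f, skips

    def __call__(self, x: Tensor):
        """x: (B, 4, h, w, d) -> dict with tokens, pooled embedding, skips."""
        cfg = self.cfg
        f = cfg.downsample_factor
        if any(s % f for s in x.shape[2:]):
            raise ValueError("patch shape not divisible by the stem downsampling factor")
        if cfg.backbone_mode == "transformer_only":
            b, c, X, Y, Z = x.shape
            gx, gy, gz = X // f, Y // f, Z // f
            # partition into f^3 blocks, x fastest token order
            cells = x.reshape(b, c, gx, f, gy, f, gz, f)
            cells = cells.transpose(0, 6, 4, 2, 1, 3, 5, 7)  # (B,gz,gy,gx,C,f,f,f)
            tokens_in = cells.reshape(b, gx * gy * gz, c * f**3)
            z = self.patch_embed(tokens_in)
            grid_shape = (gx, gy, gz)
            skips = None
            s_weights = None
        else:
            f0, skips = self.stem_forward(x)
            f0_star, s_weights = self.channel_attention(f0)
            grid_shape = f0.shape[2:]
            z = grid_to_tokens(f0_star)
        z = z + self.positions(grid_shape)
        for layer in self.layers:
            z = layer(z)
        g = z.mean(axis=1)  # GAP over tokens
        return {"tokens": z, "pooled": g, "grid_shape": tuple(grid_shape),
                "skips": skips, "channel_weights": s_weights}


# -------------------------------------------------------------------- heads
def global_pool(z: Tensor) -> Tensor:
    """h = (1/N) sum_i z_i over the token axis."""
    return z.mean(axis=1)


class Classifier(Module):
    def __init__(self, channels: int, class_count: int, rng: np.random.Generator):
        self.fc = Linear(channels, class_count, rng)

    def __call__(self, h: Tensor):
        logits = self.fc(h)
        return logits, logits.softmax(axis=-1)


def classification_loss(probs: Tensor, y_onehot: np.ndarray) -> Tensor:
    """Categorical cross-entropy -sum_k y_k log yhat_k, eps-clamped."""
    y = Tensor(np.asarray(y_onehot, dtype=np.float64))
    per_sample = -(y * probs.clip_min(EPS_LOG).log()).sum(axis=-1)
    return per_sample.mean() if per_sample.ndim else per_sample


class SegmentationDecoder(Module):
    """Mirrored transposed-conv decoder with stem skip connections."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        if cfg.backbone_mode == "transformer_only":
            raise ValueError("segmentation decoder requires a convolutional grid")
        C = cfg.channels
        self.ups: list[ConvTranspose3d] = []
        self.fuses: list[Conv3d] = []
        self.acts: list[PReLU] = []
        skip_channels = self._skip_channels(cfg)
        for sc in skip_channels:
            self.ups.append(ConvTranspose3d(C, C, 2, 2, rng))
            self.fuses.append(Conv3d(C + sc, C, 3, 1, rng))
            self.acts.append(PReLU(C))
        self.head = Conv3d(C, N_REGIONS, 1, 1, rng)
        self._skip_indices_cached = self._skip_indices(cfg)

    @staticmethod
    def _skip_channels(cfg: EncoderConfig) -> list[int]:
        """Channels of the stem feature concatenated at each upsampling step
        (deepest-but-one resolution first, raw input last)."""
        chans = [cfg.in_channels] + [cfg.channels] * cfg.conv_depth
        strided = sorted(cfg.strided)
        # resolution level after block b = number of strided blocks <= b
        # pick, for each level below the deepest, the last feature at that level
        levels: dict[int, int] = {0: cfg.in_channels}
        lev = 0
        for b in range(1, cfg.conv_depth + 1):
            if b in strided:
                lev += 1
            levels[lev] = chans[b]
        deepest = lev
        return [levels[l] for l in range(deepest - 1, -1, -1)]

    @staticmethod
    def _skip_indices(cfg: EncoderConfig) -> list[int]:
        strided = sorted(cfg.strided)
        levels: dict[int, int] = {0: 0}
        lev = 0
        for b in range(1, cfg.conv_depth + 1):
            if b in strided:
                lev += 1
            levels[lev] = b
        deepest = lev
        return [levels[l] for l in range(deepest - 1, -1, -1)]

    def __call__(self, tokens: Tensor, grid_shape, skips: list[Tensor]):
        if skips is None:
            raise ValueError("segmentation decoding needs stem skip features")
        f = tokens_to_grid(tokens, grid_shape)
        idx = self._skip_indices_cached
        for up, fuse, act, i in zip(self.ups, self.fuses, self.acts, idx):
            f = up(f)
            f = act(fuse(concatenate([f, skips[i]], axis=1)))
        logits = self.head(f)
        return logits.softmax(axis=1)


def dice_loss(pred_probs: Tensor, region_mask: np.ndarray,
              eps: float = 1e-5) -> Tensor:
    """Soft Dice loss over the three foreground tumor classes.

    L = 1 - mean_c (2 sum p_c g_c + eps) / (sum p_c + sum g_c + eps).
    """
    terms = []
    for c in range(1, N_REGIONS):
        g = (np.asarray(region_mask) == c).astype(np.float64)
        p = pred_probs[:, c] if pred_probs.ndim == 5 else pred_probs[c]
        gt = Tensor(g)
        num = (p * gt).sum() * 2.0 + eps
        den = p.sum() + Tensor(g.sum()) + eps
        terms.append(num / den)
    dice = terms[0]
    for t in terms[1:]:
        dice = dice + t
    return 1.0 - dice * (1.0 / len(terms))


# --------------------------------------------------------------------- model
class DAMLM(Module):
    """Encoder + classifier (+ optional segmentation decoder)."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg.encoder, rng)
        self.classifier = Classifier(cfg.encoder.channels, cfg.class_count, rng)
        self.decoder = None
        if cfg.segmentation:
            self.decoder = SegmentationDecoder(cfg.encoder, rng)

    def __call__(self, x: Tensor, segment: bool | None = None) -> dict:
        enc = self.encoder(x)
        h = enc["pooled"]
        logits, probs = self.classifier(h)
        out = {**enc, "h": h, "logits": logits, "probs": probs, "seg_probs": None}
        if (segment if segment is not None else self.decoder is not None) and self.decoder:
            out["seg_probs"] = self.decoder(enc["tokens"], enc["grid_shape"], enc["skips"])
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        params = self.named_parameters()
        buffers = self.named_buffers()
        header = json.dumps({"config": _config_to_dict(self.cfg),
                             "names": list(params),
                             "buffer_names": list(buffers)})
        arrays = {f"p{i}": t.data for i, t in enumerate(params.values())}
        arrays.update({f"b{i}": a for i, a in enumerate(buffers.values())})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "DAMLM":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            model = cls(_config_from_dict(header["config"]))
            params = model.named_parameters()
            for i, name in enumerate(header["names"]):
                params[name].data[...] = z[f"p{i}"]
            buffers = model.named_buffers()
            for i, name in enumerate(header.get("buffer_names", [])):
                buffers[name][...] = z[f"b{i}"]
        return model


def _config_to_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    enc = d.pop("encoder")
    if enc.get("strided_blocks") is not None:
        enc["strided_blocks"] = tuple(enc["strided_blocks"])
    return ModelConfig(encoder=EncoderConfig(**enc), **d)
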