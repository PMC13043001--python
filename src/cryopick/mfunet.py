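"""Multi-frequency domain U-Net for semantic segmentation of micrographs.

Architecture: a 4-stage pyramid encoder (strides 4/8/16/32; either a
pyramid-transformer-style encoder with spatial-reduction attention or a
small strided-CNN variant that trains quickly on CPU), a ContextAggregation
bottleneck (dilated 3x3 convolutions at rates 1/3/5 plus a global-average
branch, fused by a 1x1 convolution), Global-Local ECA gating on the skip
connections, and a decoder whose blocks process features in the wavelet
domain (per-subband depthwise convolutions between an orthonormal DWT/IDWT
pair) alongside a spatial convolution path, with residual connections.
The main head emits full-resolution logits; three auxiliary heads at the
1/4, 1/8 and 1/16 decoder levels support deep supervision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .losses import SemanticOutput
from .nn import tensor as T


@dataclass
class ModelConfig:
    encoder: str = "tiny_cnn"
    stage_channels: tuple = (8, 16, 32, 64)
    decoder_channels: tuple = (32, 16, 8, 8)  # at strides 16/8/4/2
    wavelet: str = "haar"
    wt_levels: int = 1
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    dilations: tuple = (1, 3, 5)
    input_size: int = 1024
    deep_supervision: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.encoder not in ("tiny_cnn", "pvt_like"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        self.stage_channels = tuple(self.stage_channels)
        self.decoder_channels = tuple(self.decoder_channels)
        self.dilations = tuple(self.dilations)


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1D kernel size: nearest odd to |log2(C)/gamma + b/gamma|.

    Ties between two odd integers break downward; minimum 1.
    """
    v = abs(math.log2(channels) / gamma + b / gamma)
    lo = max(1, 2 * int((v - 1) // 2) + 1)  # largest odd <= v (>=1)
    hi = lo + 2
    return lo if (v - lo) <= (hi - v) else hi


def wavelet_kernels(name: str, dtype=np.float32):
    """2D analysis kernels (LL, LH, HL, HH) of an orthonormal wavelet.

    Filters come from PyWavelets; the transform below applies them as
    cross-correlations, which keeps the operator orthogonal (the inverse
    is its adjoint).
    """
    import pywt

    wav = pywt.Wavelet(name)
    if not wav.orthogonal:
        raise ValueError(f"wavelet {name!r} is not orthogonal")
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    kernels = [
        np.outer(lo, lo),  # LL
        np.outer(lo, hi),  # LH (horizontal detail)
        np.outer(hi, lo),  # HL (vertical detail)
        np.outer(hi, hi),  # HH
    ]
    return np.stack(kernels), len(lo)


def dwt2(x, kernels, flen):
    """One-level 2D DWT of an NCHW tensor (periodic boundary).

    Output has 4*C channels ordered [LL..., LH..., HL..., HH...] at half
    resolution. Input spatial dims must be even.
    """
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("dwt2 requires even spatial dims")
    if flen > 2:
        pad = flen - 2
        x = T.concat([x, x[:, :, :pad, :]], axis=2)
        x = T.concat([x, x[:, :, :, :pad]], axis=3)
    c4 = np.zeros((4 * c, 1, flen, flen), dtype=x.data.dtype)
    for s in range(4):
        c4[s * c : (s + 1) * c, 0] = kernels[s]
    # grouped conv: each subband kernel applied per channel
    xr = T.concat([x, x, x, x], axis=1)
    return T.conv2d(xr, nn.Tensor(c4), stride=2, padding=0, groups=4 * c)


def idwt2(d, kernels, flen, out_hw):
    """Inverse of :func:`dwt2` — the adjoint of the orthogonal analysis."""
    b, c4, _, _ = d.shape
    c = c4 // 4
    k = np.zeros((4 * c, 1, flen, flen), dtype=d.data.dtype)
    for s in range(4):
        k[s * c : (s + 1) * c, 0] = kernels[s]
    pad = flen - 2
    hw = (out_hw[0] + pad, out_hw[1] + pad)
    y = T.conv_transpose2d(d, nn.Tensor(k), stride=2, padding=0, groups=4 * c,
                           out_hw=hw)
    if pad:
        # adjoint of the periodic padding: fold the wrapped border back
        top = y[:, :, out_hw[0] :, :]
        y = T.concat(
            [y[:, :, :pad, :] + top, y[:, :, pad : out_hw[0], :]], axis=2
        )
        right = y[:, :, :, out_hw[1] :]
        y = T.concat(
            [y[:, :, :, :pad] + right, y[:, :, :, pad : out_hw[1]]], axis=3
        )
    # sum the four reconstructed subband contributions
    parts = [y[:, s * c : (s + 1) * c] for s in range(4)]
    return parts[0] + parts[1] + parts[2] + parts[3]


class GlobalLocalECA(nn.Module):
    """Dual-path skip-connection gate.

    Local path: bias-free depthwise-separable convolution (fine texture).
    Global path: channel weights in (0,1) from global average pooling
    followed by a 1D convolution across channels of adaptive odd size and
    a sigmoid; output = local(x) + x * w.
    """

    def __init__(self, channels, rng, gamma=2.0, b=1.0):
        if channels < 2:
            raise ValueError("GlobalLocalECA needs at least 2 channels")
        self.local = nn.DepthwiseSeparableConv(channels, rng)
        self.k = eca_kernel_size(channels, gamma, b)
        self.conv1d = nn.Conv2d(1, 1, 1, rng, bias=False)
        # replace with a (1, k) kernel acting along the channel axis
        self.conv1d.weight = nn.Tensor(
            nn.kaiming(rng, (1, 1, 1, self.k), self.k), requires_grad=True
        )
        self.conv1d.padding = (0, self.k // 2)

    def channel_weights(self, x):
        b, c = x.shape[0], x.shape[1]
        gap = T.global_avg_pool(x)  # (B, C, 1, 1)
        seq = T.reshape(gap, (b, 1, 1, c))
        w = T.sigmoid(self.conv1d(seq))
        return T.reshape(w, (b, c, 1, 1))

    def forward(self, x):
        return self.local(x) + x * self.channel_weights(x)


class ContextAggregation(nn.Module):
    """Multi-scale bottleneck: dilated 3x3 branches + global pooling branch."""

    def __init__(self, channels, rng, dilations=(1, 3, 5)):
        self.dilations = tuple(dilations)
        self.branches = [
            nn.Conv2d(channels, channels, 3, rng, dilation=d) for d in self.dilations
        ]
        self.gap_conv = nn.Conv2d(channels, channels, 1, rng)
        self.fuse = nn.Conv2d(len(self.dilations) * channels + channels,
                              channels, 1, rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h < 5 or w < 5:
            raise ValueError(
                f"ContextAggregation needs spatial dims >= 5, got {(h, w)}"
            )
        outs = [T.relu(conv(x)) for conv in self.branches]
        g = T.relu(self.gap_conv(T.global_avg_pool(x)))
        zeros = nn.Tensor(np.zeros((1, 1, h, w), dtype=np.float32))
        outs.append(g + zeros)  # broadcast to the spatial grid
        return self.fuse(T.concat(outs, axis=1))


class WTConvBlock(nn.Module):
    """Wavelet-domain convolution block.

    DWT -> small depthwise convolution on each subband (recursively on the
    LL chain for ``wt_levels`` levels) -> IDWT, plus a standard spatial
    convolution path. The caller adds the identity residual.
    """

    def __init__(self, channels, rng, wavelet="haar", wt_levels=1):
        self.kernels, self.flen = wavelet_kernels(wavelet)
        self.wt_levels = wt_levels
        self.channels = channels
        self.subband_convs = [
            nn.Conv2d(4 * channels, 4 * channels, 3, rng, groups=4 * channels)
            for _ in range(wt_levels)
        ]
        self.spatial = nn.Conv2d(channels, channels, 3, rng)

    def set_identity(self):
        """Configure the wavelet path as a perfect-reconstruction identity
        and zero the spatial path (used to verify invertibility)."""
        for conv in self.subband_convs:
            w = np.zeros_like(conv.weight.data)
            w[:, 0, 1, 1] = 1.0
            conv.weight.data = w
            conv.bias.data = np.zeros_like(conv.bias.data)
        self.spatial.weight.data = np.zeros_like(self.spatial.weight.data)
        self.spatial.bias.data = np.zeros_like(self.spatial.bias.data)

    def _wave(self, x, level):
        c = self.channels
        d = dwt2(x, self.kernels, self.flen)
        d = self.subband_convs[level](d)
        if level + 1 < self.wt_levels and d.shape[2] % 2 == 0 and d.shape[2] >= 4:
            ll = d[:, :c]
            ll = self._wave(ll, level + 1)
            d = T.concat([ll, d[:, c:]], axis=1)
        return idwt2(d, self.kernels, self.flen, (x.shape[2], x.shape[3]))

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        pad_h, pad_w = h % 2, w % 2
        if pad_h or pad_w:  # pad-and-crop odd inputs
            if pad_h:
                x = T.concat([x, x[:, :, -1:, :]], axis=2)
            if pad_w:
                x = T.concat([x, x[:, :, :, -1:]], axis=3)
        y = self._wave(x, 0) + self.spatial(x)
        if pad_h or pad_w:
            y = y[:, :, :h, :w]
        return y


class TinyCNNEncoder(nn.Module):
    """Four strided-convolution stages at strides 4/8/16/32."""

    def __init__(self, channels, rng):
        c1, c2, c3, c4 = channels
        self.stem = nn.Sequential(
            nn.Conv2d(1, c1, 3, rng, stride=2), nn.ReLU(),
            nn.Conv2d(c1, c1, 3, rng, stride=2), nn.ReLU(),
            nn.Conv2d(c1, c1, 3, rng), nn.ReLU(),
        )
        self.stages = [
            nn.Sequential(
                nn.Conv2d(cin, cout, 3, rng, stride=2), nn.ReLU(),
                nn.Conv2d(cout, cout, 3, rng), nn.ReLU(),
            )
            for cin, cout in zip((c1, c2, c3), (c2, c3, c4))
        ]

    def forward(self, x):
        f1 = self.stem(x)
        f2 = self.stages[0](f1)
        f3 = self.stages[1](f2)
        f4 = self.stages[2](f3)
        return [f1, f2, f3, f4]


class _SRABlock(nn.Module):
    """Pre-norm transformer block with spatial-reduction attention."""

    def __init__(self, c, rng, sr_ratio):
        self.norm1 = nn.LayerNormChannels(c)
        self.norm2 = nn.LayerNormChannels(c)
        self.q = nn.Conv2d(c, c, 1, rng)
        self.kv_reduce = (
            nn.Conv2d(c, c, sr_ratio, rng, stride=sr_ratio, padding=0)
            if sr_ratio > 1
            else None
        )
        self.k = nn.Conv2d(c, c, 1, rng)
        self.v = nn.Conv2d(c, c, 1, rng)
        self.proj = nn.Conv2d(c, c, 1, rng)
        # convolutional MLP (1x1 expand, depthwise 3x3, 1x1 project)
        self.mlp = nn.Sequential(
            nn.Conv2d(c, 2 * c, 1, rng),
            nn.Conv2d(2 * c, 2 * c, 3, rng, groups=2 * c),
            nn.GELU(),
            nn.Conv2d(2 * c, c, 1, rng),
        )
        self.scale = 1.0 / math.sqrt(c)

    def _attention(self, x):
        b, c, h, w = x.shape
        q = T.reshape(self.q(x), (b, c, h * w))
        q = T.transpose(q, (0, 2, 1))  # (B, N, C)
        kv_src = self.kv_reduce(x) if self.kv_reduce is not None else x
        m = kv_src.shape[2] * kv_src.shape[3]
        k = T.reshape(self.k(kv_src), (b, c, m))  # (B, C, M)
        v = T.transpose(T.reshape(self.v(kv_src), (b, c, m)), (0, 2, 1))
        attn = T.softmax(T.matmul(q, k) * self.scale, axis=-1)  # (B, N, M)
        out = T.matmul(attn, v)  # (B, N, C)
        out = T.reshape(T.transpose(out, (0, 2, 1)), (b, c, h, w))
        return self.proj(out)

    def forward(self, x):
        x = x + self._attention(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class PVTLikeEncoder(nn.Module):
    """Pyramid-transformer-style encoder: overlapping patch embeddings +
    one spatial-reduction attention block per stage."""

    def __init__(self, channels, rng):
        strides = (4, 2, 2, 2)
        patch_k = (7, 3, 3, 3)
        sr = (8, 4, 2, 1)
        cins = (1,) + tuple(channels[:3])
        self.embeds = [
            nn.Conv2d(cin, cout, k, rng, stride=s, padding=k // 2)
            for cin, cout, k, s in zip(cins, channels, patch_k, strides)
        ]
        self.norms = [nn.LayerNormChannels(c) for c in channels]
        self.blocks = [
            _SRABlock(c, rng, r) for c, r in zip(channels, sr)
        ]

    def forward(self, x):
        feats = []
        for embed, norm, block in zip(self.embeds, self.norms, self.blocks):
            x = block(norm(embed(x)))
            feats.append(x)
        return feats


class _DecoderLevel(nn.Module):
    """x2 upsample, optional ECA-gated skip fusion, wavelet block, residual."""

    def __init__(self, cin, cskip, cout, rng, cfg: ModelConfig):
        self.eca = (
            GlobalLocalECA(cskip, rng, cfg.eca_gamma, cfg.eca_b) if cskip else None
        )
        self.fuse = nn.Conv2d(cin + cskip, cout, 1, rng)
        self.wt = WTConvBlock(cout, rng, cfg.wavelet, cfg.wt_levels)

    def forward(self, x, skip=None):
        x = T.upsample_bilinear2x(x)
        if skip is not None:
            x = T.concat([x, self.eca(skip)], axis=1)
        pre = self.fuse(x)
        return T.relu(pre + self.wt(pre))


class MFUNet(nn.Module):
    """The full encoder-bottleneck-decoder with deep-supervision heads."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.stage_channels
        dc = cfg.decoder_channels
        if cfg.encoder == "tiny_cnn":
            self.encoder = TinyCNNEncoder(ch, rng)
        else:
            self.encoder = PVTLikeEncoder(ch, rng)
        self.bottleneck = ContextAggregation(ch[3], rng, cfg.dilations)
        self.levels = [
            _DecoderLevel(ch[3], ch[2], dc[0], rng, cfg),  # /32 -> /16
            _DecoderLevel(dc[0], ch[1], dc[1], rng, cfg),  # /16 -> /8
            _DecoderLevel(dc[1], ch[0], dc[2], rng, cfg),  # /8  -> /4
            _DecoderLevel(dc[2], 0, dc[3], rng, cfg),      # /4  -> /2
        ]
        self.head = nn.Conv2d(dc[3], 1, 1, rng)
        self.aux_heads = [nn.Conv2d(c, 1, 1, rng) for c in (dc[2], dc[1], dc[0])]

    def forward(self, x: nn.Tensor):
        """Return (logits, aux_logits) tensors at full input resolution."""
        b, c, h, w = x.shape
        if h != w or h % 32:
            raise ValueError(
                f"input must be square with side divisible by 32, got {(h, w)}"
            )
        f1, f2, f3, f4 = self.encoder(x)
        d = self.bottleneck(f4)
        d16 = self.levels[0](d, f3)
        d8 = self.levels[1](d16, f2)
        d4 = self.levels[2](d8, f1)
        d2 = self.levels[3](d4)
        logits = T.upsample_bilinear2x(self.head(d2))
        aux = []
        if self.cfg.deep_supervision:
            for head, feat in zip(self.aux_heads, (d4, d8, d16)):
                aux.append(T.upsample_to(head(feat), (h, w)))
        return logits, aux

    def predict(self, image: np.ndarray) -> SemanticOutput:
        """Inference on one preprocessed [0,1] image (numpy in/out)."""
        x = nn.Tensor(np.asarray(image, dtype=np.float32)[None, None])
        logits, aux = self.forward(x)
        prob = 1.0 / (1.0 + np.exp(-logits.data[0, 0]))
        aux_probs = [1.0 / (1.0 + np.exp(-a.data[0, 0])) for a in aux]
        return SemanticOutput(
            prob=prob,
            aux_probs=aux_probs,
            logits=logits.data[0, 0],
            aux_logits=[a.data[0, 0] for a in aux],
        )


def save_checkpoint(model: MFUNet, path):
    state = model.named_state()
    cfg = json.dumps(model.cfg.__dict__)
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> MFUNet:
    data = np.load(path)
    cfg_raw = bytes(data["__config__"]).decode()
    cfg = ModelConfig(**json.loads(cfg_raw))
    model = MFUNet(cfg)
    model.load_state({k: data[k] for k in data.files if k != "__config__"})
    return model
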