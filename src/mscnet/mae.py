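"""Multi-structure A/V Extraction network.

The encoder stages of a U-shaped scaffold are convolutional blocks followed by
a contextual-attention block that replaces the query-key matrix product of a
standard transformer with concatenation: a grouped convolution of the keys
yields a *static* context map; 1x1 convolutions over concat(static, query)
produce per-pixel, per-group softmax weights over a small local neighborhood;
the *dynamic* context is the value map aggregated under those weights.  The
block output is static + dynamic.  Cost is linear in pixel count because the
aggregation is local rather than a dense token-token product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import (
    Conv2d,
    ConvBNReLU,
    DoubleConv,
    Module,
    Tensor,
    cat,
    softmax,
)
from .mve import UNetScaffold

N_CLASSES = 3  # background / artery / vein; uncertain is never predicted


def standard_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Reference scaled dot-product attention: softmax(QK^T / sqrt(d_k)) V.

    A readable oracle used only in tests and documentation; the production
    blocks never form the token-token product.
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    if q.shape[1] != k.shape[1]:
        raise ValueError(f"key dim mismatch: Q {q.shape} vs K {k.shape}")
    if k.shape[0] != v.shape[0]:
        raise ValueError(f"token count mismatch: K {k.shape} vs V {v.shape}")
    scores = q @ k.T / np.sqrt(k.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ v


@dataclass
class CotBlockConfig:
    channels: int
    key_kernel: int = 3
    groups: int = 4
    attn_kernel: int = 3

    def validate(self) -> None:
        if self.channels % self.groups:
            raise ValueError(
                f"channels {self.channels} not divisible by groups {self.groups}"
            )
        if self.key_kernel % 2 == 0 or self.attn_kernel % 2 == 0:
            raise ValueError("kernels must be odd")


class CotBlock(Module):
    """Contextual-attention block with local value aggregation."""

    def __init__(self, cfg: CotBlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c, g, ka = cfg.channels, cfg.groups, cfg.attn_kernel
        hidden = max(c // 2, g)
        self.conv_in = ConvBNReLU(c, c, kernel=3, rng=rng)
        self.w_v = Conv2d(c, c, 1, rng=rng)
        self.key_conv = Conv2d(c, c, cfg.key_kernel, groups=g, rng=rng)
        self.w_theta = Conv2d(2 * c, hidden, 1, rng=rng)
        self.w_delta = Conv2d(hidden, g * ka * ka, 1, rng=rng)

    def attention_weights(self, x: Tensor) -> Tensor:
        """Per-pixel, per-group softmax weights, shape (N, G, ka^2, H, W)."""
        cfg = self.cfg
        feats = self.conv_in(x)           # X; queries and keys alike
        ks = self.key_conv(feats)         # static context
        logits = self.w_delta(self.w_theta(cat([ks, feats], axis=1)).relu())
        n, _, h, w = logits.shape
        logits = logits.reshape(n, cfg.groups, cfg.attn_kernel ** 2, h, w)
        return softmax(logits, axis=2)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        c, g, ka = cfg.channels, cfg.groups, cfg.attn_kernel
        feats = self.conv_in(x)
        ks = self.key_conv(feats)
        v = self.w_v(feats)
        logits = self.w_delta(self.w_theta(cat([ks, feats], axis=1)).relu())
        n, _, h, w = logits.shape
        attn = softmax(logits.reshape(n, g, ka * ka, h, w), axis=2)

        pad = ka // 2
        vp = v.reshape(n, g, c // g, h, w).pad2d(pad)
        dyn = None
        for idx, (dy, dx) in enumerate(
                (dy, dx) for dy in range(ka) for dx in range(ka)):
            shifted = vp[:, :, :, dy:dy + h, dx:dx + w]
            term = attn[:, :, idx:idx + 1] * shifted
            dyn = term if dyn is None else dyn + term
        return ks + dyn.reshape(n, c, h, w)


class MaeNet(Module):
    """4-channel input (RGB + vessel probability) -> 3-class logits."""

    def __init__(self, base_width: int = 64, depth: int = 4,
                 cot_groups: int = 4, key_kernel: int = 3, attn_kernel: int = 3,
                 plain: bool = False, decoder_attention: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()

        if plain:
            factory = lambda i, o: DoubleConv(i, o, rng=rng)
        else:
            def factory(i, o):
                return _ConvCotStage(i, o, cot_groups, key_kernel, attn_kernel, rng)
        # attention blocks sit in the encoder by default; optionally also in
        # the decoder stages
        dec_factory = factory if (decoder_attention and not plain) else None
        self.net = UNetScaffold(4, N_CLASSES, base_width, depth, factory,
                                rng=rng, dec_factory=dec_factory)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (class logits, penultimate features)."""
        return self.net(x)


class _ConvCotStage(Module):
    def __init__(self, in_ch, out_ch, groups, key_kernel, attn_kernel, rng):
        super().__init__()
        g = groups
        while out_ch % g:
            g //= 2
        self.conv = DoubleConv(in_ch, out_ch, rng=rng)
        self.cot = CotBlock(
            CotBlockConfig(out_ch, key_kernel=key_kernel, groups=max(g, 1),
                           attn_kernel=attn_kernel), rng=rng)

    def forward(self, x):
        return self.cot(self.conv(x))


def mae_forward(rgb: np.ndarray, vessel_prob: np.ndarray,
                model: MaeNet) -> tuple[np.ndarray, np.ndarray]:
    """Run a (3, H, W) RGB array + (1, H, W) vessel probability map.

    Returns (logits (3, H, W), penultimate features).
    """
    from ._nn import no_grad

    rgb = np.asarray(rgb, dtype=np.float32)
    vessel_prob = np.asarray(vessel_prob, dtype=np.float32)
    if rgb.shape[1:] != vessel_prob.shape[1:]:
        raise ValueError(
            f"misaligned inputs: rgb {rgb.shape} vs vessel {vessel_prob.shape}"
        )
    x = np.concatenate([rgb, vessel_prob], axis=0)[None]
    model.eval()
    with no_grad():
        logits, feats = model(Tensor(x))
    return logits.data[0], feats.data[0]


__all__ = [
    "N_CLASSES", "standard_attention", "CotBlockConfig", "CotBlock",
    "MaeNet", "mae_forward",
]
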