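"""Multi-source Feature Integration.

The vessel probability map is passed through the boundary-enhancing
activation F(x) = exp(-|x - 0.5|) - exp(-0.5), which peaks at probability 0.5
(vessel boundaries and micro-vessels) and vanishes at 0 and 1 (confident
background and thick-vessel interiors).  The enhanced map is fused with the
A/V logits and penultimate features by a light convolutional refinement head
whose final 1x1 convolution is zero-initialized, so at initialization the
head is an exact identity on the A/V logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm2d, Conv2d, Module, Tensor, cat, no_grad

ENHANCE_PEAK = 1.0 - float(np.exp(-0.5))


@dataclass
class EnhancedVesselMap:
    """Elementwise-enhanced vessel map; values lie in [0, 1 - e^-0.5]."""

    data: np.ndarray  # (1, H, W)

    def __post_init__(self):
        if self.data.min() < -1e-9 or self.data.max() > ENHANCE_PEAK + 1e-9:
            raise ValueError(
                f"enhanced map out of range [0, {ENHANCE_PEAK}]: "
                f"[{self.data.min()}, {self.data.max()}]"
            )


def vessel_enhance(p: np.ndarray) -> EnhancedVesselMap:
    """Apply F(x) = exp(-|x - 0.5|) - exp(-0.5) to a probability map."""
    p = np.asarray(p, dtype=np.float64)
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValueError(
            f"vessel_enhance expects probabilities in [0, 1], got range "
            f"[{p.min()}, {p.max()}] — pass the sigmoid output, not logits"
        )
    p = np.clip(p, 0.0, 1.0)
    out = np.exp(-np.abs(p - 0.5)) - np.exp(-0.5)
    if out.ndim == 2:
        out = out[None]
    return EnhancedVesselMap(data=out)


def vessel_enhance_t(p: Tensor) -> Tensor:
    """Differentiable version of :func:`vessel_enhance` for training graphs."""
    return (-(p - 0.5).abs()).exp() - float(np.exp(-0.5))


class FuseHead(Module):
    """Fuse A/V logits, features and the enhanced vessel map.

    ``mode="concat"`` (default): concat -> two 3x3 convs -> zero-initialized
    1x1 conv, added residually, so the head is an exact identity on the A/V
    logits at initialization.  ``mode="gate"``: elementwise multiplicative
    gating ``logits * (1 + g * enhanced)`` with a scalar gain ``g``
    initialized to zero (also an identity at init).
    """

    def __init__(self, feat_ch: int, n_classes: int = 3, hidden: int = 16,
                 mode: str = "concat", rng: np.random.Generator | None = None):
        super().__init__()
        if mode not in ("concat", "gate"):
            raise ValueError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        if mode == "concat":
            in_ch = n_classes + feat_ch + 1
            self.conv1 = Conv2d(in_ch, hidden, 3, rng=rng)
            self.bn1 = BatchNorm2d(hidden)
            self.conv2 = Conv2d(hidden, hidden, 3, rng=rng)
            self.conv3 = Conv2d(hidden, n_classes, 1, rng=rng, zero_init=True)
        else:
            gain = Tensor(np.zeros(1, dtype=np.float32))
            gain.requires_grad = True
            self.gain = gain

    def forward(self, av_logits: Tensor, av_features: Tensor,
                enhanced: Tensor) -> Tensor:
        shapes = {t.shape[2:] for t in (av_logits, av_features, enhanced)}
        if len(shapes) != 1:
            raise ValueError(f"misaligned fusion inputs: {sorted(shapes)}")
        if self.mode == "gate":
            return av_logits * (1.0 + self.gain * enhanced)
        x = cat([av_logits, av_features, enhanced], axis=1)
        x = self.bn1(self.conv1(x)).relu()
        x = self.conv2(x)
        return av_logits + self.conv3(x)


def fuse(av_logits: np.ndarray, av_features: np.ndarray,
         enhanced: EnhancedVesselMap, head: FuseHead) -> np.ndarray:
    """Array-level fusion: returns final (3, H, W) A/V logits."""
    head.eval()
    with no_grad():
        out = head(
            Tensor(np.asarray(av_logits, dtype=np.float32)[None]),
            Tensor(np.asarray(av_features, dtype=np.float32)[None]),
            Tensor(np.asarray(enhanced.data, dtype=np.float32)[None]),
        )
    return out.data[0]


__all__ = [
    "ENHANCE_PEAK", "EnhancedVesselMap", "vessel_enhance", "vessel_enhance_t",
    "FuseHead", "fuse",
]
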