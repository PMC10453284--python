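"""Multi-scale Vessel Extraction network.

A U-shaped encoder/decoder whose encoder stages are split-concat residual
blocks: a leading 1x1 convolution produces C channels that are split into
``n_subsets`` groups; each group after the first is concatenated with the
previous group's output and passed through a small 3x3 conv, so late groups
see an increasingly large receptive field.  The outputs are re-concatenated,
mixed by a 1x1 convolution and added to a (projected) shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import (
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    DoubleConv,
    Module,
    Sequential,
    Tensor,
    cat,
    maxpool2,
    upsample2x_bilinear,
)


@dataclass
class MveConfig:
    base_width: int = 64
    depth: int = 4
    n_subsets: int = 4
    kernel: int = 3

    def validate(self) -> None:
        if self.base_width % self.n_subsets:
            raise ValueError(
                f"base_width {self.base_width} not divisible by "
                f"n_subsets {self.n_subsets}"
            )
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")


class Res2NetBlock(Module):
    """Split-concat residual block (spatial size preserved)."""

    def __init__(self, in_ch: int, out_ch: int, n_subsets: int = 4,
                 kernel: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if out_ch % n_subsets:
            raise ValueError(
                f"out channels {out_ch} not divisible by n_subsets {n_subsets}"
            )
        self.n_subsets = n_subsets
        self.sub_ch = out_ch // n_subsets
        self.conv_in = ConvBNReLU(in_ch, out_ch, kernel=1, rng=rng)
        # F_i maps concat(u_i, y_{i-1}) of 2*C/s channels down to C/s
        self.fs = [ConvBNReLU(2 * self.sub_ch, self.sub_ch, kernel=kernel, rng=rng)
                   for _ in range(n_subsets - 1)]
        self.conv_out = Conv2d(out_ch, out_ch, 1, rng=rng)
        self.bn_out = BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.shortcut = Conv2d(in_ch, out_ch, 1, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        u = self.conv_in(x)
        s, c = self.n_subsets, self.sub_ch
        subsets = [u[:, i * c:(i + 1) * c] for i in range(s)]
        ys = [subsets[0]]
        for i in range(1, s):
            ys.append(self.fs[i - 1](cat([subsets[i], ys[-1]], axis=1)))
        out = self.bn_out(self.conv_out(cat(ys, axis=1)))
        res = x if self.shortcut is None else self.shortcut(x)
        return (out + res).relu()

    def split_path_param_count(self) -> int:
        """Parameters of the cascaded small convolutions (weights only)."""
        return sum(int(np.prod(f.conv.weight.shape)) for f in self.fs)


class _Up(Module):
    """Bilinear 2x up-sampling followed by a channel-halving 1x1 conv."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv = ConvBNReLU(in_ch, out_ch, kernel=1, rng=rng)

    def forward(self, x):
        return self.conv(upsample2x_bilinear(x))


class UNetScaffold(Module):
    """Shared U-shaped scaffold; the encoder stage factory is pluggable."""

    def __init__(self, in_ch: int, out_ch: int, base_width: int, depth: int,
                 stage_factory, rng=None, dec_factory=None):
        super().__init__()
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.depth = depth
        self.enc = []
        prev = in_ch
        for wdt in widths[:-1]:
            self.enc.append(stage_factory(prev, wdt))
            prev = wdt
        self.bottleneck = stage_factory(prev, widths[-1])
        if dec_factory is None:
            dec_factory = lambda i, o: DoubleConv(i, o, rng=rng)
        self.ups = []
        self.dec = []
        for i in reversed(range(depth)):
            self.ups.append(_Up(widths[i + 1], widths[i], rng=rng))
            self.dec.append(dec_factory(2 * widths[i], widths[i]))
        self.head = Conv2d(base_width, out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (head output, penultimate features)."""
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^depth={div}; "
                "pad or resize the input first"
            )
        skips = []
        for stage in self.enc:
            x = stage(x)
            skips.append(x)
            x = maxpool2(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x)
            x = dec(cat([skip, x], axis=1))
        return self.head(x), x


class MveNet(Module):
    """1-channel vessel input -> per-pixel vessel probability."""

    def __init__(self, cfg: MveConfig | None = None, plain: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or MveConfig()
        cfg.validate()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        if plain:
            factory = lambda i, o: DoubleConv(i, o, rng=rng)
        else:
            factory = lambda i, o: Res2NetBlock(i, o, cfg.n_subsets, cfg.kernel,
                                                rng=rng)
        self.net = UNetScaffold(1, 1, cfg.base_width, cfg.depth, factory, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        logits, _ = self.net(x)
        return logits.sigmoid()


def mve_forward(vessel_input: np.ndarray, model: MveNet) -> np.ndarray:
    """Run an un-batched (1, H, W) input through the network."""
    from ._nn import no_grad

    model.eval()
    with no_grad():
        out = model(Tensor(vessel_input[None].astype(np.float32)))
    return out.data[0]


__all__ = ["MveConfig", "Res2NetBlock", "UNetScaffold", "MveNet", "mve_forward"]
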