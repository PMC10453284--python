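"""Neural-network layers built on the autograd engine (NCHW convention)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, cat, conv2d, maxpool2, upsample2x_bilinear


class Module:
    """Base class: recursive parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buf_owners: dict[str, tuple[Module, str]] = {}
        self._collect_buffer_owners("", buf_owners)
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(params[name].data.dtype).copy()
            elif name in buf_owners:
                owner, attr = buf_owners[name]
                setattr(owner, attr, value.copy())
            else:
                raise KeyError(f"unexpected key in state dict: {name}")

    def _collect_buffer_owners(self, prefix, out):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                out[prefix + name] = (self, name)
        for name, child in self._children():
            child._collect_buffer_owners(prefix + name + ".", out)


def _param(array: np.ndarray) -> Tensor:
    t = Tensor(np.ascontiguousarray(array, dtype=np.float32))
    t.requires_grad = True
    return t


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"channels ({in_ch}->{out_ch}) not divisible by groups={groups}")
        if kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {kernel}")
        self.groups = groups
        self.padding = kernel // 2
        fan_in = (in_ch // groups) * kernel * kernel
        rng = rng or np.random.default_rng()
        if zero_init:
            w = np.zeros((out_ch, in_ch // groups, kernel, kernel))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (out_ch, in_ch // groups, kernel, kernel))
        self.weight = _param(w)
        self.bias = _param(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding,
                      groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2(x)


class Upsample2x(Module):
    """Bilinear 2x up-sampling."""

    def forward(self, x: Tensor) -> Tensor:
        return upsample2x_bilinear(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel=3, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.act = ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class DoubleConv(Module):
    """Two 3x3 conv + BN + ReLU layers (plain U-Net stage)."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        self.block = Sequential(
            ConvBNReLU(in_ch, out_ch, rng=rng),
            ConvBNReLU(out_ch, out_ch, rng=rng),
        )

    def forward(self, x):
        return self.block(x)


__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid", "MaxPool2",
    "Upsample2x", "Sequential", "ConvBNReLU", "DoubleConv", "Tensor", "cat",
]
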