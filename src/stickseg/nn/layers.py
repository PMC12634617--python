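"""Layer modules built on :mod:`stickseg.nn.tensor`.

Follows the familiar module idiom: a :class:`Module` owns parameters and
sub-modules discovered through its attributes, exposes ``parameters()``,
``train()`` / ``eval()`` and a trainable-parameter count.
"""

from __future__ import annotations

import numpy as np

from .tensor import (Tensor, avg_pool2d, batch_norm, conv2d, max_pool2d,
                     upsample2d)

__all__ = ["Module", "ModuleList", "Sequential", "Parameter", "Conv2d",
           "BatchNorm2d", "ReLU", "DynamicReLU", "Sigmoid", "MaxPool2d",
           "AvgPool2d", "Upsample", "SpatialDropout2d", "Identity"]


def Parameter(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- discovery ----------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        """Total number of trainable weight elements."""
        return int(sum(p.size for p in self.parameters()))

    # -- mode ---------------------------------------------------------------
    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=params[k].data.dtype)
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unexpected state entry {k!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Conv2d(Module):
    """2-D convolution; He-normal initialisation, optional channel groups."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 groups: int = 1, bias: bool = True, seed: int | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide in={in_channels} and out={out_channels}")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        rng = np.random.default_rng(seed)
        fan_in = in_channels // groups * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels // groups, kernel, kernel))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) \
            if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training, self.momentum,
                          self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class DynamicReLU(Module):
    """Channel-gated rectifier: ``y = relu(x) * (a_c + b_c * sigmoid(gap_c))``.

    ``a`` initialised to 1 and ``b`` to 0, so a fresh module behaves exactly
    like a plain ReLU; training lets each channel learn an input-conditioned
    slope.  2C trainable parameters.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.a = Parameter(np.ones(channels, dtype=np.float32))
        self.b = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        gap = x.mean(axis=(2, 3), keepdims=True)          # N,C,1,1
        gate = self.a.reshape(1, -1, 1, 1) + \
            self.b.reshape(1, -1, 1, 1) * gap.sigmoid()
        return x.relu() * gate


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return avg_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale: int = 2, mode: str = "bilinear"):
        super().__init__()
        self.scale, self.mode = scale, mode

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        return upsample2d(x, (h * self.scale, w * self.scale), self.mode)


class SpatialDropout2d(Module):
    """Zeroes whole feature channels with probability ``p`` while training,
    rescaling survivors by 1/(1-p); identity in evaluation mode."""

    def __init__(self, p: float, seed: int | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        n, c = x.shape[0], x.shape[1]
        keep = (self.rng.random((n, c, 1, 1)) >= self.p)
        mask = keep.astype(np.float32) / (1.0 - self.p)
        return x * Tensor(mask)


class Identity(Module):
    def forward(self, x):
        return x
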