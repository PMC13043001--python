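"""Parameter-holding layers on top of the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: recursive parameter discovery + state (de)serialization."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def named_state(self, prefix=""):
        out = {}
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[name] = v.data
            elif isinstance(v, Module):
                out.update(v.named_state(name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_state(f"{name}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{name}.{i}"] = item.data
        return out

    def load_state(self, state, prefix=""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[name], dtype=v.data.dtype).reshape(v.shape)
            elif isinstance(v, Module):
                v.load_state(state, name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, f"{name}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.asarray(
                            state[f"{name}.{i}"], dtype=item.data.dtype
                        ).reshape(item.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming(rng, shape, fan_in, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=None, dilation=1,
                 groups=1, bias=True):
        if padding is None:
            padding = dilation * (k - 1) // 2
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        fan_in = (cin // groups) * k * k
        self.weight = Tensor(
            kaiming(rng, (cout, cin // groups, k, k), fan_in), requires_grad=True
        )
        self.bias = (
            Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)


class DepthwiseSeparableConv(Module):
    """3x3 depthwise + 1x1 pointwise, bias-free (preserves zeros)."""

    def __init__(self, c, rng, k=3):
        self.dw = Conv2d(c, c, k, rng, groups=c, bias=False)
        self.pw = Conv2d(c, c, 1, rng, bias=False)

    def forward(self, x):
        return self.pw(T.relu(self.dw(x)))


class LayerNormChannels(Module):
    """LayerNorm over the channel axis of NCHW feature maps."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Tensor(np.ones((1, c, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = T.reduce_mean(x, axis=1, keepdims=True)
        xc = x - mu
        var = T.reduce_mean(xc * xc, axis=1, keepdims=True)
        inv = T.power(var + self.eps, -0.5)
        return xc * inv * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        return T.gelu(x)
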