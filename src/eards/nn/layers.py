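"""Neural-network modules on top of the autodiff tape.

The Module system mirrors the conventions of mainstream deep-learning
frameworks at a miniature scale: parameter registration by attribute
assignment, ``train()/eval()`` modes, flat ``state_dict`` of numpy arrays.

Every leaf layer also knows its own *analytic* complexity through
``macs(h, w)`` — multiply counts of its weight application at a given input
spatial size — which the profiler aggregates without running a forward pass.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_children(self):
        return list(self._children.items())

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for cn, child in self._children.items():
            yield from child.named_parameters(prefix + cn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization -------------------------------------------------------
    def state_dict(self, prefix: str = "", out: dict | None = None) -> dict:
        out = {} if out is None else out
        for n, p in self._params.items():
            out[prefix + n] = p.data
        for n, b in self._buffers.items():
            out[prefix + n] = b
        for cn, child in self._children.items():
            child.state_dict(prefix + cn + ".", out)
        return out

    def load_state_dict(self, state: dict, strict: bool = True):
        own = self.state_dict()
        missing = [k for k in own if k not in state]
        if strict and missing:
            raise KeyError(f"missing keys in state dict: {missing[:5]}...")
        for n, p in self._params.items():
            key = self._find_key(state, n)
            if key is not None:
                if state[key].shape != p.data.shape:
                    raise ValueError(
                        f"shape mismatch for '{n}': {state[key].shape} vs {p.data.shape}")
                p.data = np.asarray(state[key], dtype=np.float32)
        for n in list(self._buffers):
            key = self._find_key(state, n)
            if key is not None:
                self._set_buffer(n, np.asarray(state[key]))
        for cn, child in self._children.items():
            sub = {k[len(cn) + 1:]: v for k, v in state.items() if k.startswith(cn + ".")}
            child.load_state_dict(sub, strict=strict)

    @staticmethod
    def _find_key(state, name):
        return name if name in state else None

    # -- interface -----------------------------------------------------------
    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def macs(self, h: int, w: int):
        """Return (mac_count, (out_h, out_w)) for an input of spatial size h x w."""
        raise NotImplementedError(type(self).__name__)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = [f"m{i}" for i in range(len(mods))]

    def __iter__(self):
        return iter(self._children[n] for n in self._order)

    def forward(self, x):
        for m in self:
            x = m(x)
        return x

    def macs(self, h, w):
        total = 0
        for m in self:
            c, (h, w) = m.macs(h, w)
            total += c
        return total, (h, w)


class Identity(Module):
    def forward(self, x):
        return x

    def macs(self, h, w):
        return 0, (h, w)


def _kaiming(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """k x k convolution, 'same' padding unless overridden, optional bias.

    ``bias`` defaults to False: in this codebase convolutions are always
    followed by a normalization layer unless stated otherwise.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = False):
        super().__init__()
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_out = out_ch * k * k
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, k, k), fan_out))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        if self.k == 1 and self.stride == 1:
            w2 = T.reshape(self.weight, (self.out_ch, self.in_ch))
            return T.conv1x1(x, w2, self.bias)
        return T.conv2d(x, self.weight, stride=self.stride, padding=self.padding,
                        b=self.bias)

    def macs(self, h, w):
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return self.k * self.k * self.in_ch * self.out_ch * ho * wo, (ho, wo)


class DepthwiseConv2d(Module):
    def __init__(self, rng, ch: int, k: int = 3, stride: int = 1):
        super().__init__()
        self.ch, self.k, self.stride = ch, k, stride
        self.padding = (k - 1) // 2
        self.weight = Parameter(_kaiming(rng, (ch, k, k), k * k))

    def forward(self, x):
        return T.depthwise_conv(x, self.weight, stride=self.stride,
                                padding=self.padding)

    def macs(self, h, w):
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return self.k * self.k * self.ch * ho * wo, (ho, wo)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))

    def forward(self, x):
        if self.training:
            out, bm, bv = T.batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self._set_buffer("running_mean",
                             ((1 - m) * self.running_mean + m * bm).astype(np.float32))
            self._set_buffer("running_var",
                             ((1 - m) * self.running_var + m * bv).astype(np.float32))
            return out
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * invstd
        shift = self.beta.data - self.running_mean * scale
        out = T.affine_channels(x, scale.astype(np.float32), shift.astype(np.float32))
        # re-route gradients to gamma/beta in eval mode is unnecessary for
        # this codebase (training always uses batch statistics)
        return out

    def macs(self, h, w):
        return 0, (h, w)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(_kaiming(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)

    def macs(self, h, w):
        return self.in_f * self.out_f, (h, w)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)

    def macs(self, h, w):
        return 0, (h, w)


class Swish(Module):
    def forward(self, x):
        return T.swish(x)

    def macs(self, h, w):
        return 0, (h, w)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)

    def macs(self, h, w):
        return 0, (h, w)


class UpsampleBilinear(Module):
    """Scale spatial size by an integer factor with bilinear interpolation."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        _, _, h, w = x.shape
        return T.upsample_bilinear(x, h * self.factor, w * self.factor)

    def macs(self, h, w):
        return 0, (h * self.factor, w * self.factor)
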