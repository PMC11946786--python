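"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters require grad even under no_grad


def _init_weight(rng: np.random.Generator, shape, fan_in: int, zero: bool = False):
    if zero:
        return np.zeros(shape, dtype=np.float32)
    std = 1.0 / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    @staticmethod
    def _walk(value, kind):
        """Yield every instance of ``kind`` in a value, recursing into
        arbitrarily nested lists/tuples and into sub-modules."""
        if isinstance(value, kind):
            yield value
        if isinstance(value, Module):
            for v in vars(value).values():
                yield from Module._walk(v, kind)
        elif isinstance(value, (list, tuple)):
            for item in value:
                yield from Module._walk(item, kind)

    def modules(self):
        yield from Module._walk(self, Module)

    def parameters(self) -> list[Parameter]:
        seen, out = set(), []
        for p in Module._walk(self, Parameter):
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = state[str(i)]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float32).copy()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 bias=True, rng=None, zero_init=False):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(
            _init_weight(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in, zero_init)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride, bias=True, rng=None, zero_init=False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(
            _init_weight(rng, (in_ch, out_ch, kernel, kernel), in_ch * kernel * kernel, zero_init)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride = stride

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class DepthwiseConv2d(Conv2d):
    """k×k depth-wise convolution, zero padding (k-1)//2, shape preserving."""

    def __init__(self, channels, kernel, rng=None, zero_init=False):
        super().__init__(channels, channels, kernel, stride=1, padding=(kernel - 1) // 2,
                         groups=channels, rng=rng, zero_init=zero_init)


class Linear(Module):
    def __init__(self, in_dim, out_dim, bias=True, rng=None, zero_init=False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(_init_weight(rng, (in_dim, out_dim), in_dim, zero_init))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of (B, C, H, W) maps."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))
        self.eps = eps

    def forward(self, x):
        return F.layer_norm(x, self.gamma, self.beta, axis=1, eps=self.eps)
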