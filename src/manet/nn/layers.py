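"""Neural-network layer modules on top of the autodiff tensor core."""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor, DEFAULT_DTYPE


class Parameter(Tensor):
    """Trainable tensor (requires_grad always on)."""

    def __init__(self, data, name=None):
        super().__init__(np.asarray(data), requires_grad=True, name=name)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in, dtype=DEFAULT_DTYPE):
    """Kaiming-uniform fan-in init, leaky-ReLU flavor (a = sqrt(5)): the
    standard convolution default in the major frameworks; bound 1/sqrt(fan_in)."""
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Minimal module base: parameter discovery, train/eval mode, zeroing."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{k}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{prefix}{k}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        state = {k: p.data for k, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean
                state[f"{name}.running_var"] = m.running_var
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"]).copy()
                m.running_var = np.asarray(state[f"{name}.running_var"]).copy()

    def _named_modules(self, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield f"{prefix}{k}", v
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{prefix}{k}.{i}", item
                        yield from item._named_modules(f"{prefix}{k}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=None,
                 bias=True, rng=None, dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = int(kernel_size)
        self.stride = int(stride)
        self.padding = k // 2 if padding is None else int(padding)
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, k
        fan_in = in_channels * k * k
        self.weight = Parameter(kaiming_uniform(rng, (out_channels, in_channels, k, k), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution with kernel == stride (non-overlapping taps)."""

    def __init__(self, in_channels, out_channels, kernel_size=2, stride=2,
                 bias=True, rng=None, dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = int(kernel_size)
        self.stride = int(stride)
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, k
        fan_in = in_channels * k * k
        self.weight = Parameter(kaiming_uniform(rng, (in_channels, out_channels, k, k), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x):
        return T.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.num_features = num_features
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features, dtype=dtype))
        self.bias = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def forward(self, x):
        return T.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=False, rng=None, dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(kaiming_uniform(rng, (in_features, out_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x):
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = T.add(out, self.bias)
        return out
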