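"""Layer abstractions over the autodiff tensor: Module, Conv2d, BatchNorm2d, Linear."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "Linear", "Identity", "Sequential"]


class Parameter(Tensor):
    """A trainable tensor; discovered by Module.parameters()."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even inside no_grad


class Module:
    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        seen = set()
        stack = [self]
        while stack:
            mod = stack.pop()
            for v in vars(mod).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return out

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_parameters(f"{prefix}{name}.{i}.")

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=np.float64)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.array(state[f"{name}.running_mean"], dtype=np.float64)
                m.running_var = np.array(state[f"{name}.running_var"], dtype=np.float64)

    def _named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m._named_modules(f"{prefix}{name}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        bound = math.sqrt(2.0 / fan_in)  # He init for SiLU/ReLU stacks
        self.weight = Parameter(rng.normal(0.0, bound, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.03, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = F.batch_norm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return out
        dt = x.data.dtype
        mu = self.running_mean.reshape(1, -1, 1, 1).astype(dt)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1).astype(dt)
        g = self.gamma.reshape(1, self.num_features, 1, 1)
        b = self.beta.reshape(1, self.num_features, 1, 1)
        return (x - mu) * (inv * g) + b


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, bound, size=(out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        return y if self.bias is None else y + self.bias


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
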