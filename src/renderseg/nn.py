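"""Neural-network building blocks and the AdamW optimiser.

Thin module system over :mod:`renderseg.autograd`: parameters are tensors
with ``requires_grad=True``; modules expose ``parameters()`` and a flat,
dotted-name ``state_dict()`` used by checkpointing.  Initialisation draws
from a caller-supplied ``numpy.random.Generator`` so every weight in the
network is reproducible from one seed; no global random state is touched.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples redrawn until within 2 std (ViT-style init)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, (Parameter, Module)):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, child in self._children():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            else:
                yield from child.named_parameters(prefix=full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            if isinstance(child, Module):
                yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- persistence ----------------------------------------------------
    def _buffers(self):
        """Override to expose non-trainable arrays (e.g. running stats)."""
        return {}

    def named_buffers(self, prefix: str = ""):
        for name, arr in self._buffers().items():
            yield f"{prefix}{name}", arr
        for name, child in self._children():
            if isinstance(child, Module):
                yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: arr.copy() for name, arr in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing entries: {sorted(missing)[:5]}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data[...] = state[name]
        for name, arr in buffers.items():
            arr[...] = state[name]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = truncated_normal(rng, (in_features, out_features),
                                 std=in_features ** -0.5)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            truncated_normal(rng, (out_ch, in_ch, kernel, kernel), std=fan_in ** -0.5))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel.

    Training mode normalises with batch statistics and updates running
    estimates; eval mode uses the running estimates, which makes small
    fixed-weight examples deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        shape = (1, C, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            inv = (var + self.eps) ** -0.5
            out = centered * inv
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            inv = Tensor(1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps))
            out = (x - mu) * inv
        return out * self.gamma.reshape(shape) + self.beta.reshape(shape)


class PReLU(Module):
    """Parametric ReLU with one learnable slope per channel (channel axis 1)."""

    def __init__(self, channels: int = 1, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.full(channels, init))

    def forward(self, x: Tensor) -> Tensor:
        pos = x.relu()
        neg = x - pos                       # min(x, 0)
        shape = [1] * x.ndim
        if len(self.slope.data) > 1:
            shape[1] = len(self.slope.data)
        return pos + self.slope.reshape(shape) * neg


class AdamW:
    """Decoupled-weight-decay Adam (default hyper-parameters)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        state = {f"m.{i}": m.copy() for i, m in enumerate(self.m)}
        state.update({f"v.{i}": v.copy() for i, v in enumerate(self.v)})
        state["t"] = np.array(self.t)
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for i in range(len(self.m)):
            self.m[i][...] = state[f"m.{i}"]
            self.v[i][...] = state[f"v.{i}"]
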