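"""Neural-network layers and optimization on top of :mod:`scprofile.autodiff`.

Provides the building blocks for the tiny sequence encoder and the
hypernetwork decoder: linear and 1-D convolution layers, batch/layer
normalization, single-head self-attention, a feed-forward block, and an AdamW
optimizer with global-norm gradient clipping. Modules follow a
``named_modules`` / ``named_parameters`` discipline so that adapter injection
can address submodules by path (e.g. ``"blocks.0.attn.q_proj"``).
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-discovered parameters and submodules."""

    def __init__(self):
        self.training = True

    # -- discovery ---------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, val in vars(self).items():
            path = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Module):
                yield from val.named_modules(path)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{path}.{i}")

    def named_parameters(self, prefix: str = ""):
        for mod_path, mod in self.named_modules(prefix):
            for name, val in vars(mod).items():
                if isinstance(val, Parameter):
                    yield (f"{mod_path}.{name}" if mod_path else name), val

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.size for p in self.parameters()
            if (p.requires_grad or not trainable_only)
        )

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for mod_path, mod in self.named_modules():
            for name, val in vars(mod).items():
                if name.startswith("running_") and isinstance(val, np.ndarray):
                    key = f"{mod_path}.{name}" if mod_path else name
                    out[key] = val.copy()
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, arr in state.items():
            if key in params:
                params[key].data = np.asarray(arr).astype(ad.DTYPE)
            else:
                mod_path, _, name = key.rpartition(".")
                mods = dict(self.named_modules())
                if mod_path in mods and name.startswith("running_"):
                    setattr(mods[mod_path], name, np.asarray(arr).astype(np.float64))
                else:
                    raise KeyError(f"unknown state entry {key!r}")
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        std = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(d_out, d_in)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.T
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1d(Module):
    """Same-padded 1-D convolution on (L, C_in) inputs, weight (C_out, k*C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride = stride
        std = 1.0 / math.sqrt(c_in * kernel)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, kernel * c_in)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias, pad="same",
                         stride=self.stride)


class BatchNorm1d(Module):
    """Normalizes each channel over positions; running stats for eval mode.

    ``frozen=True`` uses running statistics even in training mode (the
    stabilization phase at the start of fine-tuning).
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.frozen = False

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.frozen:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return ad.batch_norm(x, self.gamma, self.beta, self.eps)
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ad.power(v + self.eps, -0.5) * self.gamma + self.beta


class SelfAttention(Module):
    """Multi-head scaled dot-product self-attention over positions."""

    def __init__(self, d: int, rng: np.random.Generator, n_heads: int = 4):
        super().__init__()
        if d % n_heads:
            raise ValueError(f"channels {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.out_proj = Linear(d, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        L = x.shape[0]
        h, dh = self.n_heads, self.d // self.n_heads
        # (L, d) -> (h, L, dh)
        def split(t):
            return t.reshape((L, h, dh)).transpose(1, 0, 2)

        q, k, v = (split(p(x)) for p in (self.q_proj, self.k_proj, self.v_proj))
        att = ad.softmax((q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(dh)),
                         axis=-1)
        out = (att @ v).transpose(1, 0, 2).reshape((L, self.d))
        return self.out_proj(out)


class FeedForward(Module):
    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class Dropout(Module):
    """Inverted dropout; inert in eval mode or when disabled."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng
        self.enabled = True

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or not self.enabled or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class TransformerBlock(Module):
    def __init__(self, d: int, rng: np.random.Generator, ff_mult: int = 2,
                 dropout: float = 0.0, n_heads: int = 4):
        super().__init__()
        self.ln1 = LayerNorm(d)
        self.attn = SelfAttention(d, rng, n_heads)
        self.ln2 = LayerNorm(d)
        self.mlp = FeedForward(d, ff_mult * d, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)))
        x = x + self.drop(self.mlp(self.ln2(x)))
        return x


class MLP(Module):
    """Plain feed-forward stack with GELU between layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.gelu(x)
        return x


# -- optimization ----------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay and per-group learning rates.

    ``groups`` is a list of dicts: {"params": [...], "lr": float}.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-6):
        self.groups = [
            {"params": list(g["params"]), "lr": float(g["lr"]),
             "base_lr": float(g["lr"])}
            for g in groups
        ]
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {}
        self._v = {}

    def set_lr_scale(self, scale: float):
        for g in self.groups:
            g["lr"] = g["base_lr"] * scale

    def clip_grad_norm(self, max_norm: float) -> float:
        params = [p for g in self.groups for p in g["params"] if p.grad is not None]
        total = math.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                              for p in params))
        if not math.isfinite(total):
            # skip the step entirely on a non-finite gradient
            for p in params:
                p.grad = None
            return total
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in params:
                p.grad *= scale
        return total

    def step(self):
        self.t += 1
        for g in self.groups:
            for p in g["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                m, v = self._m[key], self._v[key]
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad ** 2
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p.data -= g["lr"] * (
                    mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
                )

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()
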