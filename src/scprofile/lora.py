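"""Low-rank adaptation (LoRA) of linear and convolutional layers.

A LoRA adapter adds a trainable low-rank delta to a frozen base weight:
``W_eff = W + (alpha / r) * B @ A`` with ``A`` (r x d_in) Gaussian-initialized
and ``B`` (d_out x r) zero-initialized, so the adapted layer is exactly the
base layer at initialization. After training the delta can be merged into the
base weight, removing all inference overhead.

Injection addresses submodules by dotted path with ``fnmatch``-style patterns,
e.g. ``["*.attn.q_proj", "*.attn.v_proj", "*.mlp.*", "*conv*"]``.
"""

from __future__ import annotations

import fnmatch

import numpy as np

from . import autodiff as ad
from .nn import Conv1d, Linear, Module, Parameter

DEFAULT_RANK = 8


class LoRALinear(Module):
    def __init__(self, base: Linear, r: int, alpha: float, rng: np.random.Generator):
        super().__init__()
        self.base = base
        self.r = r
        self.alpha = alpha
        base.weight.requires_grad = False
        if base.bias is not None:
            base.bias.requires_grad = False
        self.lora_A = Parameter(rng.normal(0.0, 1.0 / r, size=(r, base.d_in)))
        self.lora_B = Parameter(np.zeros((base.d_out, r)))

    def forward(self, x):
        y = self.base(x)
        delta = (x @ self.lora_A.T) @ self.lora_B.T
        return y + delta * (self.alpha / self.r)

    def merged_weight(self) -> np.ndarray:
        return self.base.weight.data + (self.alpha / self.r) * (
            self.lora_B.data @ self.lora_A.data
        )


class LoRAConv1d(Module):
    """LoRA on the flattened (C_out, k*C_in) convolution weight."""

    def __init__(self, base: Conv1d, r: int, alpha: float, rng: np.random.Generator):
        super().__init__()
        self.base = base
        self.r = r
        self.alpha = alpha
        base.weight.requires_grad = False
        base.bias.requires_grad = False
        d_in = base.kernel * base.c_in
        self.lora_A = Parameter(rng.normal(0.0, 1.0 / r, size=(r, d_in)))
        self.lora_B = Parameter(np.zeros((base.c_out, r)))

    def forward(self, x):
        w_eff = self.base.weight + (
            self.lora_B @ self.lora_A
        ) * (self.alpha / self.r)
        return ad.conv1d(x, w_eff, self.base.bias, pad="same",
                         stride=self.base.stride)

    def merged_weight(self) -> np.ndarray:
        return self.base.weight.data + (self.alpha / self.r) * (
            self.lora_B.data @ self.lora_A.data
        )


def _resolve(root: Module, path: str):
    """Return (owner, attr_name, index_or_None) for a dotted module path."""
    parts = path.split(".")
    obj = root
    for part in parts[:-1]:
        obj = obj[int(part)] if part.isdigit() and isinstance(obj, list) else (
            getattr(obj, part)
        )
    last = parts[-1]
    if last.isdigit() and isinstance(obj, list):
        return obj, None, int(last)
    return obj, last, None


def list_adaptable(encoder: Module) -> list[str]:
    """Dotted paths of every Linear/Conv1d eligible for adaptation."""
    out = []
    for path, mod in encoder.named_modules():
        if path and isinstance(mod, (Linear, Conv1d)):
            out.append(path)
    return out


def lora_sites(encoder: Module) -> list[str]:
    return [p for p, m in encoder.named_modules()
            if isinstance(m, (LoRALinear, LoRAConv1d))]


def inject_lora(encoder: Module, targets: list[str], r: int = DEFAULT_RANK,
                alpha: float | None = None, seed: int = 0) -> Module:
    """Wrap every submodule matching a target pattern with a LoRA adapter.

    Freezes the base weights of the wrapped layers; alpha defaults to r
    (scaling alpha/r = 1). Modifies the encoder in place and returns it.
    """
    if alpha is None:
        alpha = float(r)
    rng = np.random.default_rng(seed)
    available = list_adaptable(encoder)
    matched = [p for p in available
               if any(fnmatch.fnmatch(p, pat) for pat in targets)]
    if not matched:
        raise ValueError(
            f"no submodule matches {targets!r}; available: {available}"
        )
    for path in matched:
        owner, attr, idx = _resolve(encoder, path)
        base = owner[idx] if attr is None else getattr(owner, attr)
        wrapper_cls = LoRALinear if isinstance(base, Linear) else LoRAConv1d
        wrapped = wrapper_cls(base, r, alpha, rng)
        if attr is None:
            owner[idx] = wrapped
        else:
            setattr(owner, attr, wrapped)
    return encoder


def merge_lora(encoder: Module) -> Module:
    """Fold every adapter's low-rank delta into its base weight and strip
    the adapters. Raises if no adapters are present (e.g. double merge)."""
    sites = lora_sites(encoder)
    if not sites:
        raise ValueError("no LoRA adapters present (already merged?)")
    for path in sites:
        owner, attr, idx = _resolve(encoder, path)
        wrapper = owner[idx] if attr is None else getattr(owner, attr)
        base = wrapper.base
        base.weight.data = wrapper.merged_weight()
        base.weight.requires_grad = True
        if getattr(base, "bias", None) is not None:
            base.bias.requires_grad = True
        if attr is None:
            owner[idx] = base
        else:
            setattr(owner, attr, base)
    return encoder


def lora_parameters(encoder: Module):
    """All trainable adapter parameters (A and B matrices)."""
    out = []
    for path, mod in encoder.named_modules():
        if isinstance(mod, (LoRALinear, LoRAConv1d)):
            out.extend([mod.lora_A, mod.lora_B])
    return out
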