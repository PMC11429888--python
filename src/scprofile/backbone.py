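"""Sequence encoder: contract, tiny trainable implementation, head, cache.

A sequence encoder maps a one-hot DNA window of length L (divisible by 32)
to an embedding of L/32 bins x D channels. The full-scale setting uses
L = 524,288 bp and D = 1,920 channels with predictions made for the center
6,144 bins (196,608 bp); the desk-scale default is L = 8,192 bp (256 bins)
with D = 64, which the rest of the package treats identically (the decoder
derives all shapes from D).

``TinyBackbone`` is a small convolution + transformer encoder trained from
random initialization. It is the package's own encoder, exposing the same
adaptation surface (convolutions; attention query/value projections; MLP
projections) so low-rank adapters and the trainable GELU head behave exactly
as they would on a large pretrained encoder.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm1d, Conv1d, Linear, Module, TransformerBlock
from .sequence import digest, one_hot

BIN_WIDTH = 32
PAPER_INPUT_LENGTH = 524_288
PAPER_CROP_BINS = 6_144
PAPER_CHANNELS = 1_920
CHECKPOINT_FORMAT_VERSION = 1


def crop_margins(n_bins: int, crop_to: int) -> int:
    """Bins to trim from each side for a center crop; errors on odd trim."""
    if crop_to > n_bins:
        raise ValueError(f"cannot crop {n_bins} bins to {crop_to}")
    trim = n_bins - crop_to
    if trim % 2:
        raise ValueError(f"asymmetric crop: {n_bins} -> {crop_to} trims {trim} bins")
    return trim // 2


@dataclass(frozen=True)
class EncoderConfig:
    input_length: int = 8192
    channels: int = 64
    n_transformer_layers: int = 2
    n_heads: int = 4
    conv_kernel: int = 5
    stem_kernel: int = 15
    dropout: float = 0.0
    norm: str = "layer"  # conv-stack normalization: "layer" | "batch"
    head_channels: int | None = None  # defaults to `channels`
    seed: int = 0

    def __post_init__(self):
        if self.input_length % BIN_WIDTH:
            raise ValueError(
                f"input length {self.input_length} not divisible by {BIN_WIDTH}"
            )

    @property
    def n_bins(self) -> int:
        return self.input_length // BIN_WIDTH

    @property
    def out_channels(self) -> int:
        return self.head_channels or self.channels


def _sinusoidal_positions(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angles = pos / (10000.0 ** (2 * (i // 2) / d))
    enc = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return enc


class TinyBackbone(Module):
    """Conv + transformer encoder at 32-bp resolution (trainable from scratch).

    Three convolution stages (pool 4 x 4 x 2 = 32) bring base-pair input to
    bin resolution; transformer blocks then mix information across bins.
    """

    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = config.channels
        # channel-wise LayerNorm preserves per-window occupancy signal
        # (how many positions fire) that whole-window statistics erase
        from .nn import LayerNorm

        norm_cls = LayerNorm if config.norm == "layer" else BatchNorm1d
        self.conv_stem = Conv1d(4, D, config.stem_kernel, rng, stride=4)
        self.bn_stem = norm_cls(D)
        self.conv_tower = [Conv1d(D, D, config.conv_kernel, rng) for _ in range(2)]
        self.bn_tower = [norm_cls(D) for _ in range(2)]
        self.blocks = [
            TransformerBlock(D, rng, dropout=config.dropout,
                             n_heads=config.n_heads)
            for _ in range(config.n_transformer_layers)
        ]
        # global-context pathways: an additive residual and a
        # multiplicative (FiLM-style) gate let per-bin amplitude scale
        # with window-wide features such as total motif dosage
        self.global_proj = Linear(D, D, rng)
        self.global_gate = Linear(D, D, rng)
        self.global_gate.weight.data *= 0.1  # gate starts near identity

    # -- SequenceEncoder contract -----------------------------------------
    @property
    def input_length(self) -> int:
        return self.config.input_length

    @property
    def n_bins(self) -> int:
        return self.config.input_length // BIN_WIDTH

    @property
    def out_channels(self) -> int:
        return self.config.channels

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[0] % BIN_WIDTH:
            raise ValueError(f"sequence length {x.shape[0]} not divisible by 32")
        h = ad.gelu(self.bn_stem(self.conv_stem(x)))  # stride-4 stem -> L/4
        for conv, bn, pool in zip(self.conv_tower, self.bn_tower, (4, 2)):
            h = ad.gelu(bn(conv(h)))
            h = ad.avg_pool(h, pool)
        h = h + Tensor(_sinusoidal_positions(h.shape[0], h.shape[1]))
        for block in self.blocks:
            h = block(h)
        g = h.mean(axis=0, keepdims=True)
        h = h + ad.gelu(self.global_proj(g))
        h = h * (1.0 + ad.ttanh(self.global_gate(g)))
        return h

    def set_stabilization(self, on: bool) -> None:
        """Phase switch: freeze batch-norm statistics and disable dropout
        while ``on`` (the stabilization phase at the start of fine-tuning)."""
        from .nn import Dropout

        for _, m in self.named_modules():
            if isinstance(m, BatchNorm1d):
                m.frozen = on
            if isinstance(m, Dropout):
                m.enabled = not on


class PointwiseHead(Module):
    """Per-position affine map D_raw -> D_out followed by GELU, trained from
    random initialization (refines the encoder embedding for the single-cell
    setting). Applied independently per bin."""

    def __init__(self, d_in: int, d_out: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.proj = Linear(d_in, d_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return ad.gelu(self.proj(x))


class EmbeddingCache:
    """LRU cache keyed by (sequence digest, shift, orientation).

    A hit returns the stored array object, bitwise-identical to the fresh
    forward pass that produced it (eval-mode forwards are deterministic).
    """

    def __init__(self, capacity: int = 8):
        self.capacity = capacity
        self._store: OrderedDict = OrderedDict()
        self.hits = 0
        self.misses = 0

    def get(self, key):
        if key in self._store:
            self._store.move_to_end(key)
            self.hits += 1
            return self._store[key]
        self.misses += 1
        return None

    def put(self, key, value) -> None:
        self._store[key] = value
        self._store.move_to_end(key)
        while len(self._store) > self.capacity:
            self._store.popitem(last=False)


def encode(encoder: Module, seq, crop_to: int | None = None,
           head: PointwiseHead | None = None,
           cache: EmbeddingCache | None = None,
           shift: int = 0, orientation: str = "fwd") -> np.ndarray:
    """Eval-mode embedding of a sequence, center-cropped to ``crop_to`` bins.

    ``seq`` may be a string or a one-hot array. Results are cached by
    (digest, shift, orientation) when a cache is supplied.
    """
    import hashlib

    if isinstance(seq, str):
        key = (digest(seq), shift, orientation)
        x = one_hot(seq)
    else:
        x = np.asarray(seq, dtype=np.float64)
        key = (hashlib.sha1(np.ascontiguousarray(x).tobytes()).hexdigest(),
               shift, orientation)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    was_training = encoder.training
    encoder.eval()
    emb = encoder(Tensor(x))
    if head is not None:
        head.eval()
        emb = head(emb)
    out = emb.data
    if crop_to is not None:
        m = crop_margins(out.shape[0], crop_to)
        if m:
            out = out[m:-m]
    if was_training:
        encoder.train()
    if cache is not None:
        cache.put(key, out)
    return out


# -- checkpointing -----------------------------------------------------------

def save_encoder(path, encoder: TinyBackbone, head: PointwiseHead | None = None,
                 extra_state: dict | None = None) -> None:
    """Single-file archive: config JSON + all weights + format version."""
    payload = {
        "__format_version__": np.array(CHECKPOINT_FORMAT_VERSION),
        "__config__": np.frombuffer(
            json.dumps(asdict(encoder.config)).encode(), dtype=np.uint8
        ),
    }
    for k, v in encoder.state_dict().items():
        payload[f"encoder/{k}"] = v
    if head is not None:
        for k, v in head.state_dict().items():
            payload[f"head/{k}"] = v
    for k, v in (extra_state or {}).items():
        payload[f"extra/{k}"] = v
    np.savez(path, **payload)


def load_encoder(path):
    """Returns (encoder, head-or-None, extra_state dict)."""
    with np.load(path) as z:
        version = int(z["__format_version__"])
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {version}")
        config = EncoderConfig(**json.loads(bytes(z["__config__"]).decode()))
        encoder = TinyBackbone(config)
        enc_state = {k[len("encoder/"):]: z[k] for k in z.files
                     if k.startswith("encoder/")}
        encoder.load_state_dict(enc_state)
        head_state = {k[len("head/"):]: z[k] for k in z.files
                      if k.startswith("head/")}
        head = None
        if head_state:
            d_out, d_in = head_state["proj.weight"].shape
            head = PointwiseHead(d_in, d_out)
            head.load_state_dict(head_state)
        extra = {k[len("extra/"):]: z[k] for k in z.files if k.startswith("extra/")}
    return encoder, head, extra
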