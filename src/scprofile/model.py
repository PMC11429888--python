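"""The sequence-to-single-cell-profile model.

``ProfileModel`` bundles the pieces of the architecture: a sequence encoder
(optionally wrapped with low-rank adapters), the trainable pointwise GELU
head, and one hypernetwork decoder per assay (RNA: 2 strand tracks; ATAC: 1
track) sharing the same cell-embedding input. The forward pass produces
squashed-scale, nonnegative profiles for a batch of cells over the center
bins of the input window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor
from .backbone import (
    CHECKPOINT_FORMAT_VERSION,
    EncoderConfig,
    PointwiseHead,
    TinyBackbone,
    crop_margins,
)
from .decoder import ATAC_TRACKS, RNA_TRACKS, HyperNet, decode_cells_batched
from .lora import inject_lora, lora_parameters

DEFAULT_LORA_TARGETS = [
    "conv_stem", "conv_tower.*",
    "*.attn.q_proj", "*.attn.v_proj", "*.mlp.fc1", "*.mlp.fc2",
]


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    embedding_dim: int = 14
    crop_to: int | None = None  # center bins decoded; None = all bins
    hypernet_hidden: tuple = (256, 256)
    lora_rank: int = 8
    lora_alpha: float | None = None  # None -> rank (scaling alpha/r = 1)
    lora_targets: tuple = tuple(DEFAULT_LORA_TARGETS)
    seed: int = 0

    @property
    def n_output_bins(self) -> int:
        return self.crop_to if self.crop_to is not None else self.encoder.n_bins


class ProfileModel:
    def __init__(self, config: ModelConfig):
        self.config = config
        D = config.encoder.out_channels
        self.encoder = TinyBackbone(config.encoder)
        self.head = PointwiseHead(config.encoder.channels, D, seed=config.seed + 1)
        self.hypernet_rna = HyperNet(
            config.embedding_dim, D, RNA_TRACKS,
            hidden=config.hypernet_hidden, seed=config.seed + 2,
        )
        self.hypernet_atac = HyperNet(
            config.embedding_dim, D, ATAC_TRACKS,
            hidden=config.hypernet_hidden, seed=config.seed + 3,
        )
        self.has_adapters = False

    # -- adaptation --------------------------------------------------------
    def add_adapters(self) -> None:
        """Inject LoRA into the encoder and freeze every base encoder
        parameter, so gradients reach only adapters, head, and hypernets."""
        inject_lora(
            self.encoder, list(self.config.lora_targets),
            r=self.config.lora_rank, alpha=self.config.lora_alpha,
            seed=self.config.seed + 4,
        )
        adapter_ids = {id(p) for p in lora_parameters(self.encoder)}
        for _, p in self.encoder.named_parameters():
            if id(p) not in adapter_ids:
                p.requires_grad = False
        self.has_adapters = True

    def merge_adapters(self) -> None:
        from .lora import merge_lora

        merge_lora(self.encoder)
        self.has_adapters = False

    def parameter_groups(self) -> dict:
        """'decoder' = hypernetwork parameters; 'lora_head' = every other
        trainable parameter (adapters + head; plus the encoder itself when
        no adapters are injected and the backbone trains end to end)."""
        decoder = self.hypernet_rna.parameters() + self.hypernet_atac.parameters()
        lora_head = [p for _, p in self.encoder.named_parameters()
                     if p.requires_grad]
        lora_head += [p for p in self.head.parameters() if p.requires_grad]
        return {"decoder": decoder, "lora_head": lora_head}

    def modules(self):
        return [self.encoder, self.head, self.hypernet_rna, self.hypernet_atac]

    def train(self):
        for m in self.modules():
            m.train()

    def eval(self):
        for m in self.modules():
            m.eval()

    def zero_grad(self):
        for m in self.modules():
            m.zero_grad()

    # -- forward -----------------------------------------------------------
    def embed(self, x) -> Tensor:
        """One-hot (L, 4) -> cropped embedding track (n_output_bins, D)."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        emb = self.head(self.encoder(t))
        if self.config.crop_to is not None:
            m = crop_margins(emb.shape[0], self.config.crop_to)
            if m:
                emb = emb[m:emb.shape[0] - m]
        return emb

    def forward_cells(self, x, embeddings) -> dict:
        """Squashed-scale profiles for a batch of cells.

        Returns {"rna": (C, bins, 2), "atac": (C, bins, 1)} Tensors.
        """
        track = self.embed(x)
        w_rna = self.hypernet_rna(embeddings)
        w_atac = self.hypernet_atac(embeddings)
        return {
            "rna": decode_cells_batched(track, w_rna),
            "atac": decode_cells_batched(track, w_atac),
        }

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, mod in [("encoder", self.encoder), ("head", self.head),
                          ("hypernet_rna", self.hypernet_rna),
                          ("hypernet_atac", self.hypernet_atac)]:
            for k, v in mod.state_dict().items():
                out[f"{name}/{k}"] = v
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, mod in [("encoder", self.encoder), ("head", self.head),
                          ("hypernet_rna", self.hypernet_rna),
                          ("hypernet_atac", self.hypernet_atac)]:
            sub = {k[len(name) + 1:]: v for k, v in state.items()
                   if k.startswith(name + "/")}
            mod.load_state_dict(sub)

    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["encoder"] = asdict(self.config.encoder)
        payload = {
            "__format_version__": np.array(CHECKPOINT_FORMAT_VERSION),
            "__config__": np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            "__has_adapters__": np.array(int(self.has_adapters)),
        }
        payload.update(self.state_dict())
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "ProfileModel":
        with np.load(path) as z:
            version = int(z["__format_version__"])
            if version != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint format {version}")
            cfg = json.loads(bytes(z["__config__"]).decode())
            cfg["encoder"] = EncoderConfig(**cfg["encoder"])
            cfg["hypernet_hidden"] = tuple(cfg["hypernet_hidden"])
            cfg["lora_targets"] = tuple(cfg["lora_targets"])
            model = cls(ModelConfig(**cfg))
            if int(z["__has_adapters__"]):
                model.add_adapters()
            state = {k: z[k] for k in z.files if not k.startswith("__")}
            model.load_state_dict(state)
        return model
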