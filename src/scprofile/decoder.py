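"""Cell-conditioned hypernetwork decoder.

The decoder that turns a sequence embedding into a per-cell profile is not a
fixed layer: a small MLP (the hypernetwork) maps each cell's embedding vector
to the weights of a position-wise linear read-out (a 1x1 convolution along
the sequence axis). For stranded RNA the generated weight tensor has shape
(D+1, 2, 1) — D filter weights plus one bias per strand; for unstranded ATAC
it is (D+1, 1, 1). In the full-scale setting D = 1,920, giving the (1921, 2,
1) RNA decoder; in toy mode D follows the encoder's head width.

The read-out activation is a softplus, keeping decoded (squashed-scale)
profiles nonnegative; the hypernetwork default is two hidden layers of width
256 with GELU. Both are configurable assumptions — see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import MLP, Module

RNA_TRACKS = 2  # one per strand
ATAC_TRACKS = 1


class HyperNet(Module):
    """MLP mapping a cell embedding (E) to decoder weights ((D+1) * S)."""

    def __init__(self, embedding_dim: int, channels: int, n_tracks: int,
                 hidden=(256, 256), seed: int = 0):
        super().__init__()
        self.embedding_dim = embedding_dim
        self.channels = channels
        self.n_tracks = n_tracks
        rng = np.random.default_rng(seed)
        self.mlp = MLP([embedding_dim, *hidden, (channels + 1) * n_tracks], rng)

    def forward(self, embeddings) -> Tensor:
        """(C, E) cell embeddings -> (C, D+1, S) decoder weights."""
        emb = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
        if emb.ndim == 1:
            emb = emb.reshape((1, self.embedding_dim))
        if emb.shape[-1] != self.embedding_dim:
            raise ValueError(
                f"embedding dimension {emb.shape[-1]} != expected "
                f"{self.embedding_dim}"
            )
        flat = self.mlp(emb)
        return flat.reshape((emb.shape[0], self.channels + 1, self.n_tracks))


def make_decoder_weights(hypernet: HyperNet, embedding) -> np.ndarray:
    """Generate one cell's decoder weights, shape (D+1, S, 1).

    Deterministic in the embedding: identical embeddings yield identical
    weights regardless of batch composition.
    """
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 1:
        raise ValueError("one cell at a time; use the hypernet directly for batches")
    w = hypernet(emb[None, :]).data[0]  # (D+1, S)
    return w[:, :, None]


def decode_profile(track, weights) -> np.ndarray:
    """Apply one cell's decoder to an embedding track.

    track: (bins, D); weights: (D+1, S, 1) or (D+1, S). Returns the
    squashed-scale profile (bins, S) = softplus(track @ filter + bias).
    """
    track = np.asarray(track, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim == 3:
        w = w[:, :, 0]
    D = track.shape[1]
    if w.shape[0] != D + 1:
        raise ValueError(f"weight first dim {w.shape[0]} != channels+1 ({D + 1})")
    z = track @ w[:D] + w[D]
    return np.logaddexp(0.0, z)


def decode_cells_batched(track, weight_batch) -> Tensor:
    """Decode one shared track for many cells (differentiably).

    track: (bins, D) array or Tensor; weight_batch: (C, D+1, S) Tensor from
    the hypernetwork. Returns softplus profiles (C, bins, S). Row i equals
    :func:`decode_profile` for cell i; the track is computed once and reused.
    """
    track_t = track if isinstance(track, Tensor) else Tensor(track)
    n_cells = weight_batch.shape[0]
    if n_cells == 0:
        return Tensor(np.zeros((0, track_t.shape[0], weight_batch.shape[2])))
    D = track_t.shape[1]
    filt = weight_batch[:, :D, :]          # (C, D, S)
    bias = weight_batch[:, D:D + 1, :]     # (C, 1, S)
    bins_first = track_t.reshape((1, *track_t.shape))  # (1, bins, D)
    z = ad.matmul(bins_first, filt) + bias  # broadcast -> (C, bins, S)
    return ad.softplus(z)


def decode_exonic(track, weight_batch, exon_bins) -> Tensor:
    """Decode only the embedding slices overlapping exons.

    ``exon_bins`` is an index set into [0, n_bins); cost scales with its
    size. Equals the full decode restricted to those bins.
    """
    track_t = track if isinstance(track, Tensor) else Tensor(track)
    idx = np.asarray(sorted(set(map(int, exon_bins))), dtype=np.int64)
    n_bins = track_t.shape[0]
    if idx.size and (idx.min() < 0 or idx.max() >= n_bins):
        raise IndexError(f"exon bin outside [0, {n_bins})")
    if idx.size == 0:
        return Tensor(np.zeros((weight_batch.shape[0], 0, weight_batch.shape[2])))
    return decode_cells_batched(track_t[idx], weight_batch)
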