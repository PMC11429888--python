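"""Squashed-scale transform for coverage values.

Coverage counts are heavy-tailed; before modeling they are compressed by a
power transform with soft clipping:

    u = scale * x
    squash(x) = u**p                          if u**p <= clip_soft
              = clip_soft + sqrt(u**p - clip_soft)   otherwise

with exponent ``p`` in (0, 1] (default 3/4). The transform is strictly
increasing on [0, inf) and therefore exactly invertible. RNA uses
``clip_soft=5`` and ``scale=1``; ATAC signal is pre-scaled by 0.05 so that
its values sit on the same scale as RNA coverage, and inversion multiplies
back by 20.

The exact exponent/pre-scale constants of the squashing scheme this follows
are not uniquely fixed by its description; the defaults here (p=3/4,
scale=1 for RNA) are assumptions and are fully parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ATAC_SCALE = 0.05  # ATAC pre-scale; inversion multiplies by 1/0.05 = 20


@dataclass(frozen=True)
class SquashParams:
    """Parameters of the squashed-scale transform.

    exponent: power in (0, 1]; clip_soft: soft-clip threshold (inf disables);
    scale: pre-scale applied to natural values (1 for RNA, 0.05 for ATAC).
    """

    exponent: float = 0.75
    clip_soft: float = 5.0
    scale: float = 1.0

    def __post_init__(self):
        if not (0 < self.exponent <= 1):
            raise ValueError("exponent must be in (0, 1]")
        if self.clip_soft <= 0:
            raise ValueError("clip_soft must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


RNA_SQUASH = SquashParams(exponent=0.75, clip_soft=5.0, scale=1.0)
ATAC_SQUASH = SquashParams(exponent=0.75, clip_soft=5.0, scale=ATAC_SCALE)


def squash(x, params: SquashParams = RNA_SQUASH) -> np.ndarray:
    """Natural-scale coverage -> squashed scale. Rejects negative input."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("squash requires nonnegative input")
    u = (params.scale * x) ** params.exponent
    over = u > params.clip_soft
    y = np.where(over, params.clip_soft + np.sqrt(np.maximum(u - params.clip_soft, 0.0)), u)
    return y


def unsquash(y, params: SquashParams = RNA_SQUASH) -> np.ndarray:
    """Exact inverse of :func:`squash` on its range, including the 1/scale
    multiplier (x20 for ATAC at scale 0.05)."""
    y = np.asarray(y, dtype=np.float64)
    over = y > params.clip_soft
    u = np.where(over, params.clip_soft + (y - params.clip_soft) ** 2, y)
    x = np.maximum(u, 0.0) ** (1.0 / params.exponent) / params.scale
    return x
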