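"""DNA sequence utilities: one-hot encoding, reverse complement, digests."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def one_hot(seq: str) -> np.ndarray:
    """(L, 4) one-hot; ambiguous bases (N etc.) encode as the zero vector."""
    arr = np.zeros((len(seq), 4), dtype=np.float64)
    idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for i, b in enumerate(BASES):
        arr[idx == ord(b), i] = 1.0
    return arr


def decode_one_hot(arr: np.ndarray) -> str:
    out = []
    for row in arr:
        out.append(BASES[int(np.argmax(row))] if row.sum() > 0 else "N")
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rc_one_hot(arr: np.ndarray) -> np.ndarray:
    """Reverse complement in one-hot space: flip positions, swap A<->T, C<->G."""
    return arr[::-1, ::-1].copy()


def digest(seq: str) -> str:
    return hashlib.sha1(seq.upper().encode()).hexdigest()


def extract_window(chrom_seq: str, start: int, length: int) -> str:
    """Window [start, start+length); positions outside the chromosome are
    N-padded so bin arithmetic is preserved near edges."""
    lo = max(start, 0)
    hi = min(start + length, len(chrom_seq))
    core = chrom_seq[lo:hi] if hi > lo else ""
    return "N" * (lo - start) + core + "N" * (start + length - max(hi, start))
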