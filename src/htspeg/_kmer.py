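"""Integer k-mer encoding shared by the cluster prefilter and the mapper."""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _v, _b in enumerate(b"ACGT"):
    _LUT[_b] = _v


def seq_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0..T=3, anything else 255)."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid k-mer codes of a code array.

    Returns ``(positions, kmers)`` where ``kmers[i]`` is the base-4 integer
    of the window starting at ``positions[i]``; windows containing non-ACGT
    bases are dropped.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        valid &= window != 255
        vals = vals * 4 + np.where(window == 255, 0, window).astype(np.uint64)
    pos = np.nonzero(valid)[0]
    return pos.astype(np.int64), vals[pos]
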