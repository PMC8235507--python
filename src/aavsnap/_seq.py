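"""Low-level sequence helpers used throughout the package.

Sequences are plain uppercase strings; the alignment kernels work on small
integer codes (A=0, C=1, G=2, T=3, anything else=4 which never matches).
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> code lookup for fast encoding
_CODE_TABLE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE_TABLE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT characters map to N."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into int64 codes (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer hashes of an encoded sequence; windows containing N get -1.

    The hash is the exact 2-bit packing of the k-mer (k <= 31), so there are
    no collisions.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    h = win @ powers
    bad = (win >= 4).any(axis=1)
    h[bad] = -1
    return h
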