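"""Base-code utilities.

Sequences are handled internally as ``uint8`` arrays with A=0, C=1, G=2, T=3.
Code 255 marks a non-ACGT character; windows additionally use -1 (int8) for
"no observation".
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
N_BASES = 4

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# complement in code space: A<->T, C<->G
COMP = np.array([T, G, C, A], dtype=np.uint8)

DINUCS = [a + b for a in BASES for b in BASES]  # index = 4*first + second


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string into uint8 codes."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8/int8 codes back to an ACGT string ('N' for non-codes)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    c = np.asarray(codes)
    safe = np.where((c >= 0) & (c < 4), c, 4).astype(np.intp)
    return lut[safe].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    c = np.asarray(codes)
    out = np.where((c >= 0) & (c < 4), COMP[np.clip(c, 0, 3).astype(np.intp)], c)
    return out.astype(c.dtype)


def revcomp(codes: np.ndarray) -> np.ndarray:
    return complement(codes)[::-1]
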