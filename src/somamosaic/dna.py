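"""Small DNA alphabet helpers shared across modules.

Sequences are handled either as Python strings over {A,C,G,T,N} or as
numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4). N never matches any
motif and is used internally as a window separator.
"""
from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

CODE = {b: i for i, b in enumerate(ALPHABET)}
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
COMP_CODE = np.array([T, G, C, A, N], dtype=np.uint8)

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
BASES = frozenset("ACGT")

# byte-level lookup: ASCII code -> base code (invalid bytes -> 255)
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in CODE.items():
    _BYTE_TO_CODE[ord(_b)] = _i
    _BYTE_TO_CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into a uint8 code array."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    if (codes == 255).any():
        bad = sorted({chr(b) for b in raw[codes == 255]})
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def complement(base: str) -> str:
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def is_pyrimidine(base: str) -> bool:
    return base in PYRIMIDINES


def member_mask(bases: frozenset[str] | set[str]) -> np.ndarray:
    """Boolean lookup over base codes: mask[code] is True iff base in set."""
    mask = np.zeros(5, dtype=bool)
    for b in bases:
        mask[CODE[b]] = True
    return mask
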