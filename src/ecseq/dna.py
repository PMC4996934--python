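"""Nucleotide encoding helpers shared across modules.

Bases are coded A=0, C=1, G=2, T=3, N=4.  The complement of code ``b`` for a
real base is ``3 - b``, which the reverse-complement helpers rely on.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

# ASCII -> code lookup (everything unexpected maps to N).
_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a nucleotide string."""
    return _DECODE[codes].tobytes().decode("ascii")


def decode_rows(codes: np.ndarray) -> list[str]:
    """Decode a 2-D code array into one string per row."""
    buf = _DECODE[codes.ravel()].tobytes()
    width = codes.shape[1]
    return [buf[i * width:(i + 1) * width].decode("ascii") for i in range(codes.shape[0])]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis of a code array."""
    out = codes[..., ::-1].copy()
    real = out != N_CODE
    out[real] = 3 - out[real]
    return out


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
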