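"""Compact integer encoding of nucleotide sequences.

Genomes and reads are held as ``uint8`` arrays: A,C,G,T -> 0..3, ambiguous
reference positions (N and other IUPAC codes) -> 4, ambiguous read bases -> 5.
Reference N (4) never equals a read base, and read N (5) never equals any
reference code, so a plain array comparison implements the convention that an
ambiguous position mismatches everything.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
REF_N = 4
READ_N = 5

_REF_ENCODE = np.full(256, REF_N, dtype=np.uint8)
_READ_ENCODE = np.full(256, READ_N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _REF_ENCODE[_b] = _i
    _REF_ENCODE[_b + 32] = _i  # lower case
    _READ_ENCODE[_b] = _i
    _READ_ENCODE[_b + 32] = _i

_DECODE = np.frombuffer(b"ACGTNN", dtype=np.uint8)
# complement: A<->T, C<->G; ambiguity codes stay ambiguous
_COMP = np.array([T, G, C, A, REF_N, READ_N], dtype=np.uint8)


def encode_ref(seq: str | bytes) -> np.ndarray:
    """Encode a reference sequence (non-ACGT -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _REF_ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def encode_read(seq: str | bytes) -> np.ndarray:
    """Encode a read sequence (non-ACGT -> 5)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _READ_ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis (works on read matrices)."""
    return _COMP[codes][..., ::-1]
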