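"""Small DNA helpers shared across the package.

Sequences cross module boundaries as plain ``str`` over {A,C,G,T}; hot loops
(read simulation, alignment) work on uint8 code arrays with A,C,G,T -> 0..3,
so that reverse complement is ``3 - codes``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3 as a uint8 array."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return codes.copy()


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(random_codes(rng, n))
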