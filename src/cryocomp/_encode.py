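"""Internal 2-bit nucleotide encoding shared by the scanning modules."""

from __future__ import annotations

import numpy as np

# A,C,G,T -> 0,1,2,3; everything else (IUPAC ambiguity codes) -> 255
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0,C=1,G=2,T=3, ambiguity=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Decode 0..3 codes back to an ACGT string."""
    return _BASES[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
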