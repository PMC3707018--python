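"""Small shared helpers: half-up rounding, sequence encoding, reverse complement."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 2-bit base codes; 255 marks N / invalid. Integer order == lexicographic order,
# so min(code, rc_code) is the canonical (lexicographically smaller) k-mer.
BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODE[ord(_b)] = _i
    BASE_CODE[ord(_b.lower())] = _i


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Byte-code a DNA string (A,C,G,T -> 0..3; N -> 255)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
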