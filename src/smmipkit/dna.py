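"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
# integer codes used in consensus arrays
A, C, G, T = 0, 1, 2, 3
DEL = 4      # base deleted relative to the reference
UNKNOWN = 5  # not sequenced / no consensus

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODE = np.full(256, UNKNOWN, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

_DECODE = np.array(list("ACGT-N"), dtype="U1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence string -> int8 code array (non-ACGT -> UNKNOWN)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings (fast byte compare)."""
    if a == b:
        return 0
    xa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int((xa != xb).sum())
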