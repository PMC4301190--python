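"""Low-level DNA sequence helpers shared across modules.

Sequences are handled in two forms: Python strings over ACGT (user-facing)
and numpy uint8 arrays with A=0, C=1, G=2, T=3 (compute-facing). Code 4 is
reserved for N/separator bases that never match anything.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[c] for c in arr)


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
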