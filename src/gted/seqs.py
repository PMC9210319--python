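"""Nucleotide string/array helpers shared across modules.

Sequences are plain upper-case strings at module boundaries and uint8
arrays (A=0, C=1, G=2, T=3, anything else=4) inside the alignment and
masking kernels.  Code 4 never matches anything, so N-runs are opaque to
both seeding and dynamic programming.
"""

from __future__ import annotations

import numpy as np

VALID_ALPHABET = set("ACGTN")

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DECODE = np.array(list("ACGTN"), dtype="U1")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[arr])


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    mask = out < 4
    out[mask] = 3 - out[mask]
    return out


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def check_alphabet(seq: str, name: str = "sequence") -> None:
    bad = set(seq.upper()) - VALID_ALPHABET
    if bad:
        from .errors import DataError

        raise DataError(f"{name} contains non-ACGTN characters: {sorted(bad)}")


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-mer of ``arr``.

    Returns (codes, valid) where ``codes[i]`` encodes ``arr[i:i+k]`` and
    ``valid[i]`` is False when the window contains an N.
    """
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        w = arr[j : j + n]
        codes = (codes << 2) | (w & 3).astype(np.int64)
        invalid |= w >= 4
    return codes, ~invalid
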