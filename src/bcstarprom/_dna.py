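"""Low-level DNA string helpers used throughout the package.

These are deliberately tiny: plain strings are the working currency for
amplicon-scale sequences, and the hot loops (fuzzy anchor search, base
encoding for PWM scanning) are kept allocation-light.
"""
from __future__ import annotations

import numpy as np

from .errors import LengthMismatchError

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: IUPAC degeneracy table. H/D/V/B are the three-letter codes used for
#: degenerate barcode synthesis; N is fully degenerate.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise LengthMismatchError(
            f"sequences have different lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def encode_bases(seq: str) -> np.ndarray:
    """Map an ACGT string to an int8 array (A=0 C=1 G=2 T=3).

    Raises ValueError on any non-ACGT character.
    """
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def fuzzy_find(haystack: str, needle: str, max_mismatch: int = 1, start: int = 0) -> int:
    """Leftmost occurrence of ``needle`` in ``haystack`` within ``max_mismatch``
    substitutions, or -1.

    Exact matches are located with ``str.find`` first, so the error-free path
    costs a single C-level scan.
    """
    exact = haystack.find(needle, start)
    if max_mismatch == 0:
        return exact
    n = len(needle)
    end = len(haystack) - n
    for i in range(start, end + 1):
        if i == exact:
            return i
        mm = 0
        window = haystack[i : i + n]
        for x, y in zip(window, needle):
            if x != y:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return exact if exact != -1 else -1


def matches_within(seq: str, ref: str, max_mismatch: int) -> bool:
    """True if two equal-length strings differ at <= max_mismatch positions."""
    if len(seq) != len(ref):
        return False
    mm = 0
    for x, y in zip(seq, ref):
        if x != y:
            mm += 1
            if mm > max_mismatch:
                return False
    return True
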