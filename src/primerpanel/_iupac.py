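"""IUPAC nucleotide code tables shared across the package.

Bases are encoded as 4-bit masks (A=1, C=2, G=4, T=8) so that two codes
are compatible iff ``mask_a & mask_b != 0``.  The gap character "-" maps
to 0 and is therefore incompatible with everything.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_SETS)
GAP = "-"

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

IUPAC_MASK: dict[str, int] = {
    code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
IUPAC_MASK[GAP] = 0

# ord(char) -> mask lookup table for fast numpy encoding
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_TABLE[ord(_c)] = _m

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", GAP: GAP,
}
_COMP_TRANS = str.maketrans(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMP_TRANS)[::-1]


def encode_mask(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of 4-bit base masks."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _MASK_TABLE[arr]


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate pattern stands for."""
    n = 1
    for c in seq:
        n *= len(IUPAC_SETS[c])
    return n


def is_compatible(a: str, b: str) -> bool:
    """True iff the IUPAC sets of two single codes intersect."""
    return bool(IUPAC_MASK[a] & IUPAC_MASK[b])


def validate(seq: str, allow_gap: bool = False) -> int | None:
    """Return the 0-based position of the first invalid character, or None."""
    allowed = IUPAC_CODES | {GAP} if allow_gap else IUPAC_CODES
    for i, c in enumerate(seq):
        if c not in allowed:
            return i
    return None
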