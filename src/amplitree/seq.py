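"""DNA alphabet helpers: IUPAC codes, complements, encodings.

The bitmask encoding (A=1, C=2, G=4, T=8) makes degenerate-primer matching a
vectorised AND: a primer position matches a reference base iff their masks
intersect.  Reference ``N`` is encoded as 0 so it never matches anything —
conservative, since an N in the database gives no evidence of a primer site.
"""

from __future__ import annotations

import numpy as np

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: IUPAC character → bitmask over concrete bases.
IUPAC_BITS: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC.items()
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)

#: Reference-base encoding: concrete bases get their bit, N gets 0 (never matches).
_REF_LUT = np.zeros(256, dtype=np.uint8)
for _b, _bit in _BASE_BIT.items():
    _REF_LUT[ord(_b)] = _bit


def revcomp(seq: str) -> str:
    """Reverse complement, degenerate-code aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return all(c in IUPAC for c in seq)


def validate_reference(seq: str, *, where: str = "sequence") -> str:
    """Uppercase, U→T, and reject characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in "ACGTN":
            raise ValueError(f"non-IUPAC reference character {c!r} at position {i} in {where}")
    return s


def encode_reference(seq: str) -> np.ndarray:
    """uint8 bitmask array for a reference sequence (N → 0)."""
    return _REF_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_primer(primer: str) -> np.ndarray:
    """uint8 bitmask array for a (possibly degenerate) primer."""
    try:
        return np.array([IUPAC_BITS[c] for c in primer], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in primer {primer!r}") from None


def degeneracy(primer: str) -> int:
    """Number of concrete sequences the degenerate primer stands for."""
    n = 1
    for c in primer:
        n *= len(IUPAC[c])
    return n
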