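"""Small nucleotide-sequence utilities shared across the package.

Coordinates are 0-based half-open everywhere in the library; user-facing
tables convert to 1-based closed at write time.
"""

from __future__ import annotations

import numpy as np

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement table covering all IUPAC codes (degenerate codes map to the
#: code describing the complement set, e.g. R -> Y).
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_DNA = set("ACGTN")
_RNA = set("ACGUN")

# base -> small integer; anything outside ACGT (incl. N) encodes to 4 and
# mismatches every base during alignment.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BYTE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _DNA


def is_rna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _RNA


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 decodes to ``N``."""
    return _BYTE[codes].tobytes().decode("ascii")
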