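"""Semi-global affine-gap alignment of amplicon reads.

Reads are aligned globally against the amplicon with free end-gaps on the
amplicon side (the read may cover any contiguous stretch of the reference).
Scoring is match +2, mismatch -3, gap open -6, gap extend -1, so a gap of
length k costs 6 + k.  Traceback prefers, in order, diagonal, deletion,
insertion; indel events are afterwards left-normalized so equivalent gap
placements collapse to a single canonical representation.

The inner dynamic program is numba-jitted; reads containing ``N`` mismatch
every reference base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq import encode

OP_DIAG = 0  # read base vs ref base
OP_INS = 1   # read base vs gap in ref (insertion relative to the amplicon)
OP_DEL = 2   # gap in read vs ref base (deletion relative to the amplicon)

_NEG = np.int32(-(1 << 29))


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 6   # charged once per gap run, on top of the first extend
    gap_extend: int = 1


@dataclass
class Alignment:
    """One read-vs-amplicon alignment (read coordinates implicit)."""

    score: int
    ref_start: int
    ref_end: int
    ops: np.ndarray  # uint8 per column: OP_DIAG / OP_INS / OP_DEL
    n_matches: int

    @property
    def identity(self) -> float:
        return self.n_matches / len(self.ops) if len(self.ops) else 0.0


@njit(cache=True)
def _affine_semiglobal(read, ref, match, mismatch, gap_open, gap_ext):  # pragma: no cover - jitted
    m = read.shape[0]
    n = ref.shape[0]
    M = np.full((m + 1, n + 1), _NEG, np.int32)
    I = np.full((m + 1, n + 1), _NEG, np.int32)
    D = np.full((m + 1, n + 1), _NEG, np.int32)
    pM = np.zeros((m + 1, n + 1), np.uint8)
    pI = np.zeros((m + 1, n + 1), np.uint8)
    pD = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        M[0, j] = 0
    for i in range(1, m + 1):
        for j in range(n + 1):
            a = M[i - 1, j] - gap_open - gap_ext
            b = I[i - 1, j] - gap_ext
            if a >= b:
                I[i, j] = a
                pI[i, j] = 0
            else:
                I[i, j] = b
                pI[i, j] = 1
            if j > 0:
                c = M[i, j - 1] - gap_open - gap_ext
                d = D[i, j - 1] - gap_ext
                if c >= d:
                    D[i, j] = c
                    pD[i, j] = 0
                else:
                    D[i, j] = d
                    pD[i, j] = 2
                if read[i - 1] == ref[j - 1] and read[i - 1] < 4:
                    s = match
                else:
                    s = mismatch
                best = M[i - 1, j - 1]
                lay = 0
                if D[i - 1, j - 1] > best:
                    best = D[i - 1, j - 1]
                    lay = 2
                if I[i - 1, j - 1] > best:
                    best = I[i - 1, j - 1]
                    lay = 1
                M[i, j] = best + s
                pM[i, j] = lay
    # best end point over the last row; ties -> preferred layer, smallest j
    bs = _NEG
    bj = 0
    bl = 0
    for j in range(n + 1):
        if M[m, j] > bs:
            bs = M[m, j]
            bj = j
            bl = 0
        if D[m, j] > bs:
            bs = D[m, j]
            bj = j
            bl = 2
        if I[m, j] > bs:
            bs = I[m, j]
            bj = j
            bl = 1
    ops = np.empty(m + n, np.uint8)
    k = 0
    i = m
    j = bj
    lay = bl
    nmatch = 0
    while i > 0:
        if lay == 0:
            ops[k] = 0
            if read[i - 1] == ref[j - 1] and read[i - 1] < 4:
                nmatch += 1
            lay = pM[i, j]
            i -= 1
            j -= 1
        elif lay == 1:
            ops[k] = 1
            lay = pI[i, j]
            i -= 1
        else:
            ops[k] = 2
            lay = pD[i, j]
            j -= 1
        k += 1
    return bs, j, bj, ops[:k][::-1].copy(), nmatch


def align_read(
    read: str,
    ref: str,
    scoring: Scoring = Scoring(),
    min_identity: float | None = 0.6,
) -> Alignment | None:
    """Align one read to an amplicon; ``None`` means the read failed the
    identity floor and is counted unaligned by callers."""
    if not read or not ref:
        raise ValueError("read and reference must be non-empty")
    score, ref_start, ref_end, ops, nmatch = _affine_semiglobal(
        encode(read), encode(ref),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    aln = Alignment(int(score), int(ref_start), int(ref_end), ops, int(nmatch))
    if min_identity is not None and aln.identity < min_identity:
        return None
    return aln


def gapless_alignment(read: str, ref: str, ref_start: int, scoring: Scoring = Scoring()) -> Alignment:
    """Build the trivial all-diagonal alignment of ``read`` against
    ``ref[ref_start:ref_start+len(read)]`` (fast path for unedited reads)."""
    a = encode(read)
    b = encode(ref)[ref_start : ref_start + len(read)]
    if a.size != b.size:
        raise ValueError("read extends past the reference for a gapless alignment")
    nmatch = int(np.count_nonzero((a == b) & (a < 4)))
    score = nmatch * scoring.match + (a.size - nmatch) * scoring.mismatch
    return Alignment(score, ref_start, ref_start + a.size, np.zeros(a.size, np.uint8), nmatch)
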