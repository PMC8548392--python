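"""Genome-wide off-target enumeration and read-level screening.

Candidate sites are enumerated at every PAM occurrence on both strands by a
banded edit-distance dynamic program of the spacer against the adjacent
genomic window (unit mismatch and unit gap costs, band width = the bulge
limit).  A "bulge" is a gap on either sequence: a DNA bulge is an extra
genome base, an RNA bulge a skipped guide base.  Tie-breaking prefers fewer
gaps, then fewer mismatches, then the shortest genomic footprint, so each
PAM contributes the minimal-distortion interpretation of its site.

Screening applies the read-level rules used for putative-edit calls: at
least five uniquely assigned reads, a mutant fraction above 20% inside the
12-bp window over the expected cut, and a clean negative control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .align import Scoring, align_read
from .calling import IndelEvent, extract_indels, left_normalize
from .guides import DEFAULT_CUT_OFFSET, DEFAULT_WINDOW_WIDTH, PamPattern
from .io import ReadBatch
from .seq import IUPAC, revcomp

DEFAULT_MAX_MM = 4
DEFAULT_MAX_BULGES = 2
#: Minimum uniquely assigned reads for a locus to be scored.
MIN_UNIQUE_READS = 5
#: Mutant-read fraction (strict) above which a covered locus is flagged.
MUTANT_FRACTION_CUTOFF = 0.20
#: Alignment-score margin over the runner-up locus for "uniquely mapped".
UNIQUENESS_MARGIN = 10
#: Control mutant fractions up to this are treated as sequencing background.
CONTROL_BACKGROUND_FLOOR = 0.005

_INF = 10**6


@dataclass(frozen=True)
class OffTargetCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    protospacer: str  # genomic slice, guide sense
    pam_seq: str
    n_mismatches: int
    n_bulges: int
    bulge_kinds: tuple[str, ...]
    cut_center: int          # top-strand inter-base coordinate
    window: tuple[int, int]  # top-strand half-open interval

    @property
    def n_differences(self) -> int:
        return self.n_mismatches + self.n_bulges


def _pam_regex(pattern: PamPattern) -> re.Pattern:
    # lookahead allows overlapping occurrences; genome N never matches
    body = "".join(
        b if len(IUPAC[sym]) == 1 else "[" + "".join(sorted(IUPAC[sym])) + "]"
        for sym, b in zip(pattern.pattern, pattern.pattern)
    )
    return re.compile(f"(?=({body}))")


def best_site_alignment(
    spacer: str, window: str, max_mm: int, max_bulges: int
) -> tuple[int, int, int, tuple[str, ...]] | None:
    """Best (fewest-gap, then fewest-mismatch) alignment of a spacer against
    a PAM-adjacent genomic window.

    Returns ``(n_bulges, n_mismatches, footprint, bulge_kinds)`` or ``None``
    if no alignment satisfies the mismatch limit.  The DP state is
    (gaps used, spacer consumed, window consumed) with minimal mismatches as
    the value; trailing window bases are free.
    """
    L, W = len(spacer), len(window)
    G = max_bulges
    dp = [[[_INF] * (W + 1) for _ in range(L + 1)] for _ in range(G + 1)]
    ptr = [[[0] * (W + 1) for _ in range(L + 1)] for _ in range(G + 1)]
    dp[0][0][0] = 0
    for g in range(G + 1):
        dpg = dp[g]
        for i in range(L + 1):
            row = dpg[i]
            for j in range(W + 1):
                cur = row[j]
                if cur >= _INF:
                    continue
                if i < L and j < W:  # diagonal
                    step = cur + (
                        0 if spacer[i] == window[j] and window[j] in "ACGT" else 1
                    )
                    if step < dpg[i + 1][j + 1]:
                        dpg[i + 1][j + 1] = step
                        ptr[g][i + 1][j + 1] = 1
                if g < G:
                    if j < W and cur < dp[g + 1][i][j + 1]:  # DNA bulge
                        dp[g + 1][i][j + 1] = cur
                        ptr[g + 1][i][j + 1] = 2
                    if i < L and cur < dp[g + 1][i + 1][j]:  # RNA bulge
                        dp[g + 1][i + 1][j] = cur
                        ptr[g + 1][i + 1][j] = 3
    best: tuple[int, int, int] | None = None
    for g in range(G + 1):
        for j in range(W + 1):
            mm = dp[g][L][j]
            if mm <= max_mm and (best is None or (g, mm, j) < best):
                best = (g, mm, j)
    if best is None:
        return None
    g, mm, j = best
    kinds: list[str] = []
    i = L
    while i > 0 or ptr[g][i][j] in (2, 3):
        move = ptr[g][i][j]
        if move == 1:
            i -= 1
            j -= 1
        elif move == 2:
            kinds.append("dna")
            g -= 1
            j -= 1
        elif move == 3:
            kinds.append("rna")
            g -= 1
            i -= 1
        else:
            break
    return best[0], mm, best[2], tuple(reversed(kinds))


def enumerate_offtargets(
    genome: str | dict[str, str],
    spacer: str,
    pam: PamPattern | str,
    max_mm: int = DEFAULT_MAX_MM,
    max_bulges: int = DEFAULT_MAX_BULGES,
    cut_offset: int = DEFAULT_CUT_OFFSET,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> list[OffTargetCandidate]:
    """Scan both strands for sites within the mismatch/bulge limits.

    One candidate is emitted per PAM occurrence per strand, carrying the
    minimal-distortion alignment; expected cut windows are measured on the
    genome from the PAM 3' end.
    """
    pam = PamPattern(pam) if isinstance(pam, str) else pam
    spacer = spacer.upper().replace("U", "T")
    if len(spacer) < 16:
        raise ValueError(f"spacer must be at least 16 nt, got {len(spacer)}")
    chroms = {"genome": genome} if isinstance(genome, str) else genome
    regex = _pam_regex(pam)
    plen = len(pam)
    L = len(spacer)
    out: list[OffTargetCandidate] = []
    for chrom, seq in chroms.items():
        seq = seq.upper()
        N = len(seq)
        if N == 0:
            continue
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for m in regex.finditer(s):
                p = m.start()
                wstart = p + plen
                window = s[wstart : wstart + L + max_bulges]
                if len(window) < L - max_bulges:
                    continue
                hit = best_site_alignment(spacer, window, max_mm, max_bulges)
                if hit is None:
                    continue
                n_bulges, n_mm, footprint, kinds = hit
                lo, hi = wstart, wstart + footprint
                cut = wstart + cut_offset
                half = window_width // 2
                win = (cut - half, cut + half)
                if strand == "+":
                    start, end = lo, hi
                    cut_top, win_top = cut, win
                else:
                    start, end = N - hi, N - lo
                    cut_top = N - cut
                    win_top = (N - win[1], N - win[0])
                out.append(
                    OffTargetCandidate(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        protospacer=s[lo:hi],
                        pam_seq=s[p : p + plen],
                        n_mismatches=n_mm,
                        n_bulges=n_bulges,
                        bulge_kinds=kinds,
                        cut_center=cut_top,
                        window=win_top,
                    )
                )
    out.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return out


# ---------------------------------------------------------------------------
# Read-level screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenVerdict:
    candidate: OffTargetCandidate
    n_unique_reads: int
    mutant_fraction: float
    control_mutant_fraction: float
    verdict: str  # putative_edit | clean | insufficient_coverage


def _window_mutant_fraction(
    reads: ReadBatch,
    locus_ref: str,
    window: tuple[int, int],
    alt_refs: tuple[str, ...],
    margin: int,
    scoring: Scoring,
) -> tuple[int, int]:
    """(uniquely assigned reads, reads with a window indel)."""
    n_unique = 0
    n_mutant = 0
    cache: dict[str, tuple[bool, bool]] = {}
    for seq in reads.seqs:
        if seq in cache:
            unique, mutant = cache[seq]
        else:
            aln = align_read(seq, locus_ref, scoring, min_identity=0.6)
            if aln is None:
                cache[seq] = (False, False)
                continue
            unique = True
            for alt in alt_refs:
                alt_aln = align_read(seq, alt, scoring, min_identity=None)
                if alt_aln is not None and aln.score - alt_aln.score < margin:
                    unique = False
                    break
            mutant = False
            if unique:
                events = extract_indels(aln, seq, locus_ref)
                mutant = any(ev.in_window(window) for ev in events)
            cache[seq] = (unique, mutant)
        if unique:
            n_unique += 1
            if mutant:
                n_mutant += 1
    return n_unique, n_mutant


def screen_candidate(
    candidate: OffTargetCandidate,
    reads: ReadBatch,
    control_reads: ReadBatch,
    locus_ref: str,
    locus_start: int = 0,
    alt_refs: tuple[str, ...] = (),
    min_reads: int = MIN_UNIQUE_READS,
    frac: float = MUTANT_FRACTION_CUTOFF,
    margin: int = UNIQUENESS_MARGIN,
    control_floor: float = CONTROL_BACKGROUND_FLOOR,
    scoring: Scoring = Scoring(),
) -> ScreenVerdict:
    """Screen one candidate locus for a putative edit.

    ``locus_ref`` is the reference slice the reads were assigned to and
    ``locus_start`` its offset on the candidate's chromosome; ``alt_refs``
    are competing loci for the uniqueness check (best score must exceed the
    runner-up by ``margin``).  A site is a putative edit iff it has at least
    ``min_reads`` unique reads, a window mutant fraction strictly above
    ``frac``, and a control fraction at or below ``control_floor``.
    """
    window = (candidate.window[0] - locus_start, candidate.window[1] - locus_start)
    if window[0] < 0 or window[1] > len(locus_ref):
        raise ValueError("candidate cut window lies outside the provided locus reference")
    n_unique, n_mutant = _window_mutant_fraction(
        reads, locus_ref, window, alt_refs, margin, scoring
    )
    if n_unique < min_reads:
        return ScreenVerdict(candidate, n_unique, 0.0, 0.0, "insufficient_coverage")
    mutant_fraction = n_mutant / n_unique
    c_unique, c_mutant = _window_mutant_fraction(
        control_reads, locus_ref, window, alt_refs, margin, scoring
    )
    control_fraction = c_mutant / c_unique if c_unique else 0.0
    if mutant_fraction > frac and control_fraction <= control_floor:
        verdict = "putative_edit"
    else:
        verdict = "clean"
    return ScreenVerdict(candidate, n_unique, mutant_fraction, control_fraction, verdict)


def candidates_frame(candidates: list[OffTargetCandidate]):
    """BED6+ table of candidates (0-based half-open, score = differences)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "name": c.protospacer,
                "score": c.n_differences,
                "strand": c.strand,
                "n_mismatches": c.n_mismatches,
                "n_bulges": c.n_bulges,
                "bulge_kinds": ",".join(c.bulge_kinds) or ".",
                "pam": c.pam_seq,
                "cut_center": c.cut_center,
            }
            for c in candidates
        ],
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_mismatches", "n_bulges", "bulge_kinds", "pam", "cut_center",
        ],
    )
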