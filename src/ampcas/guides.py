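"""Cas12f1 target-site and guide-RNA models.

Cas12f1 nucleases recognise a 5' PAM (SpCas12f1: TTC, AsCas12f1: YTTN) and
cleave 22-24 bp downstream of it, leaving staggered ends; editing outcomes
are therefore scored inside a fixed-width window centred on the expected cut
site.  This module models PAM matching over the IUPAC alphabet, cut-site
geometry on either strand, spacer-length validation, the crRNA:tracrRNA
repeat/anti-repeat duplex, and single-guide (sgRNA) assembly, plus a simple
pileup-enrichment caller used to locate guide RNA species in coverage tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import IUPAC, is_rna, revcomp

#: Default distance from the PAM 3' end to the expected cut centre, the
#: midpoint of the observed 22-24 bp run-off range.
DEFAULT_CUT_OFFSET = 23
#: Width of the editing-analysis window centred on the cut site.
DEFAULT_WINDOW_WIDTH = 12
#: Minimum spacer length supporting cleavage of both strands.
MIN_SPACER_LEN = 16


@dataclass(frozen=True)
class PamPattern:
    """A 5'-of-protospacer PAM motif in IUPAC nucleotide code."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("PAM pattern must be non-empty")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in PAM pattern: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window_seq: str) -> bool:
        return match_pam(window_seq, self)


def match_pam(window_seq: str, pattern: PamPattern | str) -> bool:
    """Test a genomic window against a PAM motif.

    Each base must fall in the IUPAC class of the corresponding pattern
    symbol.  An ``N`` in the *sequence* is treated as an unknown base and
    matches only the pattern symbol ``N``.

    Raises ``ValueError`` on length mismatch or non-nucleotide characters.
    """
    pat = pattern.pattern if isinstance(pattern, PamPattern) else PamPattern(pattern).pattern
    if len(window_seq) != len(pat):
        raise ValueError(
            f"PAM window length {len(window_seq)} != pattern length {len(pat)}"
        )
    for base, sym in zip(window_seq, pat):
        if base not in "ACGTN":
            raise ValueError(f"non-nucleotide character {base!r} in PAM window")
        if base == "N":
            if sym != "N":
                return False
        elif base not in IUPAC[sym]:
            return False
    return True


def expected_cut_window(
    pam_interval: tuple[int, int],
    strand: str,
    offset: int = DEFAULT_CUT_OFFSET,
    width: int = DEFAULT_WINDOW_WIDTH,
    seq_len: int | None = None,
    site_name: str = "",
) -> tuple[int, tuple[int, int]]:
    """Expected cut centre and analysis window for a PAM placement.

    On the + strand the protospacer runs rightward from the PAM, so the cut
    centre is ``pam_end + offset`` (an inter-base coordinate); on the -
    strand the geometry mirrors toward decreasing coordinates from the PAM's
    top-strand start.  The window is the half-open interval of ``width``
    bases centred on the cut.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not 22 <= offset <= 24:
        raise ValueError(f"cut offset must lie in 22..24 bp, got {offset}")
    if width <= 0 or width % 2:
        raise ValueError(f"window width must be a positive even number, got {width}")
    if strand == "+":
        cut_center = pam_interval[1] + offset
    else:
        cut_center = pam_interval[0] - offset
    window = (cut_center - width // 2, cut_center + width // 2)
    if seq_len is not None and (window[0] < 0 or window[1] > seq_len or not 0 <= cut_center <= seq_len):
        name = site_name or f"pam@{pam_interval[0]}:{pam_interval[1]}({strand})"
        raise ValueError(
            f"cut window {window} of site {name} extends beyond the amplicon (len {seq_len})"
        )
    return cut_center, window


@dataclass(frozen=True)
class SpacerCheck:
    ok: bool
    reason: str | None = None


def validate_spacer(spacer: str, min_len: int = MIN_SPACER_LEN) -> SpacerCheck:
    """Check a spacer supports cleavage (length >= 16 nt)."""
    if len(spacer) >= min_len:
        return SpacerCheck(True)
    return SpacerCheck(
        False, f"spacer is {len(spacer)} nt; at least {min_len} nt required for cleavage"
    )


@dataclass(frozen=True)
class TargetSite:
    """A guide binding site on a reference amplicon.

    ``pam_interval`` is on the top strand; ``strand`` is the strand carrying
    the protospacer; ``cut_center`` is an inter-base coordinate and
    ``window`` the half-open editing-analysis interval around it.
    """

    amplicon_id: str
    pam_interval: tuple[int, int]
    strand: str
    spacer: str
    cut_center: int
    window: tuple[int, int]
    pam: PamPattern = field(default_factory=lambda: PamPattern("TTC"))

    def __post_init__(self) -> None:
        if len(self.spacer) < MIN_SPACER_LEN:
            raise ValueError(
                f"site {self.amplicon_id}: spacer shorter than {MIN_SPACER_LEN} nt"
            )
        if self.window[1] - self.window[0] <= 0:
            raise ValueError("window must be non-empty")

    @classmethod
    def from_guide(
        cls,
        amplicon_id: str,
        amplicon: str,
        spacer: str,
        pam: PamPattern | str,
        pam_start: int,
        strand: str = "+",
        offset: int = DEFAULT_CUT_OFFSET,
        width: int = DEFAULT_WINDOW_WIDTH,
    ) -> "TargetSite":
        """Build and validate a site from a guide declaration.

        Checks that the PAM matches its motif on the protospacer strand and
        that the amplicon actually carries the protospacer next to it.
        """
        pam = PamPattern(pam) if isinstance(pam, str) else pam
        spacer = spacer.upper().replace("U", "T")
        check = validate_spacer(spacer)
        if not check.ok:
            raise ValueError(f"site {amplicon_id}: {check.reason}")
        plen = len(pam)
        pam_interval = (pam_start, pam_start + plen)
        if pam_start < 0 or pam_interval[1] > len(amplicon):
            raise ValueError(f"site {amplicon_id}: PAM interval outside amplicon")
        if strand == "+":
            pam_seq = amplicon[pam_start : pam_start + plen]
            proto = amplicon[pam_interval[1] : pam_interval[1] + len(spacer)]
        elif strand == "-":
            pam_seq = revcomp(amplicon[pam_start : pam_start + plen])
            proto = revcomp(amplicon[pam_start - len(spacer) : pam_start])
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if not match_pam(pam_seq, pam):
            raise ValueError(
                f"site {amplicon_id}: PAM {pam_seq} at {pam_interval} does not match {pam.pattern}"
            )
        if proto != spacer:
            raise ValueError(
                f"site {amplicon_id}: protospacer {proto} next to the PAM does not equal the spacer"
            )
        cut_center, window = expected_cut_window(
            pam_interval, strand, offset, width, len(amplicon), amplicon_id
        )
        return cls(amplicon_id, pam_interval, strand, spacer, cut_center, window, pam)


# ---------------------------------------------------------------------------
# crRNA:tracrRNA duplex and sgRNA assembly
# ---------------------------------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

#: Pairing scores for the ungapped repeat:anti-repeat scan: Watson-Crick 2,
#: G:U wobble 1, anything else -2.
PAIR_SCORES = {"wc": 2, "wobble": 1, "mismatch": -2}


@dataclass(frozen=True)
class Duplex:
    """An ungapped antiparallel repeat:anti-repeat pairing."""

    repeat_interval: tuple[int, int]
    tracr_interval: tuple[int, int]
    score: int
    pairing: tuple[str, ...]  # per repeat position, 5'->3': wc/wobble/mismatch


def _pair_state(r: str, t: str) -> str:
    if (r, t) in _WC:
        return "wc"
    if (r, t) in _WOBBLE:
        return "wobble"
    return "mismatch"


def find_anti_repeat(tracr: str, repeat: str, min_len: int = 8) -> Duplex | None:
    """Locate the anti-repeat: the best ungapped antiparallel pairing of the
    CRISPR repeat against any tracrRNA window.

    Repeat position ``i`` (5'->3') pairs with tracr position
    ``t + L - 1 - i`` inside the window starting at ``t``.  Returns ``None``
    if the best score falls below ``min_len``; leftmost window wins ties.
    """
    if not tracr or not repeat:
        raise ValueError("tracr and repeat must be non-empty")
    if not (is_rna(tracr) and is_rna(repeat)):
        raise ValueError("find_anti_repeat expects RNA sequences (U, not T)")
    L = len(repeat)
    if L > len(tracr):
        return None
    best: Duplex | None = None
    for t in range(len(tracr) - L + 1):
        states = tuple(
            _pair_state(repeat[i], tracr[t + L - 1 - i]) for i in range(L)
        )
        score = sum(PAIR_SCORES[s] for s in states)
        if best is None or score > best.score:
            best = Duplex((0, L), (t, t + L), score, states)
    assert best is not None
    if best.score < min_len:
        return None
    return best


@dataclass(frozen=True)
class GuideArchitecture:
    """Components of an engineered single guide RNA.

    The native system uses a separate crRNA (repeat + spacer) and a long
    tracrRNA carrying an anti-repeat; the single guide joins them through a
    tetranucleotide linker.
    """

    tracr: str
    crrna_repeat: str
    spacer: str
    linker: str = "GAAA"
    duplex: Duplex | None = None

    @classmethod
    def build(
        cls, tracr: str, crrna_repeat: str, spacer: str, linker: str = "GAAA",
        min_duplex_score: int = 8,
    ) -> "GuideArchitecture":
        duplex = find_anti_repeat(tracr, crrna_repeat, min_duplex_score)
        return cls(tracr, crrna_repeat, spacer, linker, duplex)


DEFAULT_SGRNA_ORDER = ("tracr", "linker", "crrna_repeat", "spacer")


def assemble_sgRNA(
    arch: GuideArchitecture, order: tuple[str, ...] = DEFAULT_SGRNA_ORDER
) -> str:
    """Concatenate guide components 5'->3' (default tracr-linker-repeat-spacer)."""
    if len(arch.linker) != 4:
        raise ValueError(f"linker must be 4 nt, got {len(arch.linker)}")
    for name in ("tracr", "crrna_repeat", "spacer"):
        if not getattr(arch, name):
            raise ValueError(f"sgRNA component {name!r} is empty")
    if sorted(order) != sorted(DEFAULT_SGRNA_ORDER):
        raise ValueError(f"order must permute {DEFAULT_SGRNA_ORDER}, got {order}")
    return "".join(getattr(arch, name) for name in order)


# ---------------------------------------------------------------------------
# Pileup species calling
# ---------------------------------------------------------------------------

def call_enriched_species(
    coverage: np.ndarray, k: float = 10.0, merge_gap: int = 5
) -> list[tuple[int, int]]:
    """Maximal intervals enriched >= ``k`` times over the track median.

    Used to pick out crRNA/tracrRNA species from an RNA-seq read pileup:
    positions at or above ``k * median`` depth form runs, and runs separated
    by at most ``merge_gap`` positions are merged.  An all-zero track yields
    no intervals.
    """
    cov = np.asarray(coverage)
    if cov.ndim != 1:
        raise ValueError("coverage must be a 1-D track")
    if np.any(cov < 0):
        raise ValueError("coverage must be non-negative")
    if cov.size == 0 or not np.any(cov):
        return []
    threshold = k * float(np.median(cov))
    hot = (cov >= threshold) & (cov > 0)
    intervals: list[tuple[int, int]] = []
    start = None
    for pos, flag in enumerate(hot):
        if flag and start is None:
            start = pos
        elif not flag and start is not None:
            intervals.append((start, pos))
            start = None
    if start is not None:
        intervals.append((start, cov.size))
    merged: list[tuple[int, int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)
    return merged
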