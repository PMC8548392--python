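"""On-target indel quantification from amplicon deep sequencing.

The stage mirrors the standard editing-outcome workflow: 3' quality
trimming (running-sum rule at Phred 13), semi-global alignment to the
amplicon, extraction and left-normalization of indel events, grouping of
identical events into types inside the 12-bp window around the expected cut
site, a negative-control filter requiring each type to be at least 30 times
more frequent than in the control, and finally mutant/wild-type read
tallies.  Two frequency metrics are reported: the literal mutant/wild-type
ratio and the mutant percentage of aligned reads (the default display
metric).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import OP_DEL, OP_DIAG, OP_INS, Alignment, Scoring, align_read, gapless_alignment
from .guides import TargetSite
from .io import ReadBatch
from .seq import encode

#: Phred threshold of the 3' running-sum trimmer.
DEFAULT_TRIM_THRESHOLD = 13
#: Reads shorter than this after trimming are discarded.
MIN_READ_LEN = 30
#: Control-filter multiplier: a type must be this many times more frequent
#: in the sample than in the negative control to be retained.
DEFAULT_MULTIPLIER = 30.0
#: Pseudocount substituted for a type unseen in the control (avoids a zero
#: denominator while keeping the filter depth-aware).
CONTROL_PSEUDOCOUNT = 0.5
#: Reads below this alignment identity are counted unaligned.
DEFAULT_IDENTITY_FLOOR = 0.6
# Gapless fast path: same-length-prefix reads with at most this mismatch
# fraction are accepted without the full DP (a genuine indel shifts the
# downstream sequence and blows far past it).
_FAST_PATH_MM_FRAC = 0.05


@dataclass(frozen=True)
class IndelEvent:
    """One normalized indel against the amplicon.

    Deletions remove ``ref [start, end)``; insertions add ``inserted`` at
    the inter-base coordinate ``start`` (== ``end``).  Events are stored
    left-normalized: shifted as far left as sequence equivalence allows.
    """

    kind: str  # "del" | "ins"
    start: int
    end: int
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.kind == "del":
            if self.end <= self.start or self.inserted:
                raise ValueError("deletion needs a non-empty interval and no inserted sequence")
        elif self.kind == "ins":
            if self.end != self.start or not self.inserted:
                raise ValueError("insertion needs an anchor (start == end) and inserted sequence")
        else:
            raise ValueError(f"unknown indel kind {self.kind!r}")

    @property
    def length(self) -> int:
        return len(self.inserted) if self.kind == "ins" else self.end - self.start

    def in_window(self, window: tuple[int, int]) -> bool:
        """Interval intersection for deletions; anchor containment (closed)
        for insertions."""
        a, b = window
        if self.kind == "ins":
            return a <= self.start <= b
        return self.start < b and self.end > a


def left_normalize(event: IndelEvent, ref: str) -> IndelEvent:
    """Shift an indel left while the flanking base equals its last base."""
    if event.kind == "del":
        start, end = event.start, event.end
        while start > 0 and ref[start - 1] == ref[end - 1]:
            start -= 1
            end -= 1
        if start == event.start:
            return event
        return IndelEvent("del", start, end)
    anchor, seq = event.start, event.inserted
    while anchor > 0 and ref[anchor - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        anchor -= 1
    if anchor == event.start:
        return event
    return IndelEvent("ins", anchor, anchor, seq)


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def quality_trim(qual: np.ndarray, threshold: int = DEFAULT_TRIM_THRESHOLD) -> int:
    """Return the retained length under the 3' running-sum rule.

    The cut point maximizes ``sum(threshold - q)`` accumulated from the 3'
    end; if no cut point is positive the read is kept whole.  Ties resolve
    to the longest retained read.
    """
    q = np.asarray(qual)
    if q.size == 0:
        return 0
    deltas = threshold - q[::-1].astype(np.int64)
    sums = np.cumsum(deltas)
    best = int(sums.max())
    if best <= 0:
        return int(q.size)
    return int(q.size - (int(np.argmax(sums)) + 1))


def _trim_lengths(quals: list[np.ndarray], threshold: int) -> np.ndarray:
    """Vectorized quality_trim over a batch (grouped by read length)."""
    lengths = np.fromiter((q.size for q in quals), dtype=np.int64, count=len(quals))
    keep = np.empty(len(quals), dtype=np.int64)
    for L in np.unique(lengths):
        idx = np.nonzero(lengths == L)[0]
        if L == 0:
            keep[idx] = 0
            continue
        mat = np.empty((idx.size, L), dtype=np.int64)
        for row, i in enumerate(idx):
            mat[row] = quals[i]
        sums = np.cumsum(threshold - mat[:, ::-1], axis=1)
        best = sums.max(axis=1)
        cut = np.argmax(sums, axis=1) + 1
        keep[idx] = np.where(best <= 0, L, L - cut)
    return keep


# ---------------------------------------------------------------------------
# Indel extraction
# ---------------------------------------------------------------------------

def extract_indels(alignment: Alignment, read: str, ref: str) -> list[IndelEvent]:
    """Convert gap runs of an alignment into left-normalized events in
    amplicon coordinates.  Substitutions are ignored."""
    events: list[IndelEvent] = []
    i = 0
    j = alignment.ref_start
    ops = alignment.ops
    k = 0
    n = len(ops)
    while k < n:
        op = ops[k]
        if op == OP_DIAG:
            i += 1
            j += 1
            k += 1
            continue
        run = k
        while run < n and ops[run] == op:
            run += 1
        span = run - k
        if op == OP_INS:
            events.append(left_normalize(IndelEvent("ins", j, j, read[i : i + span]), ref))
            i += span
        else:
            events.append(left_normalize(IndelEvent("del", j, j + span), ref))
            j += span
        k = run
    return events


# ---------------------------------------------------------------------------
# Sample tallies and the control filter
# ---------------------------------------------------------------------------

@dataclass
class SampleTally:
    """Per-sample read accounting before the control filter."""

    total_reads: int
    trimmed_discarded: int
    unaligned: int
    aligned_reads: int
    window_type_counts: Counter
    all_type_counts: Counter
    # one entry per unique aligned read sequence: (multiplicity, window events)
    reads_by_events: list[tuple[int, tuple[IndelEvent, ...]]]


@dataclass
class RetainedType:
    count: int
    sample_freq: float
    control_freq: float | None


@dataclass
class SampleCallSet:
    """Final per-sample call: retained types and mutant/wild-type tallies."""

    sample_id: str
    total_reads: int
    trimmed_discarded: int
    unaligned: int
    aligned_reads: int
    type_counts: Counter              # window types, pre-filter (reads per type)
    retained: dict[IndelEvent, RetainedType]
    mutant_reads: int
    wildtype_reads: int
    saturated: bool

    @property
    def frequency_ratio(self) -> float:
        """Mutant reads divided by wild-type reads (inf when saturated)."""
        if self.wildtype_reads == 0:
            return float("inf") if self.mutant_reads else 0.0
        return self.mutant_reads / self.wildtype_reads

    @property
    def frequency_pct(self) -> float:
        """Mutant reads as a percentage of aligned reads (default metric)."""
        if self.aligned_reads == 0:
            return 0.0
        return 100.0 * self.mutant_reads / self.aligned_reads

    @property
    def mutant_fraction(self) -> float:
        return self.frequency_pct / 100.0

    def top_type(self) -> IndelEvent | None:
        """Most frequent retained type; ties resolve to the leftmost, then
        the lexicographically smallest event."""
        if not self.retained:
            return None
        return min(
            self.retained,
            key=lambda t: (-self.retained[t].count, t.start, t.kind, t.end, t.inserted),
        )


def tally_reads(
    reads: ReadBatch,
    site: TargetSite,
    amplicon: str,
    *,
    trim_threshold: int = DEFAULT_TRIM_THRESHOLD,
    min_read_len: int = MIN_READ_LEN,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    scoring: Scoring = Scoring(),
) -> SampleTally:
    """Trim, align and extract window indels for every read.

    Unique read sequences are aligned once; unedited full-length reads take
    a gapless fast path (a true indel shifts the downstream sequence and is
    routed to the full DP by the mismatch check).
    """
    total = len(reads)
    keep = _trim_lengths(reads.quals, trim_threshold)
    counts: Counter[str] = Counter()
    discarded = 0
    for seq, k in zip(reads.seqs, keep):
        if k < min_read_len:
            discarded += 1
        else:
            counts[seq[: int(k)]] += 1

    ref_codes = encode(amplicon)
    unaligned = 0
    aligned = 0
    window_counts: Counter[IndelEvent] = Counter()
    all_counts: Counter[IndelEvent] = Counter()
    reads_by_events: list[tuple[int, tuple[IndelEvent, ...]]] = []
    for seq, mult in counts.items():
        events = _events_for_read(seq, amplicon, ref_codes, identity_floor, scoring)
        if events is None:
            unaligned += mult
            continue
        aligned += mult
        window_events = tuple(ev for ev in events if ev.in_window(site.window))
        for ev in events:
            all_counts[ev] += mult
        for ev in window_events:
            window_counts[ev] += mult
        reads_by_events.append((mult, window_events))
    return SampleTally(total, discarded, unaligned, aligned, window_counts, all_counts, reads_by_events)


def _events_for_read(
    seq: str, amplicon: str, ref_codes: np.ndarray, identity_floor: float, scoring: Scoring
) -> list[IndelEvent] | None:
    if len(seq) <= len(amplicon):
        codes = encode(seq)
        mm = int(np.count_nonzero(codes != ref_codes[: codes.size]))
        if mm <= _FAST_PATH_MM_FRAC * codes.size:
            return []  # substitutions only
    aln = align_read(seq, amplicon, scoring, min_identity=identity_floor)
    if aln is None:
        return None
    return extract_indels(aln, seq, amplicon)


def call_sample(
    reads: ReadBatch,
    site: TargetSite,
    amplicon: str,
    control: SampleCallSet | None,
    multiplier: float = DEFAULT_MULTIPLIER,
    sample_id: str = "sample",
    **tally_kwargs,
) -> SampleCallSet:
    """Call retained indel types and mutant/wild-type reads for one sample.

    With ``control`` given, a window type is retained iff its sample
    frequency is at least ``multiplier`` times its control frequency, where
    a type unseen in the control contributes ``0.5 / control_aligned``.
    ``control=None`` produces an unfiltered call set (used to build the
    control itself).  A control with no aligned reads is an error: the
    filter is undefined without one.
    """
    if multiplier <= 1:
        raise ValueError(f"multiplier must exceed 1, got {multiplier}")
    tally = tally_reads(reads, site, amplicon, **tally_kwargs)
    if control is not None and control.aligned_reads == 0:
        raise ValueError("control call set has no aligned reads; the 30x filter is undefined")

    retained: dict[IndelEvent, RetainedType] = {}
    for ev, count in tally.window_type_counts.items():
        freq_s = count / tally.aligned_reads if tally.aligned_reads else 0.0
        if control is None:
            retained[ev] = RetainedType(count, freq_s, None)
            continue
        c_count = control.type_counts.get(ev, 0)
        freq_c = (c_count if c_count > 0 else CONTROL_PSEUDOCOUNT) / control.aligned_reads
        if freq_s >= multiplier * freq_c:
            retained[ev] = RetainedType(count, freq_s, freq_c)

    mutant = sum(
        mult for mult, events in tally.reads_by_events if any(ev in retained for ev in events)
    )
    wildtype = tally.aligned_reads - mutant
    return SampleCallSet(
        sample_id=sample_id,
        total_reads=tally.total_reads,
        trimmed_discarded=tally.trimmed_discarded,
        unaligned=tally.unaligned,
        aligned_reads=tally.aligned_reads,
        type_counts=tally.window_type_counts,
        retained=retained,
        mutant_reads=mutant,
        wildtype_reads=wildtype,
        saturated=(wildtype == 0 and mutant > 0),
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def callset_frame(callset: SampleCallSet, control: SampleCallSet | None = None,
                  multiplier: float = DEFAULT_MULTIPLIER) -> pd.DataFrame:
    """One row per window indel type; coordinates 1-based closed."""
    rows = []
    for ev, count in sorted(
        callset.type_counts.items(), key=lambda kv: (-kv[1], kv[0].start, kv[0].kind)
    ):
        freq_s = count / callset.aligned_reads if callset.aligned_reads else 0.0
        if control is not None and control.aligned_reads:
            c_count = control.type_counts.get(ev, 0)
            freq_c = (c_count if c_count > 0 else CONTROL_PSEUDOCOUNT) / control.aligned_reads
        else:
            freq_c = np.nan
        rows.append(
            {
                "sample": callset.sample_id,
                "kind": ev.kind,
                # 1-based closed; an insertion is anchored after base `start`
                "start": ev.start + 1 if ev.kind == "del" else ev.start,
                "end": ev.end,
                "length": ev.length,
                "inserted": ev.inserted,
                "count": count,
                "sample_freq": freq_s,
                "control_freq": freq_c,
                "retained": ev in callset.retained,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "kind", "start", "end", "length", "inserted",
            "count", "sample_freq", "control_freq", "retained",
        ],
    )


def write_callset_tsv(callset: SampleCallSet, path: str | Path,
                      control: SampleCallSet | None = None) -> None:
    callset_frame(callset, control).to_csv(path, sep="\t", index=False)


def callset_summary(callset: SampleCallSet) -> dict:
    ratio = callset.frequency_ratio
    return {
        "sample_id": callset.sample_id,
        "total_reads": callset.total_reads,
        "trimmed_discarded": callset.trimmed_discarded,
        "unaligned": callset.unaligned,
        "aligned_reads": callset.aligned_reads,
        "mutant_reads": callset.mutant_reads,
        "wildtype_reads": callset.wildtype_reads,
        "n_types_observed": len(callset.type_counts),
        "n_types_retained": len(callset.retained),
        "frequency_ratio": None if ratio == float("inf") else ratio,
        "frequency_pct": callset.frequency_pct,
        "saturated": callset.saturated,
    }
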