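"""T0 plant zygosity from dual leaf-punch call sets.

Maize is diploid, so a plant whose mutant-read fraction sits near 50% in
both leaf punches is presumed heterozygous and one near 100% homozygous —
in both cases carrying a germline (heritable) change — provided the same
indel type dominates both punches; discordant punches indicate a chimeric
(mosaic) plant.  Band thresholds quantify the ~50%/~100% heuristics with
±15% slack for sampling noise and residual chimerism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calling import IndelEvent, SampleCallSet

CALL_CLASSES = ("homozygous", "heterozygous", "chimeric", "wild_type")
#: Minimum aligned reads per punch for a plant to be callable.
DEFAULT_MIN_READS = 100


@dataclass(frozen=True)
class Bands:
    """Mutant-fraction bands for the four-way zygosity call."""

    hom_min: float = 0.85
    het_lo: float = 0.35
    het_hi: float = 0.65
    wt_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.wt_max < self.het_lo <= self.het_hi < self.hom_min <= 1):
            raise ValueError("bands must be ordered wt_max < het_lo <= het_hi < hom_min")


@dataclass
class PlantCall:
    plant_id: str
    punch_fractions: tuple[float, float]
    punch_top_types: tuple[IndelEvent | None, IndelEvent | None]
    call: str  # CALL_CLASSES or "insufficient_coverage"

    @property
    def edited(self) -> bool:
        return self.call in ("homozygous", "heterozygous")


def classify_plant(
    punch_a: SampleCallSet,
    punch_b: SampleCallSet,
    bands: Bands = Bands(),
    min_reads: int = DEFAULT_MIN_READS,
    plant_id: str = "plant",
) -> PlantCall:
    """Classify one plant from its two leaf-punch call sets.

    hom: both fractions >= hom_min with the same dominant retained type;
    het: both inside [het_lo, het_hi] with the same dominant type; wild
    type: both <= wt_max; anything else (including discordant punches) is
    chimeric.  Requiring a shared dominant type across punches from
    different leaves is what separates a germline edit from coincident
    somatic ones.
    """
    cov_a = punch_a.mutant_reads + punch_a.wildtype_reads
    cov_b = punch_b.mutant_reads + punch_b.wildtype_reads
    fa, fb = punch_a.mutant_fraction, punch_b.mutant_fraction
    tops = (punch_a.top_type(), punch_b.top_type())
    if cov_a < min_reads or cov_b < min_reads:
        return PlantCall(plant_id, (fa, fb), tops, "insufficient_coverage")
    same_top = tops[0] is not None and tops[0] == tops[1]
    if fa >= bands.hom_min and fb >= bands.hom_min and same_top:
        call = "homozygous"
    elif bands.het_lo <= fa <= bands.het_hi and bands.het_lo <= fb <= bands.het_hi and same_top:
        call = "heterozygous"
    elif fa <= bands.wt_max and fb <= bands.wt_max:
        call = "wild_type"
    else:
        call = "chimeric"
    return PlantCall(plant_id, (fa, fb), tops, call)


@dataclass
class CohortSummary:
    n_plants: int            # callable plants
    n_insufficient: int
    counts: dict[str, int]   # per CALL_CLASSES
    n_edited: int            # het + hom
    pct_edited: float
    zygosity_proportions: dict[str, float]  # over edited plants; empty if none
    top_types: list[tuple[IndelEvent, int, float]]  # (type, plants, share of edited)

    def to_dict(self) -> dict:
        return {
            "n_plants": self.n_plants,
            "n_insufficient": self.n_insufficient,
            "counts": dict(self.counts),
            "n_edited": self.n_edited,
            "pct_edited": self.pct_edited,
            "zygosity_proportions": dict(self.zygosity_proportions),
            "top_types": [
                {
                    "kind": t.kind,
                    "start": t.start,
                    "end": t.end,
                    "inserted": t.inserted,
                    "plants": n,
                    "share": share,
                }
                for t, n, share in self.top_types
            ],
        }


def summarize_cohort(calls: list[PlantCall], top_k: int = 10) -> CohortSummary:
    """Cohort-level edited-plant percentage, zygosity proportions, and the
    top-k indel table.

    ``pct_edited`` is (het + hom) / callable plants; zygosity proportions
    and the indel table are computed over edited plants only (a plant's
    mutation is the shared dominant type of its punches), matching the
    per-plant accounting used for cohort figures.  Plants without usable
    coverage are reported but excluded from every proportion.
    """
    if not calls:
        raise ValueError("summarize_cohort needs at least one plant call")
    callable_calls = [c for c in calls if c.call != "insufficient_coverage"]
    n_insufficient = len(calls) - len(callable_calls)
    if not callable_calls:
        raise ValueError("no plant has sufficient coverage in both punches")
    counts = {cls: 0 for cls in CALL_CLASSES}
    for c in callable_calls:
        counts[c.call] += 1
    n_edited = counts["homozygous"] + counts["heterozygous"]
    pct_edited = 100.0 * n_edited / len(callable_calls)
    proportions: dict[str, float] = {}
    if n_edited:
        proportions = {
            "homozygous": counts["homozygous"] / n_edited,
            "heterozygous": counts["heterozygous"] / n_edited,
        }
    type_counts: Counter[IndelEvent] = Counter()
    for c in callable_calls:
        if c.edited and c.punch_top_types[0] is not None:
            type_counts[c.punch_top_types[0]] += 1
    ranked = sorted(type_counts.items(), key=lambda kv: (-kv[1], kv[0].start, kv[0].kind))
    top = [(t, n, n / n_edited) for t, n in ranked[:top_k]]
    return CohortSummary(
        n_plants=len(callable_calls),
        n_insufficient=n_insufficient,
        counts=counts,
        n_edited=n_edited,
        pct_edited=pct_edited,
        zygosity_proportions=proportions,
        top_types=top,
    )


def plant_calls_frame(calls: list[PlantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        ta, tb = c.punch_top_types
        rows.append(
            {
                "plant_id": c.plant_id,
                "fraction_a": c.punch_fractions[0],
                "fraction_b": c.punch_fractions[1],
                "top_type_a": _type_str(ta),
                "top_type_b": _type_str(tb),
                "call": c.call,
            }
        )
    return pd.DataFrame(
        rows, columns=["plant_id", "fraction_a", "fraction_b", "top_type_a", "top_type_b", "call"]
    )


def write_plant_calls_tsv(calls: list[PlantCall], path: str | Path) -> None:
    plant_calls_frame(calls).to_csv(path, sep="\t", index=False)


def _type_str(t: IndelEvent | None) -> str:
    if t is None:
        return "."
    if t.kind == "del":
        return f"del:{t.start + 1}-{t.end}"
    return f"ins:{t.start}+{t.inserted}"
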