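"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design end to end: single-end reads
spanning a PCR amplicon at configurable depth, a Bernoulli true-edit
fraction whose indels centre on the expected cut site 22-24 bp 3' of the
PAM, independent per-base substitution errors plus rare 1-bp error indels,
Phred qualities with a mild 3' decay, guide-omitted negative controls,
diploid two-leaf-punch plant samples with heterozygous / homozygous /
chimeric / wild-type structure, and random genomes carrying planted
off-target sites at exact mismatch/bulge compositions.  Every generator is
bit-reproducible under a fixed seed and returns a ground-truth manifest.

Repair outcomes at a given target site are modelled as site-specific: each
simulated sample draws a small Zipf-weighted set of outcomes (default 4)
from a broad deletion-dominated spectrum, reflecting microhomology-driven
repair where a handful of products dominate a site's indel table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import IndelEvent, left_normalize
from .guides import PamPattern, TargetSite
from .io import ReadBatch
from .seq import decode, encode, revcomp

_BASES = "ACGT"


def _default_del_len_weights() -> np.ndarray:
    # deletions 1-30 bp weighted toward 2-12 bp, decaying tail beyond
    lengths = np.arange(1, 31)
    w = np.where((lengths >= 2) & (lengths <= 12), 1.0, 0.0)
    w[lengths == 1] = 0.4
    tail = lengths > 12
    w[tail] = np.exp(-(lengths[tail] - 12) / 5.0)
    return w / w.sum()


def _default_ins_len_weights() -> np.ndarray:
    return np.array([0.5, 0.2, 0.15, 0.1, 0.05])


@dataclass
class IndelSpectrum:
    """Prior over single repair products at a cut site.

    Deletions dominate (default 80%); a deletion of length L starts
    ``d`` bases left of the cut centre with ``d ~ 1 + Binomial(L-1, 1/2)``,
    so the deleted span always straddles or abuts the cut.  Insertions are
    1-5 bp of random sequence anchored within a few bases of the cut.
    """

    deletion_fraction: float = 0.8
    del_len_weights: np.ndarray = field(default_factory=_default_del_len_weights)
    ins_len_weights: np.ndarray = field(default_factory=_default_ins_len_weights)

    def sample_event(
        self, rng: np.random.Generator, site: TargetSite, amplicon: str
    ) -> IndelEvent:
        """Draw one left-normalized repair product intersecting the window."""
        for _ in range(100):
            if rng.random() < self.deletion_fraction:
                L = int(rng.choice(np.arange(1, 31), p=self.del_len_weights))
                d = 1 + int(rng.binomial(L - 1, 0.5))
                start = site.cut_center - d
                if start < 1 or start + L > len(amplicon) - 1:
                    continue
                ev = IndelEvent("del", start, start + L)
            else:
                L = int(rng.choice(np.arange(1, 6), p=self.ins_len_weights))
                anchor = site.cut_center + int(np.clip(round(rng.normal(0, 1.5)), -3, 3))
                anchor = int(np.clip(anchor, 1, len(amplicon) - 1))
                ev = IndelEvent("ins", anchor, anchor, "".join(rng.choice(list(_BASES), L)))
            ev = left_normalize(ev, amplicon)
            if ev.in_window(site.window):
                return ev
        raise RuntimeError("could not draw an indel intersecting the site window")


@dataclass
class SimConfig:
    """Study conditions for read simulation.

    ``depth`` is reads per treated sample and ``control_depth`` reads per
    negative control (controls sit at the top of the plausible
    10^4-10^5 amplicon-depth band; a deep control sets the sensitivity
    floor of the 30x background filter).  ``read_length=None`` emits
    single-end reads spanning the whole amplicon.
    """

    seed: int = 0
    depth: int = 20_000
    control_depth: int = 100_000
    read_length: int | None = None
    edit_fraction: float = 0.0
    n_repair_outcomes: int = 4
    substitution_error_rate: float = 1e-3
    error_indel_rate: float = 1e-4
    mean_quality: float = 35.0
    quality_decay: float = 8.0
    quality_sd: float = 3.0
    spectrum: IndelSpectrum = field(default_factory=IndelSpectrum)

    def __post_init__(self) -> None:
        for name in ("edit_fraction", "substitution_error_rate", "error_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth <= 0 or self.control_depth <= 0:
            raise ValueError("depths must be positive")


@dataclass
class TruthManifest:
    """Ground truth for one simulated sample; round-trips through TSV."""

    read_ids: list[str]
    edited: np.ndarray  # bool per read
    events: list[IndelEvent | None]
    true_edit_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, ed, ev in zip(self.read_ids, self.edited, self.events):
            rows.append(
                {
                    "read_id": rid,
                    "edited": int(ed),
                    "kind": ev.kind if ev else ".",
                    "start": ev.start if ev else -1,
                    "end": ev.end if ev else -1,
                    "inserted": ev.inserted if ev and ev.inserted else ".",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthManifest":
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "inserted": str})
        events: list[IndelEvent | None] = []
        for kind, start, end, ins in zip(df["kind"], df["start"], df["end"], df["inserted"]):
            if kind == ".":
                events.append(None)
            else:
                events.append(IndelEvent(kind, int(start), int(end), "" if ins == "." else ins))
        edited = df["edited"].to_numpy(dtype=bool)
        return cls(list(df["read_id"]), edited, events, float(edited.mean()) if len(df) else 0.0)


def apply_event(seq: str, ev: IndelEvent) -> str:
    if ev.kind == "del":
        return seq[: ev.start] + seq[ev.end :]
    return seq[: ev.start] + ev.inserted + seq[ev.start :]


def draw_repair_outcomes(
    rng: np.random.Generator,
    site: TargetSite,
    amplicon: str,
    n: int,
    spectrum: IndelSpectrum | None = None,
) -> tuple[list[IndelEvent], np.ndarray]:
    """Draw ``n`` distinct repair products with Zipf-like weights 1/k."""
    spectrum = spectrum or IndelSpectrum()
    outcomes: list[IndelEvent] = []
    for _ in range(200):
        ev = spectrum.sample_event(rng, site, amplicon)
        if ev not in outcomes:
            outcomes.append(ev)
        if len(outcomes) == n:
            break
    weights = 1.0 / np.arange(1, len(outcomes) + 1)
    return outcomes, weights / weights.sum()


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_CHUNK_ROWS = 16384


def _emit_group(
    rng: np.random.Generator,
    hap: str,
    n: int,
    cfg: SimConfig,
) -> tuple[list[str], list[np.ndarray]]:
    """Emit n reads of one haplotype with substitution errors, rare 1-bp
    error indels, and decaying qualities."""
    codes = encode(hap)
    L = codes.size
    frac = np.arange(L) / max(L - 1, 1)
    ramp = np.clip((frac - 0.6) / 0.4, 0.0, None)  # 3' decay over the last 40%
    base_q = cfg.mean_quality - cfg.quality_decay * ramp
    seqs: list[str] = []
    quals: list[np.ndarray] = []
    for lo in range(0, n, _CHUNK_ROWS):
        g = min(_CHUNK_ROWS, n - lo)
        mat = np.tile(codes, (g, 1))
        if cfg.substitution_error_rate > 0:
            mask = rng.random((g, L)) < cfg.substitution_error_rate
            nsub = int(mask.sum())
            if nsub:
                mat[mask] = (mat[mask] + rng.integers(1, 4, nsub)) % 4
        q = base_q + rng.normal(0.0, cfg.quality_sd, (g, L))
        q = np.clip(np.rint(q), 2, 40).astype(np.uint8)
        n_err = (
            rng.binomial(L, cfg.error_indel_rate, g)
            if cfg.error_indel_rate > 0
            else np.zeros(g, dtype=np.int64)
        )
        for r in range(g):
            seq = decode(mat[r])
            qual = q[r]
            for _ in range(int(n_err[r])):
                pos = int(rng.integers(0, len(seq)))
                if rng.random() < 0.5 and len(seq) > 1:  # 1-bp deletion
                    seq = seq[:pos] + seq[pos + 1 :]
                    qual = np.delete(qual, pos)
                else:  # 1-bp insertion
                    b = _BASES[rng.integers(0, 4)]
                    seq = seq[:pos] + b + seq[pos:]
                    qual = np.insert(qual, pos, qual[min(pos, len(qual) - 1)])
            seqs.append(seq)
            quals.append(qual)
    return seqs, quals


def simulate_amplicon_reads(
    site: TargetSite,
    amplicon: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    outcomes: tuple[list[IndelEvent], np.ndarray] | None = None,
    depth: int | None = None,
    id_prefix: str = "r",
) -> tuple[ReadBatch, TruthManifest]:
    """Simulate one treated sample over an amplicon.

    Each read is marked edited by a Bernoulli(edit_fraction) draw; edited
    reads carry one repair product from the site's outcome set, then every
    read receives sequencing errors and qualities.  Deterministic under a
    fixed seed / generator.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.depth if depth is None else depth
    if outcomes is None:
        if cfg.edit_fraction > 0:
            outcomes = draw_repair_outcomes(rng, site, amplicon, cfg.n_repair_outcomes, cfg.spectrum)
        else:
            outcomes = ([], np.array([]))
    events_pool, weights = outcomes
    for ev in events_pool:
        if ev.length >= len(amplicon):
            raise ValueError("repair indel at least as long as the amplicon")

    edited = (
        rng.random(n) < cfg.edit_fraction if cfg.edit_fraction > 0 else np.zeros(n, dtype=bool)
    )
    hap_idx = np.zeros(n, dtype=np.int64)  # 0 = wild type
    if edited.any():
        hap_idx[edited] = 1 + rng.choice(len(events_pool), size=int(edited.sum()), p=weights)
    haps = [amplicon] + [apply_event(amplicon, ev) for ev in events_pool]

    seqs: list[str | None] = [None] * n
    quals: list[np.ndarray | None] = [None] * n
    for h, hap in enumerate(haps):
        rows = np.nonzero(hap_idx == h)[0]
        if rows.size == 0:
            continue
        gseqs, gquals = _emit_group(rng, hap, rows.size, cfg)
        for r, s, q in zip(rows, gseqs, gquals):
            seqs[r] = s
            quals[r] = q

    ids = [f"{id_prefix}{i:06d}" for i in range(n)]
    batch = ReadBatch(ids, seqs, quals)  # type: ignore[arg-type]
    truth = TruthManifest(
        read_ids=ids,
        edited=edited,
        events=[events_pool[h - 1] if h else None for h in hap_idx],
        true_edit_fraction=float(edited.mean()) if n else 0.0,
    )
    return batch, truth


def simulate_negative_control(
    site: TargetSite,
    amplicon: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    id_prefix: str = "c",
) -> tuple[ReadBatch, TruthManifest]:
    """A guide-omitted control: identical emission with edit_fraction 0 at
    ``cfg.control_depth``."""
    ctrl_cfg = dataclasses.replace(cfg, edit_fraction=0.0)
    return simulate_amplicon_reads(
        site, amplicon, ctrl_cfg, rng=rng, depth=cfg.control_depth, id_prefix=id_prefix
    )


# ---------------------------------------------------------------------------
# Diploid plants
# ---------------------------------------------------------------------------

PLANT_CLASSES = ("hom", "het", "chimeric", "wt")


@dataclass
class PlantTruth:
    zygosity: str
    punch_fractions: tuple[float, float]
    punch_events: tuple[IndelEvent | None, IndelEvent | None]


@dataclass
class PlantSim:
    plant_id: str
    punches: tuple[ReadBatch, ReadBatch]
    truth: PlantTruth


def simulate_plant(
    site: TargetSite,
    amplicon: str,
    zygosity: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    plant_id: str = "plant",
) -> PlantSim:
    """Two leaf-punch read sets for one T0 plant.

    hom: both punches fully edited with one shared product; het: both at
    0.5 with one shared product; chimeric: punches drawn independently from
    Uniform(0.05, 0.95) with independently drawn products; wt: error
    background only.
    """
    if zygosity not in PLANT_CLASSES:
        raise ValueError(f"zygosity must be one of {PLANT_CLASSES}, got {zygosity!r}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    spectrum = cfg.spectrum

    if zygosity in ("hom", "het"):
        shared = spectrum.sample_event(rng, site, amplicon)
        fracs = (1.0, 1.0) if zygosity == "hom" else (0.5, 0.5)
        pools = [([shared], np.array([1.0]))] * 2
        truth_events: tuple[IndelEvent | None, IndelEvent | None] = (shared, shared)
    elif zygosity == "chimeric":
        fracs = (float(rng.uniform(0.05, 0.95)), float(rng.uniform(0.05, 0.95)))
        ev_a = spectrum.sample_event(rng, site, amplicon)
        ev_b = spectrum.sample_event(rng, site, amplicon)
        pools = [([ev_a], np.array([1.0])), ([ev_b], np.array([1.0]))]
        truth_events = (ev_a, ev_b)
    else:
        fracs = (0.0, 0.0)
        pools = [([], np.array([]))] * 2
        truth_events = (None, None)

    punches = []
    for p, (frac, pool) in enumerate(zip(fracs, pools)):
        pcfg = dataclasses.replace(cfg, edit_fraction=frac)
        batch, _ = simulate_amplicon_reads(
            site, amplicon, pcfg, rng=rng, outcomes=pool, id_prefix=f"{plant_id}_p{p}_"
        )
        punches.append(batch)
    return PlantSim(plant_id, (punches[0], punches[1]), PlantTruth(zygosity, fracs, truth_events))


def simulate_cohort(
    site: TargetSite,
    amplicon: str,
    class_counts: dict[str, int],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[PlantSim]:
    """A cohort of T0 plants; class labels are interleaved deterministically."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    labels = [z for z in PLANT_CLASSES for _ in range(class_counts.get(z, 0))]
    order = rng.permutation(len(labels))
    plants = []
    for i, k in enumerate(order):
        plants.append(
            simulate_plant(site, amplicon, labels[k], cfg, rng=rng, plant_id=f"plant{i:03d}")
        )
    return plants


# ---------------------------------------------------------------------------
# Genomes with planted off-target sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted off-target."""

    start: int
    end: int
    strand: str
    n_mismatches: int
    n_bulges: int
    bulge_kinds: tuple[str, ...]
    site_seq: str  # PAM + protospacer, guide sense


def _realize_pam(rng: np.random.Generator, pam: PamPattern) -> str:
    from .seq import IUPAC

    return "".join(rng.choice(sorted(IUPAC[sym])) for sym in pam.pattern)


def _mutate_protospacer(
    rng: np.random.Generator, proto: str, n_mm: int, n_bulges: int, kinds: tuple[str, ...]
) -> str:
    seq = list(proto)
    for kind in kinds:
        if kind == "dna":  # extra genome base
            pos = int(rng.integers(1, len(seq)))
            seq.insert(pos, _BASES[rng.integers(0, 4)])
        else:  # rna bulge: guide base skipped in the genome
            pos = int(rng.integers(0, len(seq)))
            del seq[pos]
    if n_mm:
        positions = rng.choice(len(seq), size=n_mm, replace=False)
        for pos in positions:
            old = seq[pos]
            choices = [b for b in _BASES if b != old]
            seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def plant_offtargets(
    genome_length: int,
    spacer: str,
    pam: PamPattern | str,
    spec: list[tuple],
    seed: int = 0,
    max_mm: int = 4,
    max_bulges: int = 2,
    rng: np.random.Generator | None = None,
    max_iter: int = 100,
) -> tuple[str, list[PlantedSite]]:
    """Random genome carrying planted off-targets at exact compositions.

    Each spec entry is ``(n_mismatches, n_bulges)`` or
    ``(n_mismatches, n_bulges, bulge_kind)`` with kind ``dna``/``rna``
    (extra genome base / skipped guide base; a missing kind is drawn at
    random per bulge).  The background is rejection-resampled until the
    enumeration over the whole genome at (``max_mm``, ``max_bulges``) finds
    exactly the planted sites at exactly their requested compositions.
    """
    from .offtargets import enumerate_offtargets

    pam = PamPattern(pam) if isinstance(pam, str) else pam
    spacer = spacer.upper().replace("U", "T")
    rng = np.random.default_rng(seed) if rng is None else rng
    norm_spec: list[tuple[int, int, tuple[str, ...]]] = []
    for entry in spec:
        n_mm, n_b = int(entry[0]), int(entry[1])
        if n_mm > max_mm or n_b > max_bulges:
            raise ValueError(f"requested composition {entry} exceeds search limits")
        if n_b >= len(spacer):
            raise ValueError("more bulges than spacer positions")
        if len(entry) > 2:
            kinds = tuple([entry[2]] * n_b)
        else:
            kinds = tuple(str(rng.choice(["dna", "rna"])) for _ in range(n_b))
        norm_spec.append((n_mm, n_b, kinds))

    slot_span = len(pam) + len(spacer) + max_bulges + 20
    if (len(norm_spec) + 1) * 2 * slot_span > genome_length:
        raise ValueError("genome too short for the requested number of sites")

    genome = list(rng.choice(list(_BASES), genome_length))
    # evenly spaced slots with jitter keep planted sites well separated
    step = genome_length // (len(norm_spec) + 1)
    placements: list[dict] = []
    for i, (n_mm, n_b, kinds) in enumerate(norm_spec):
        pos = (i + 1) * step - slot_span // 2 + int(rng.integers(-step // 4, step // 4 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append(
            {"pos": pos, "strand": strand, "n_mm": n_mm, "n_b": n_b, "kinds": kinds}
        )

    def write_site(pl: dict) -> PlantedSite:
        proto = _mutate_protospacer(rng, spacer, pl["n_mm"], pl["n_b"], pl["kinds"])
        full = _realize_pam(rng, pam) + proto
        pos = pl["pos"]
        if pl["strand"] == "+":
            genome[pos : pos + len(full)] = list(full)
            start = pos + len(pam)
            end = start + len(proto)
        else:
            rc = revcomp(full)
            genome[pos : pos + len(full)] = list(rc)
            start = pos
            end = pos + len(proto)
        return PlantedSite(start, end, pl["strand"], pl["n_mm"], pl["n_b"], pl["kinds"], full)

    planted = [write_site(pl) for pl in placements]

    for _ in range(max_iter):
        gstr = "".join(genome)
        hits = enumerate_offtargets(gstr, spacer, pam, max_mm=max_mm, max_bulges=max_bulges)
        expected = {(p.strand, p.start): i for i, p in enumerate(planted)}
        ok = True
        seen: set[tuple[str, int]] = set()
        for hit in hits:
            key = (hit.strand, hit.start)
            if key in expected:
                seen.add(key)
                p = planted[expected[key]]
                if (hit.n_bulges, hit.n_mismatches) != (p.n_bulges, p.n_mismatches):
                    # composition collapsed (e.g. an inserted base re-alignable
                    # with fewer differences) -> re-realize this site
                    planted[expected[key]] = write_site(placements[expected[key]])
                    ok = False
            else:
                # spurious background hit: resample its neighbourhood unless it
                # overlaps a planted region, in which case re-realize the site
                lo, hi = max(0, hit.start - 30), min(genome_length, hit.end + 30)
                overlap = [
                    i for i, p in enumerate(planted) if p.start < hi + 10 and p.end > lo - 10
                ]
                if overlap:
                    for i in overlap:
                        planted[i] = write_site(placements[i])
                else:
                    genome[lo:hi] = list(rng.choice(list(_BASES), hi - lo))
                ok = False
        if ok and len(seen) == len(planted):
            return gstr, planted
        if ok:  # a planted site vanished entirely; re-realize the missing ones
            for key, i in expected.items():
                if key not in seen:
                    planted[i] = write_site(placements[i])
    raise RuntimeError("could not realize the requested off-target spec; relax it or enlarge the genome")
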