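"""TOML run configuration.

A run config declares the target site (amplicon, spacer, PAM), simulation
conditions, and threshold overrides.  Every threshold default equals the
value the analysis is built around: Phred 13 trimming, the 30x control
multiplier, the 12-bp cut window, 5 unique reads and >20% mutant fraction
for off-target screening, 16-nt minimum spacers, and the 22-24 bp cut
offset (default 23).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .guides import DEFAULT_CUT_OFFSET, DEFAULT_WINDOW_WIDTH, PamPattern, TargetSite
from .simulate import SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class Thresholds:
    trim_quality: int = 13
    control_multiplier: float = 30.0
    window_width: int = DEFAULT_WINDOW_WIDTH
    cut_offset: int = DEFAULT_CUT_OFFSET
    min_spacer_len: int = 16
    min_screen_reads: int = 5
    screen_mutant_fraction: float = 0.20
    max_mismatches: int = 4
    max_bulges: int = 2
    min_punch_reads: int = 100

    def validate(self) -> None:
        if self.control_multiplier <= 1:
            raise ConfigError(f"control_multiplier must exceed 1, got {self.control_multiplier}")
        if not 22 <= self.cut_offset <= 24:
            raise ConfigError(f"cut_offset must lie in 22..24, got {self.cut_offset}")
        if self.window_width <= 0 or self.window_width % 2:
            raise ConfigError(f"window_width must be positive and even, got {self.window_width}")
        for name in ("trim_quality", "min_screen_reads", "min_punch_reads",
                     "max_mismatches", "max_bulges", "min_spacer_len"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 < self.screen_mutant_fraction < 1:
            raise ConfigError("screen_mutant_fraction must lie in (0, 1)")


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    amplicon_id: str
    amplicon: str
    spacer: str
    pam: str
    pam_start: int
    strand: str
    sim: SimConfig
    thresholds: Thresholds
    cohort: dict[str, int] = field(default_factory=dict)
    offtarget_genome_length: int = 20_000
    offtarget_spec: list[tuple] = field(default_factory=lambda: [(0, 0), (2, 0), (2, 1)])
    raw: dict[str, Any] = field(default_factory=dict)

    def site(self) -> TargetSite:
        return TargetSite.from_guide(
            self.amplicon_id,
            self.amplicon,
            self.spacer,
            PamPattern(self.pam),
            self.pam_start,
            self.strand,
            offset=self.thresholds.cut_offset,
            width=self.thresholds.window_width,
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parse_config(data, base=path.parent)


def parse_config(data: dict[str, Any], base: Path = Path(".")) -> RunConfig:
    try:
        run = data.get("run", {})
        amp = data["amplicon"]
        guide = data["guide"]
    except KeyError as exc:
        raise ConfigError(f"missing config section: {exc}") from exc

    thresholds = Thresholds(**data.get("thresholds", {}))
    thresholds.validate()

    if "sequence" in amp:
        amplicon = str(amp["sequence"]).upper()
    elif "fasta" in amp:
        from .io import read_fasta

        fasta = read_fasta(base / amp["fasta"])
        key = amp.get("id") or next(iter(fasta))
        if key not in fasta:
            raise ConfigError(f"amplicon {key!r} not found in {amp['fasta']}")
        amplicon = fasta[key]
    else:
        raise ConfigError("amplicon section needs 'sequence' or 'fasta'")

    sim_kwargs = dict(data.get("simulate", {}))
    sim_kwargs.setdefault("seed", int(run.get("seed", 0)))
    try:
        sim = SimConfig(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [simulate] section: {exc}") from exc

    cohort = {k: int(v) for k, v in data.get("cohort", {}).items()}
    ot = data.get("offtargets", {})
    spec = [tuple(entry) for entry in ot.get("spec", [(0, 0), (2, 0), (2, 1)])]

    cfg = RunConfig(
        seed=int(run.get("seed", 0)),
        outdir=base / run.get("outdir", "ampcas_out"),
        amplicon_id=str(amp.get("id", "amplicon")),
        amplicon=amplicon,
        spacer=str(guide["spacer"]).upper().replace("U", "T"),
        pam=str(guide.get("pam", "TTC")).upper(),
        pam_start=int(guide["pam_start"]),
        strand=str(guide.get("strand", "+")),
        sim=sim,
        thresholds=thresholds,
        cohort=cohort,
        offtarget_genome_length=int(ot.get("genome_length", 20_000)),
        offtarget_spec=spec,
        raw=data,
    )
    cfg.site()  # validates the guide declaration up front
    return cfg
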