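# Methods

This note records the models, parameter choices and numerical conventions
behind `ampcas`, and what the synthetic-data layer does and does not
emulate.

## Site geometry

A target site is a PAM interval on the amplicon top strand plus the
protospacer strand.  Cas12f1 PAMs sit 5' of the protospacer (SpCas12f1
TTC, AsCas12f1 YTTN, both expressible as IUPAC patterns).  Run-off
sequencing places the cut 22–24 bp downstream of the PAM; we take the
midpoint, δ = 23, as the default cut offset (configurable per nuclease
within 22–24) and score editing in a 12-bp window centred on the cut.
Coordinates are 0-based half-open internally and 1-based closed in
written tables; the cut centre is an inter-base coordinate.  On the
minus strand the geometry mirrors toward decreasing top-strand
coordinates.  Spacers shorter than 16 nt are rejected (the enzyme
requires ≥ 16 nt for double-strand cleavage).

Guide architecture: the single guide concatenates
tracrRNA–linker–repeat–spacer with a 4-nt linker.  The junction order is
a package convention (configurable); only the linker length and the
component inventory are constrained by the biology.  The repeat:anti-repeat
duplex finder scans every tracr window for the best *ungapped* antiparallel
pairing, scoring Watson–Crick pairs 2, G:U wobbles 1, mismatches −2.  The
scoring and the no-internal-loop simplification are package choices — the
native duplex may well contain loops; the ungapped model is a deliberate
simplification, not an inference.  Pileup species calling (crRNA/tracrRNA
discovery from coverage tracks) thresholds positions at k = 10 times the
track median and merges runs across gaps ≤ 5; both values are package
conventions standing in for what was originally visual inspection.

## Read model

Single-end reads span the whole amplicon (amplicons in this assay design
are at most about twice the read length, so merged or long single reads
cover them).  Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| depth per treated sample | 20,000 | inside the plausible 10⁴–10⁵ amplicon band |
| depth per negative control | 100,000 | top of the band; see below |
| substitution error | 1e-3 / base | Illumina-class |
| error indels | 1e-4 / base, 1 bp | polymerase slippage / rare miscalls |
| base quality | mean Q35, −8 over the last 40%, sd 3 | mild 3' decay |
| edited indel spectrum | 80% deletions; lengths 1–30 weighted to 2–12; insertions 1–5 bp | deletion-dominated repair spanning the cut |
| repair outcomes per sample | 4, Zipf-weighted (1, 1/2, 1/3, 1/4) | see below |

Deletion placement: a length-L deletion starts d bases left of the cut
with d ~ 1 + Binomial(L−1, ½), so the deleted span straddles or abuts the
cut centre.  Insertions anchor within ±3 bp of the cut.  All truth events
are left-normalized before being recorded, so calling output is directly
comparable to the manifest.

**Site-specific repair outcomes.**  Each simulated sample draws a small
set of distinct repair products (default 4) from the broad spectrum and
gives them Zipf-like weights.  Real repair at a given site is
microhomology-driven: a handful of products dominate its indel table, as
top-10 allele tables from edited cohorts show.  A spectrum in which every
edited read drew an independent product would make every type a
singleton, which no per-type background filter could ever retain — the
concentration is biology, not a tuning knob.

**Deep negative controls.**  With the 0.5 pseudocount, a type absent from
a control of n_c aligned reads is retained only when its sample count
reaches 30·0.5·n_s/n_c.  The control depth therefore *is* the filter's
sensitivity floor: at n_s = n_c = 20,000 the floor is 15 reads per type,
unreachable for a 0.1% edit (~20 edited reads in total); at n_c = 100,000
the floor is 3 reads.  Controls default to 100,000 reads — the top of the
plausible depth band, equivalent to pooling a few control replicates —
because background characterisation is exactly what controls are for.

**Detection limit.**  1-bp indel types also arise from sequencing error,
so they have nonzero control frequency and a correspondingly higher
retention bar (≈ 60 reads at the default depths).  A 0.1% sample whose
dominant repair product happens to be a 1-bp type loses it to the filter;
across seeds the recovered mean at p = 0.001 therefore sits ~20–30% below
truth while remaining within 3 binomial SE.  This is the method's real
behaviour at its detection limit, shared with the filter it re-implements.

What the generator does **not** model: position-dependent Illumina error
profiles, homopolymer errors, PCR chimeras and duplicates, index hopping,
paired-end overlap merging, UMI structure.  Passing tests demonstrate the
pipeline's statistical behaviour under an idealised error model, not
robustness to those artefacts.

## Trimming, alignment, normalization

Quality trimming is the 3' running-sum rule at Phred 13: cut where
Σ(13 − q) from the 3' end is maximal, keep everything if no positive sum
exists, resolve ties toward the longest read.  Reads shorter than 30 nt
after trimming are discarded (the 30-nt floor is a package choice).

Alignment is semi-global (read global, free end-gaps on the amplicon)
with affine scoring +2/−3/−6/−1; a length-k gap costs 6 + k.  The scoring
values are package conventions, exposed in configuration.  Traceback
prefers diagonal, then deletion, then insertion; extracted events are
then left-shifted while the flanking base equals the event's last base,
so all equivalent gap placements in homopolymers/repeats yield one
canonical event.  Reads below 60% identity count as unaligned.  Unedited
full-length reads take a gapless fast path guarded by a 5% mismatch
ceiling; a genuine indel shifts the downstream sequence past that ceiling
and is routed to the full DP.  (The rare error indel within a few bases
of the 3' end can be absorbed as mismatches — a negligible, symmetric
effect on samples and controls.)  The DP is numba-jitted and unique read
sequences are aligned once.

Window membership: deletions by interval intersection, insertions by
anchor containment (closed).  Intersection rather than containment is
deliberate — observed deletions commonly span the whole window.  Reads
whose only indels are filtered types count as wild type, on the view that
those indels are background.  The mutant/wild-type *ratio* is reported
alongside the mutant *percentage* of aligned reads; the percentage is the
default display metric.  A sample with zero wild-type reads is flagged
saturated rather than given an infinite-looking percentage.

## Zygosity

Band thresholds quantify the ~100%/~50% heuristics: homozygous ≥ 0.85 in
both punches, heterozygous 0.35–0.65 in both, wild type ≤ 0.05 in both,
otherwise chimeric; ±15% slack absorbs binomial sampling and residual
somatic mosaicism.  Homozygous and heterozygous calls additionally
require the same dominant retained type in both punches — the punches
come from different leaves precisely so that coincident somatic edits do
not masquerade as germline ones.  Punches under 100 aligned reads render
a plant uncallable; such plants are reported but excluded from every
proportion and never counted as edited.  Cohort percentages follow
per-plant accounting: pct edited = (het + hom)/callable plants; zygosity
proportions and the top-k mutation table are computed over edited plants.

## Off-target search

A bulge is an alignment gap on either sequence: DNA bulge = extra genome
base, RNA bulge = skipped guide base; the mismatch+bulge taxonomy maps
onto (mismatch, gap) counts of a unit-cost DP over states (gaps used,
guide consumed, genome consumed), band width = the bulge limit, run
against the |spacer| + max_bulges window behind every PAM occurrence on
both strands (regex with lookahead, so overlapping PAMs all count;
genomic N never matches anything).  Among qualifying alignments the site
keeps the lexicographically minimal (gaps, mismatches, footprint) — the
minimal-distortion interpretation — and each PAM occurrence contributes
one candidate.  Both bulges may sit on the same sequence.  Tests prove
the scan identical to an exhaustive alignment-enumeration oracle on
planted 50-kb genomes.

Cut windows for bulged alignments are measured on the genome from the
PAM 3' end (a choice; the guide-side measurement would differ by the
bulge count).  Screening verdicts: ≥ 5 uniquely assigned reads
(uniqueness = best locus score beats the runner-up by ≥ 10; the margin is
a package stand-in for a mapper's uniqueness flag), mutant fraction
strictly > 20% in the 12-bp window, and a control fraction ≤ 0.5% — the
"absent from controls" requirement is given an error-rate-sized floor
rather than a literal zero.

The planted-genome generator realizes each requested (mismatch, bulge)
composition exactly, verifying every planted site against the enumerator
and rejection-resampling background neighbourhoods that spawn spurious
hits, so the truth manifest is exact by construction.

## Problem sizes and determinism

Every generator consumes a numpy `Generator`; a single seed reproduces
every read, quality and genome byte-for-byte.  The statistical test
suite uses: 3 × 20 seeded samples at 20,000 reads for edit-fraction
recovery; 100 seeds at 5,000/25,000 (sample/control) reads for background
suppression — the default 1:5 sample:control ratio at reduced scale, so
the filter-floor arithmetic is unchanged; 200 plants at 1,000 reads per
punch for zygosity; a 50-kb genome with 20 planted sites for the
enumeration oracle.  `scripts/acceptance.py` recomputes the same
quantities at the same sizes from a command-line seed.

## Known limitations

- Substitution (base-editing) outcomes, large rearrangements and
  amplicon-spanning deletions are out of scope; one indel per edited read
  is simulated.
- The ungapped duplex model cannot represent internal loops in the
  repeat:anti-repeat pairing.
- Ploidy > 2 and T1 heritability confirmation are out of scope; "edited"
  means predicted-germline from leaf tissue.
- The off-target screen assumes reads are pre-assigned to loci;
  genome-scale read mapping is the concern of a mapper, not this package.
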