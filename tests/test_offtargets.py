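"""Off-target enumeration vs an exhaustive oracle; read-level screening."""

import numpy as np
import pytest

import ampcas as ac
from ampcas.seq import IUPAC, revcomp

from conftest import batch_from_seqs


# ---------------------------------------------------------------------------
# Independent oracle: DFS over every alignment at every position
# ---------------------------------------------------------------------------

def oracle_best_alignment(spacer, window, max_mm, max_bulges):
    """All alignments by recursion; minimal (gaps, mismatches, footprint)."""
    results = []

    def rec(i, j, mm, gaps):
        if mm > max_mm or gaps > max_bulges:
            return
        if i == len(spacer):
            results.append((gaps, mm, j))
            return
        if j < len(window):
            hit = spacer[i] == window[j] and window[j] in "ACGT"
            rec(i + 1, j + 1, mm + (0 if hit else 1), gaps)
            rec(i, j + 1, mm, gaps + 1)  # extra genome base (DNA bulge)
        rec(i + 1, j, mm, gaps + 1)      # skipped guide base (RNA bulge)

    rec(0, 0, 0, 0)
    return min(results) if results else None


def oracle_scan(genome: str, spacer: str, pam: str, max_mm: int, max_bulges: int):
    """Brute-force site set over both strands, PAM checked by set membership."""
    out = set()
    N = len(genome)
    for strand in "+-":
        s = genome if strand == "+" else revcomp(genome)
        for p in range(N - len(pam) + 1):
            window_pam = s[p : p + len(pam)]
            if any(b == "N" or b not in IUPAC[sym] for b, sym in zip(window_pam, pam)):
                continue
            wstart = p + len(pam)
            window = s[wstart : wstart + len(spacer) + max_bulges]
            if len(window) < len(spacer) - max_bulges:
                continue
            best = oracle_best_alignment(spacer, window, max_mm, max_bulges)
            if best is None:
                continue
            gaps, mm, j = best
            lo, hi = wstart, wstart + j
            if strand == "+":
                out.add((lo, hi, "+", mm, gaps))
            else:
                out.add((N - hi, N - lo, "-", mm, gaps))
    return out


def as_site_set(candidates):
    return {(c.start, c.end, c.strand, c.n_mismatches, c.n_bulges) for c in candidates}


class TestEnumerate:
    def test_exact_protospacer_found(self, spacer):
        rng = np.random.default_rng(31)
        genome = "".join(rng.choice(list("ACGT"), 300))
        genome = genome[:100] + "TTC" + spacer + genome[100:]
        hits = [h for h in ac.enumerate_offtargets(genome, spacer, "TTC")
                if h.n_differences == 0]
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (103, 123, "+")
        assert h.pam_seq == "TTC" and h.protospacer == spacer
        assert h.cut_center == 103 + 23
        assert h.window == (h.cut_center - 6, h.cut_center + 6)

    def test_pam_gate(self, spacer):
        rng = np.random.default_rng(32)
        genome = "".join(rng.choice(list("AC"), 200))  # PAM-free background
        genome = genome[:80] + "GGG" + spacer + genome[80:]
        assert ac.enumerate_offtargets(genome, spacer, "TTC", max_mm=0, max_bulges=0) == []

    def test_short_spacer_and_empty_genome(self, spacer):
        with pytest.raises(ValueError):
            ac.enumerate_offtargets("ACGT" * 100, "ACGTACGTACGT", "TTC")
        assert ac.enumerate_offtargets("", spacer, "TTC") == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle_on_random_genomes(self, spacer, seed):
        genome, _ = ac.plant_offtargets(
            3000, spacer, "TTC", [(1, 0), (2, 1), (0, 2)], seed=40 + seed,
            max_mm=2, max_bulges=2,
        )
        hits = ac.enumerate_offtargets(genome, spacer, "TTC", max_mm=2, max_bulges=2)
        assert as_site_set(hits) == oracle_scan(genome, spacer, "TTC", 2, 2)

    def test_monotone_in_limits(self, spacer):
        genome, _ = ac.plant_offtargets(
            6000, spacer, "TTC", [(0, 0), (1, 1), (3, 2)], seed=50,
            max_mm=3, max_bulges=2,
        )
        def keys(mm, b):
            return {(c.start, c.strand)
                    for c in ac.enumerate_offtargets(genome, spacer, "TTC", mm, b)}

        assert keys(0, 0) <= keys(1, 0) <= keys(2, 1) <= keys(3, 2) <= keys(4, 2)

    def test_n_positions_never_match(self, spacer):
        genome = "A" * 50 + "TTC" + spacer[:10] + "N" + spacer[11:] + "A" * 50
        hits = ac.enumerate_offtargets(genome, spacer, "TTC", max_mm=0, max_bulges=0)
        assert hits == []
        hits = ac.enumerate_offtargets(genome, spacer, "TTC", max_mm=1, max_bulges=0)
        assert len(hits) == 1 and hits[0].n_mismatches == 1

    def test_candidate_invariants(self, spacer):
        genome, _ = ac.plant_offtargets(6000, spacer, "TTC",
                                        [(0, 0), (2, 2), (4, 1)], seed=51)
        for c in ac.enumerate_offtargets(genome, spacer, "TTC"):
            assert c.n_mismatches + c.n_bulges <= 6
            assert len(c.bulge_kinds) == c.n_bulges
            assert ac.match_pam(c.pam_seq, "TTC")
            sl = genome[c.start : c.end]
            assert (sl if c.strand == "+" else revcomp(sl)) == c.protospacer


def _locus_reads(locus, window, n_total, n_mutant, deletion_len=4):
    """Reads over a screening locus; mutant reads carry one window deletion."""
    mid = (window[0] + window[1]) // 2
    mutant = locus[: mid - deletion_len // 2] + locus[mid + deletion_len - deletion_len // 2 :]
    return batch_from_seqs([mutant] * n_mutant + [locus] * (n_total - n_mutant))


@pytest.fixture(scope="module")
def candidate(spacer):
    genome, _ = ac.plant_offtargets(2000, spacer, "TTC", [(1, 0)], seed=60)
    cand = ac.enumerate_offtargets(genome, spacer, "TTC")[0]
    lo = max(0, cand.window[0] - 60)
    hi = min(len(genome), cand.window[1] + 60)
    return cand, genome[lo:hi], lo


class TestScreen:
    def test_below_five_reads_is_insufficient(self, candidate):
        cand, locus, lo = candidate
        win = (cand.window[0] - lo, cand.window[1] - lo)
        reads = _locus_reads(locus, win, 4, 4)
        verdict = ac.screen_candidate(cand, reads, batch_from_seqs([locus] * 50),
                                      locus, locus_start=lo)
        assert verdict.verdict == "insufficient_coverage"
        assert verdict.n_unique_reads == 4

    def test_quarter_mutant_with_clean_control_flagged(self, candidate):
        cand, locus, lo = candidate
        win = (cand.window[0] - lo, cand.window[1] - lo)
        verdict = ac.screen_candidate(
            cand, _locus_reads(locus, win, 100, 25),
            batch_from_seqs([locus] * 100), locus, locus_start=lo,
        )
        assert verdict.verdict == "putative_edit"
        assert verdict.mutant_fraction == pytest.approx(0.25)

    def test_exactly_twenty_percent_not_flagged(self, candidate):
        """The rule is strictly greater than 20%."""
        cand, locus, lo = candidate
        win = (cand.window[0] - lo, cand.window[1] - lo)
        verdict = ac.screen_candidate(
            cand, _locus_reads(locus, win, 100, 20),
            batch_from_seqs([locus] * 100), locus, locus_start=lo,
        )
        assert verdict.verdict == "clean"

    def test_dirty_control_suppresses_call(self, candidate):
        cand, locus, lo = candidate
        win = (cand.window[0] - lo, cand.window[1] - lo)
        verdict = ac.screen_candidate(
            cand, _locus_reads(locus, win, 100, 25),
            _locus_reads(locus, win, 100, 25), locus, locus_start=lo,
        )
        assert verdict.verdict == "clean"
        assert verdict.control_mutant_fraction == pytest.approx(0.25)

    def test_ambiguous_reads_fail_uniqueness(self, candidate):
        """Reads mapping equally well to a near-identical alt locus do not
        count toward coverage."""
        cand, locus, lo = candidate
        win = (cand.window[0] - lo, cand.window[1] - lo)
        reads = _locus_reads(locus, win, 30, 10)
        verdict = ac.screen_candidate(
            cand, reads, batch_from_seqs([locus] * 50), locus, locus_start=lo,
            alt_refs=(locus,),  # perfect decoy: zero score margin
        )
        assert verdict.verdict == "insufficient_coverage"
        assert verdict.n_unique_reads == 0
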