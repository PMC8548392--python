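"""Generators: determinism, truth manifests, error models, planted genomes."""

import dataclasses

import numpy as np
import pytest

import ampcas as ac
from ampcas.calling import extract_indels
from ampcas.seq import revcomp
from ampcas.simulate import apply_event


class TestAmpliconReads:
    def test_bit_reproducible_under_seed(self, site, amplicon):
        cfg = ac.SimConfig(seed=11, depth=500, edit_fraction=0.3)
        a, ta = ac.simulate_amplicon_reads(site, amplicon, cfg)
        b, tb = ac.simulate_amplicon_reads(site, amplicon, cfg)
        assert a.seqs == b.seqs
        assert all((qa == qb).all() for qa, qb in zip(a.quals, b.quals))
        assert (ta.edited == tb.edited).all()

    def test_no_edits_no_error_indels_means_no_indels(self, site, amplicon):
        cfg = ac.SimConfig(seed=3, depth=300, edit_fraction=0.0, error_indel_rate=0.0)
        reads, truth = ac.simulate_amplicon_reads(site, amplicon, cfg)
        assert not truth.edited.any()
        assert all(len(s) == len(amplicon) for s in reads.seqs)
        for seq in set(reads.seqs):
            aln = ac.align_read(seq, amplicon)
            assert not extract_indels(aln, seq, amplicon)

    def test_edited_count_within_binomial_bound(self, site, amplicon):
        n, p = 2000, 0.5
        cfg = ac.SimConfig(seed=4, depth=n, edit_fraction=p)
        _, truth = ac.simulate_amplicon_reads(site, amplicon, cfg)
        assert abs(truth.edited.sum() - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_truth_indels_intersect_window(self, site, amplicon):
        cfg = ac.SimConfig(seed=5, depth=400, edit_fraction=0.8)
        _, truth = ac.simulate_amplicon_reads(site, amplicon, cfg)
        for ev in truth.events:
            if ev is not None:
                assert ev.in_window(site.window)

    def test_manifest_tsv_roundtrip(self, site, amplicon, tmp_path):
        cfg = ac.SimConfig(seed=6, depth=100, edit_fraction=0.5)
        _, truth = ac.simulate_amplicon_reads(site, amplicon, cfg)
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        back = ac.TruthManifest.from_tsv(path)
        assert back.read_ids == truth.read_ids
        assert (back.edited == truth.edited).all()
        assert back.events == truth.events

    def test_fastq_roundtrip_phred33(self, site, amplicon, tmp_path):
        cfg = ac.SimConfig(seed=7, depth=50, edit_fraction=0.2)
        reads, _ = ac.simulate_amplicon_reads(site, amplicon, cfg)
        path = tmp_path / "reads.fastq"
        ac.write_fastq(reads, path)
        text = path.read_text().splitlines()
        assert len(text) == 4 * len(reads) and text[0].startswith("@") and text[2] == "+"
        back = ac.read_fastq(path)
        assert back.seqs == reads.seqs
        assert all((a == b).all() for a, b in zip(back.quals, reads.quals))

    def test_oversized_indel_rejected(self, site, amplicon):
        huge = ac.IndelEvent("del", 0, len(amplicon))
        cfg = ac.SimConfig(seed=1, depth=10, edit_fraction=1.0)
        with pytest.raises(ValueError):
            ac.simulate_amplicon_reads(site, amplicon, cfg,
                                       outcomes=([huge], np.array([1.0])))


class TestNegativeControl:
    def test_error_indel_rate_matches_configuration(self, site, amplicon):
        """Mean error indels per read within 3 SE of rate * length."""
        cfg = ac.SimConfig(seed=8, depth=100, control_depth=20_000,
                           error_indel_rate=2e-3, substitution_error_rate=0.0)
        reads, _ = ac.simulate_negative_control(site, amplicon, cfg)
        n_indels = sum(len(s) != len(amplicon) for s in reads.seqs)
        # a read's length differs unless its (rare) events cancel: the
        # dominant canceller is one deletion + one insertion, probability
        # P(exactly 2) * 1/2 under the 50/50 kind draw
        lam = len(amplicon) * cfg.error_indel_rate
        p_any = 1 - np.exp(-lam)
        p_cancel = np.exp(-lam) * lam**2 / 2 * 0.5
        exp_reads = cfg.control_depth * (p_any - p_cancel)
        assert abs(n_indels - exp_reads) <= 3 * np.sqrt(exp_reads)

    def test_control_is_edit_free_and_deterministic(self, site, amplicon):
        cfg = ac.SimConfig(seed=9, depth=100, control_depth=500, edit_fraction=0.9)
        a, truth = ac.simulate_negative_control(site, amplicon, cfg)
        b, _ = ac.simulate_negative_control(site, amplicon, cfg)
        assert not truth.edited.any() and len(a) == 500
        assert a.seqs == b.seqs


class TestPlants:
    def test_hom_plant_without_errors_is_fully_mutant(self, site, amplicon):
        cfg = ac.SimConfig(seed=10, depth=300, substitution_error_rate=0.0,
                           error_indel_rate=0.0)
        plant = ac.simulate_plant(site, amplicon, "hom", cfg)
        ev = plant.truth.punch_events[0]
        assert plant.truth.punch_fractions == (1.0, 1.0)
        expected = apply_event(amplicon, ev)
        for punch in plant.punches:
            assert set(punch.seqs) == {expected}

    def test_het_fraction_within_binomial_bound(self, site, amplicon):
        cfg = ac.SimConfig(seed=11, depth=1000)
        plant = ac.simulate_plant(site, amplicon, "het", cfg)
        se = np.sqrt(0.25 / 1000)
        for punch in plant.punches:
            frac = sum(len(s) != len(amplicon) for s in punch.seqs) / len(punch)
            assert abs(frac - 0.5) <= 3 * se + 0.01  # small error-indel allowance

    def test_wt_plant_background_bounded(self, site, amplicon):
        cfg = ac.SimConfig(seed=12, depth=1000)
        plant = ac.simulate_plant(site, amplicon, "wt", cfg)
        cap = 10 * cfg.error_indel_rate * len(amplicon)
        for punch in plant.punches:
            frac = sum(len(s) != len(amplicon) for s in punch.seqs) / len(punch)
            assert frac <= cap

    def test_het_and_hom_share_one_type_across_punches(self, site, amplicon):
        cfg = ac.SimConfig(seed=13, depth=50)
        for z in ("hom", "het"):
            plant = ac.simulate_plant(site, amplicon, z, cfg)
            assert plant.truth.punch_events[0] == plant.truth.punch_events[1]

    def test_unknown_zygosity_rejected(self, site, amplicon):
        with pytest.raises(ValueError):
            ac.simulate_plant(site, amplicon, "triploid", ac.SimConfig(depth=10))

    def test_cohort_composition(self, site, amplicon):
        cfg = ac.SimConfig(seed=14, depth=50)
        plants = ac.simulate_cohort(site, amplicon, {"hom": 3, "wt": 2}, cfg)
        labels = sorted(p.truth.zygosity for p in plants)
        assert labels == ["hom", "hom", "hom", "wt", "wt"]


class TestPlantedOfftargets:
    def test_exact_site_planted_once(self, spacer):
        genome, planted = ac.plant_offtargets(4000, spacer, "TTC", [(0, 0)], seed=21)
        assert len(planted) == 1 and planted[0].n_mismatches == 0
        proto = genome[planted[0].start : planted[0].end]
        if planted[0].strand == "-":
            proto = revcomp(proto)
        assert proto == spacer
        hits = ac.enumerate_offtargets(genome, spacer, "TTC")
        assert len(hits) == 1 and hits[0].n_differences == 0

    def test_requested_composition_realized(self, spacer):
        genome, planted = ac.plant_offtargets(
            8000, spacer, "TTC", [(2, 1), (1, 2, "dna")], seed=22
        )
        by_key = {(p.strand, p.start): p for p in planted}
        hits = ac.enumerate_offtargets(genome, spacer, "TTC")
        assert len(hits) == 2
        for hit in hits:
            truth = by_key[(hit.strand, hit.start)]
            assert (hit.n_mismatches, hit.n_bulges) == (truth.n_mismatches, truth.n_bulges)
        dna_site = next(p for p in planted if p.n_bulges == 2)
        assert dna_site.bulge_kinds == ("dna", "dna")

    def test_strand_mirror(self, spacer):
        genome, planted = ac.plant_offtargets(4000, spacer, "TTC", [(1, 0)], seed=23)
        hits_fwd = ac.enumerate_offtargets(genome, spacer, "TTC")
        hits_rev = ac.enumerate_offtargets(revcomp(genome), spacer, "TTC")
        N = len(genome)
        mirrored = {(N - h.end, N - h.start, "-" if h.strand == "+" else "+",
                     h.n_mismatches, h.n_bulges) for h in hits_rev}
        original = {(h.start, h.end, h.strand, h.n_mismatches, h.n_bulges)
                    for h in hits_fwd}
        assert mirrored == original

    def test_infeasible_spec_rejected(self, spacer):
        with pytest.raises(ValueError):
            ac.plant_offtargets(4000, spacer, "TTC", [(5, 0)], seed=1)
        with pytest.raises(ValueError):
            ac.plant_offtargets(200, spacer, "TTC", [(0, 0)] * 20, seed=1)
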