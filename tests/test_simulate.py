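"""Generator contracts: determinism, planted geometry, count model."""

import numpy as np
import pytest

from dictymir.formats import revcomp
from dictymir.simulate import (
    GENOTYPES,
    TIMEPOINTS,
    SimScenario,
    simulate_coverage,
    simulate_genome,
    simulate_small_reads,
    simulate_tailed_reads,
)


class TestGenome:
    def test_deterministic_byte_for_byte(self, small_scenario):
        a = simulate_genome(small_scenario)[0]
        b = simulate_genome(small_scenario)[0]
        assert a.sequence == b.sequence

    def test_no_mirna_loci_gives_background_plus_repeats(self):
        sc = SimScenario(seed=3, genome_length=15_000, n_mirna_loci=0,
                         n_mor_loci=0, n_readthrough_loci=0, n_decoy_hairpins=0)
        _, features, truth = simulate_genome(sc)
        assert truth.mirna_loci() == []
        assert any(f.ftype == "DIRS1" for f in features)

    def test_arm_partner_regions_are_reverse_complements(self, small_sim):
        segment, _, truth = small_sim
        for locus in truth.mirna_loci():
            arm5 = segment.slice(*locus.mir5p, strand=locus.strand)
            hs, he = locus.hairpin
            # the region pairing mir5p is its reverse complement, offset by
            # the 2-nt 3' overhang inside the palindromic stem
            if locus.strand == "+":
                a = locus.mir5p[0] - hs
                n = he - hs
                lo = hs + n - a - len(arm5)
                partner = segment.slice(lo, lo + len(arm5), "+")
            else:
                a = he - locus.mir5p[1]
                n = he - hs
                hi = he - (n - a - len(arm5))
                partner = segment.slice(hi - len(arm5), hi, "-")
            assert partner == revcomp(arm5)

    def test_background_at_fraction(self, small_sim):
        segment, _, truth = small_sim
        bases = "".join(segment.sequence[s:e] for s, e in truth.background_regions)
        at = (bases.count("A") + bases.count("T")) / len(bases)
        assert abs(at - truth.scenario.at_fraction) < 0.02

    def test_overcrowded_genome_rejected(self):
        with pytest.raises(ValueError, match="placed"):
            simulate_genome(SimScenario(seed=1, genome_length=9_000))

    def test_decoys_cover_all_five_violations(self, default_sim):
        _, _, truth = default_sim
        violations = {d.violation for d in truth.decoys()}
        assert violations == {"read_support", "homogeneity", "overhang", "energy", "pairing"}


class TestSmallReads:
    def test_deterministic(self, small_sim, small_scenario):
        _, _, truth = small_sim
        a = simulate_small_reads(truth, "wt", "0h")
        b = simulate_small_reads(truth, "wt", "0h")
        assert len(a) == len(b)
        assert all(x == y for x, y in zip(a, b))

    def test_knockout_depletes_mirna_arms(self, default_sim, default_reads):
        _, _, truth = default_sim
        depletion = truth.scenario.ko_mirna_depletion
        wt = ko = 0
        for locus in truth.mirna_loci():
            lo, hi = locus.mir5p
            for (g, t), reads in default_reads.items():
                n = sum(1 for r in reads
                        if r.strand == locus.strand and r.start < hi and r.end > lo
                        and r.read_id.startswith(locus.locus_id))
                if g == "wt":
                    wt += n
                else:
                    ko += n
        assert wt > 0
        # binomial expectation: ko ~ wt / depletion
        ratio = wt / max(ko, 1)
        assert depletion / 3 < ratio < depletion * 3

    def test_genotype_invariance_of_repeat_loci(self, default_sim, default_reads):
        """siRNA repeat loci are unaffected by the knockout beyond sampling:
        per-locus two-sample proportion z below 3 for every locus."""
        _, _, truth = default_sim
        counts = {g: [] for g in GENOTYPES}
        for rep in truth.repeats:
            if rep.family != "DIRS1":
                continue
            lo, hi = rep.interval
            for g in GENOTYPES:
                n = sum(
                    1
                    for t in TIMEPOINTS
                    for r in default_reads[(g, t)]
                    if lo <= r.start and r.end <= hi
                )
                counts[g].append(n)
        wt = np.array(counts["wt"], dtype=float)
        ko = np.array(counts["ko"], dtype=float)
        pw, pk = wt / wt.sum(), ko / ko.sum()
        se = np.sqrt(pw * (1 - pw) / wt.sum() + pk * (1 - pk) / ko.sum())
        z = np.abs(pw - pk) / se
        assert (z < 3).all()

    def test_read_lengths_peak_at_21(self, default_reads):
        from dictymir.readclass import size_histogram

        hist = size_histogram([r for r in default_reads[("wt", "0h")]])
        assert hist.modal_length == 21


class TestCoverage:
    def test_knockout_enrichment_expectation(self, default_sim, default_coverage):
        _, _, truth = default_sim
        sc = truth.scenario
        locus = truth.loci[0]
        lo, hi = locus.tss, locus.anchor + 100
        wt = default_coverage[("wt", "0h")][locus.strand].window(lo, hi).astype(float)
        ko = default_coverage[("ko", "0h")][locus.strand].window(lo, hi).astype(float)
        assert np.isclose(ko.mean() / wt.mean(), sc.ko_pri_enrichment, rtol=0.05)

    def test_a_run_gap_is_zero_in_both_genotypes(self, default_sim, default_coverage):
        _, _, truth = default_sim
        rt = [l for l in truth.mirna_loci() if l.readthrough][0]
        for g in GENOTYPES:
            track = default_coverage[(g, "0h")][rt.strand]
            assert track.window(*rt.a_gap).sum() == 0

    def test_background_gene_coverage_genotype_invariant(self, default_sim, default_coverage):
        segment, features, _ = default_sim
        gene = [f for f in features if f.ftype == "mRNA"][0]
        wt = default_coverage[("wt", "0h")][gene.strand].window(gene.start, gene.end)
        ko = default_coverage[("ko", "0h")][gene.strand].window(gene.start, gene.end)
        assert (wt == ko).all()


class TestTailedReads:
    def test_tail_fraction_zero_means_no_tails(self, small_scenario):
        import dataclasses

        sc = dataclasses.replace(small_scenario, tail_fraction=0.0)
        _, _, truth = simulate_genome(sc)
        _, tail_truth = simulate_tailed_reads(truth, sc)
        assert tail_truth and all(v == 0 for v in tail_truth.values())

    def test_planted_tails_within_configured_range(self, default_sim):
        _, _, truth = default_sim
        lo, hi = truth.scenario.tail_length_range
        _, tail_truth = simulate_tailed_reads(truth)
        lens = [v for v in tail_truth.values() if v > 0]
        assert lens and all(lo <= v <= hi for v in lens)

    def test_tailed_read_is_genome_prefix_plus_A_tail(self, default_sim):
        segment, _, truth = default_sim
        reads, tail_truth = simulate_tailed_reads(truth)
        for r in reads[:200]:
            tl = tail_truth[r.read_id]
            templated = segment.slice(r.start, r.end, r.strand)
            assert r.seq == templated + "A" * tl
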