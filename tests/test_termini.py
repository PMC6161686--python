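"""Oligo(A)-tail calling and the T-run + G promoter motif."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dictymir.formats import AlignedSmallRead, GenomeSegment
from dictymir.simulate import simulate_tailed_reads
from dictymir.termini import (
    build_pfm,
    detect_untemplated_tail,
    find_tss_motif,
    tail_spectrum,
)


def _read(seq, start, strand="+", rid="r"):
    n = len(seq)
    span = n  # templated span set by caller when a tail is present
    return AlignedSmallRead(rid, seq, "chr1", start, start + span, strand)


class TestTailCalling:
    #           0         1         2         3         4
    #           0123456789012345678901234567890123456789012345
    GENOME = GenomeSegment("chr1", "CGTCGTGGACGTGCATCGTCGCTAAATGCGTCGTACGTACGTCGTC")
    # "GCTAAA" ends at position 25; position 26 is T (no further extension)

    def test_fully_templated_read_has_empty_tail(self):
        r = AlignedSmallRead("r", self.GENOME.sequence[2:22], "chr1", 2, 22, "+")
        tc = detect_untemplated_tail(r, self.GENOME)
        assert (tc.tail_len_min, tc.tail_len_max) == (0, 0)
        assert not tc.is_oligoA

    def test_terminal_templated_A_ambiguity_range(self):
        # genome ...GCTAAA then T; the read carries the templated prefix plus
        # an oligo(A) tail: maximal extension ends on the last templated A,
        # and the three templated terminal A's widen the range by 3
        templated = self.GENOME.sequence[0:26]
        assert templated.endswith("GCTAAA") and self.GENOME.sequence[26] == "T"
        r = AlignedSmallRead("r", templated + "AAAA", "chr1", 0, 26, "+")
        tc = detect_untemplated_tail(r, self.GENOME)
        assert tc.tail_seq == "AAAA"
        assert (tc.tail_len_min, tc.tail_len_max) == (4, 7)
        assert tc.is_oligoA
        assert tc.templated_end.value == 26          # last templated A reported

    def test_unambiguous_tail_exact(self):
        templated = self.GENOME.sequence[26:45]      # ends on T, next is C
        assert not templated.endswith("A") and self.GENOME.sequence[45] != "A"
        r = AlignedSmallRead("r", templated + "AAAA", "chr1", 26, 45, "+")
        tc = detect_untemplated_tail(r, self.GENOME)
        assert (tc.tail_len_min, tc.tail_len_max) == (4, 4)
        assert tc.is_oligoA and tc.tail_seq == "AAAA"

    def test_non_a_suffix_is_not_oligoA(self):
        templated = self.GENOME.sequence[26:45]
        r = AlignedSmallRead("r", templated + "AACA", "chr1", 26, 45, "+")
        tc = detect_untemplated_tail(r, self.GENOME)
        assert tc.tail_len_min == 4 and not tc.is_oligoA

    def test_unanchored_read_raises(self):
        r = AlignedSmallRead("r", "T" * 20, "chr1", 0, 20, "+")
        with pytest.raises(ValueError, match="not anchored"):
            detect_untemplated_tail(r, self.GENOME)

    def test_simulated_tails_recovered(self, default_sim):
        """Unambiguous planted tails are called exactly; ambiguous ranges
        always bracket the planted split; lengths stay in [4, 6]."""
        segment, _, truth = default_sim
        lo, hi = truth.scenario.tail_length_range
        reads, tail_truth = simulate_tailed_reads(truth)
        loci = {l.locus_id: l for l in truth.mirna_loci()}
        n_exact = n_tailed = 0
        for r in reads:
            locus = loci[r.read_id.rsplit("_int", 1)[0]]
            tc = detect_untemplated_tail(r, segment, anchor=locus.anchor, strand=locus.strand)
            true_len = tail_truth[r.read_id]
            assert tc.tail_len_min <= true_len <= tc.tail_len_max
            if tc.tail_len_min == tc.tail_len_max:
                assert tc.tail_len_min == true_len
                n_exact += 1
            if true_len:
                n_tailed += 1
                assert lo <= true_len <= hi
        assert n_tailed > 0 and n_exact > 0


class TestTailSpectrum:
    def test_empty(self):
        assert tail_spectrum([]) == {}

    def test_two_planted_sites_give_two_modes(self, default_sim):
        segment, _, truth = default_sim
        locus = truth.loci[0]     # intermediates planted at +243 and +248
        reads, tail_truth = simulate_tailed_reads(truth)
        calls = [
            detect_untemplated_tail(r, segment, anchor=locus.anchor, strand=locus.strand)
            for r in reads
            if r.read_id.rsplit("_int", 1)[0] == locus.locus_id
        ]
        spec = tail_spectrum(calls)
        ends = {e for (e, _l) in spec}
        assert ends == {243, 248}
        assert sum(spec.values()) == sum(1 for c in calls if c.is_oligoA)


class TestMotif:
    def test_planted_21T_run_at_minus_281(self, default_sim):
        segment, _, truth = default_sim
        locus = truth.loci[0]
        hits = find_tss_motif(segment, locus.tss, locus.strand)
        assert hits[0].run_length == 21
        assert hits[0].predicted_tss == locus.tss

    def test_planted_26T_run(self, default_sim):
        segment, _, truth = default_sim
        locus = truth.loci[1]
        hits = find_tss_motif(segment, locus.tss, locus.strand)
        assert hits[0].run_length == 26

    def test_window_without_run_is_empty(self):
        g = GenomeSegment("chr1", "ACGC" * 100)
        assert find_tss_motif(g, 200, "+") == []

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_hit_invariants_on_random_at_rich_genomes(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=600, p=[0.39, 0.11, 0.11, 0.39]))
        g = GenomeSegment("chr1", seq)
        for strand in "+-":
            anchor = 300
            for h in find_tss_motif(g, anchor, strand, min_run=4):
                assert h.run_length >= 4
                base = g.sequence[h.predicted_tss]
                prev = g.sequence[h.predicted_tss - (1 if strand == "+" else -1)]
                if strand == "-":
                    base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                    prev = {"A": "T", "C": "G", "G": "C", "T": "A"}[prev]
                assert base == "G" and prev == "T"


class TestPfm:
    def test_single_locus_one_hot(self, default_sim):
        segment, _, truth = default_sim
        locus = truth.loci[0]
        hits = find_tss_motif(segment, locus.tss, locus.strand, locus_id=locus.locus_id)
        pfm = build_pfm(hits[:1], segment, strands={locus.locus_id: locus.strand})
        for pos in pfm.positions:
            assert sorted(pfm.freqs[pos].values()) == [0.0, 0.0, 0.0, 1.0]

    def test_planted_motifs_dominate_upstream_columns(self, default_sim):
        segment, _, truth = default_sim
        hits, strands = [], {}
        for locus in truth.mirna_loci():
            h = find_tss_motif(segment, locus.tss, locus.strand, locus_id=locus.locus_id)
            hits.append(h[0])
            strands[locus.locus_id] = locus.strand
        pfm = build_pfm(hits, segment, strands=strands)
        assert pfm.freqs[1]["G"] == 1.0
        for pos in range(-8, 0):
            assert pfm.freqs[pos]["T"] >= 0.8

    def test_pfm_is_mean_of_one_hot_matrices(self, default_sim):
        segment, _, truth = default_sim
        hits, strands = [], {}
        for locus in truth.mirna_loci()[:6]:
            h = find_tss_motif(segment, locus.tss, locus.strand, locus_id=locus.locus_id)
            hits.append(h[0])
            strands[locus.locus_id] = locus.strand
        pfm = build_pfm(hits, segment, strands=strands, upstream_span=10)
        singles = [build_pfm([h], segment, strands=strands, upstream_span=10) for h in hits]
        for pos in pfm.positions:
            for b in "ACGT":
                mean = sum(s.freqs[pos][b] for s in singles) / len(singles)
                assert pfm.freqs[pos][b] == pytest.approx(mean)

    def test_columns_sum_to_one(self, default_sim):
        segment, _, truth = default_sim
        locus = truth.loci[0]
        hits = find_tss_motif(segment, locus.tss, locus.strand, locus_id=locus.locus_id)
        pfm = build_pfm(hits, segment, strands={locus.locus_id: locus.strand})
        for pos in pfm.positions:
            assert abs(sum(pfm.freqs[pos].values()) - 1.0) < 1e-9
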