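"""Criteria engine: boundary arithmetic, arm calling, fold changes, offset
pairs, decoy attribution and verdict monotonicity."""

import math

import pytest

from dictymir.hairpin import DuplexGeometry, fold
from dictymir.mircall import (
    ArmCall,
    CallConfig,
    NotASimpleHairpin,
    ReadStack,
    build_stack,
    call_arms,
    criterion_homogeneity,
    criterion_overhang,
    criterion_read_support,
    detect_mor_pairs,
    developmental_regulation,
    ko_dependence,
)
from dictymir.formats import AlignedSmallRead


def _arm(total, homogeneity, start=10, length=21):
    return ArmCall("5p", start, length, int(total * homogeneity), total, homogeneity)


class TestCriterionBoundaries:
    @pytest.mark.parametrize("t5,t3,expected", [
        (10, 10, True),     # exactly at the bar passes
        (9, 200, False),    # one arm below the bar fails, however deep the other
        (0, 0, False),
        (200, 9, False),
    ])
    def test_read_support(self, t5, t3, expected):
        ok, counts = criterion_read_support((_arm(t5, 0.9), _arm(t3, 0.9)))
        assert ok is expected and counts == (t5, t3)

    @pytest.mark.parametrize("h5,h3,expected", [
        (0.50, 0.50, True),   # "at least 50%": boundary inclusive
        (0.49, 0.90, False),
        (1.0, 1.0, True),
    ])
    def test_homogeneity(self, h5, h3, expected):
        ok, _ = criterion_homogeneity((_arm(100, h5), _arm(100, h3)))
        assert ok is expected

    @pytest.mark.parametrize("oh,strict,relaxed", [
        ((2, 2), True, True),
        ((0, 4), False, True),
        ((5, 2), False, False),
        ((0, 0), False, True),
        ((None, 2), False, False),   # unresolvable overhang fails both
    ])
    def test_overhang_modes(self, oh, strict, relaxed):
        d = DuplexGeometry(mir5p=(10, 31), mir3p=(50, 71),
                           overhang_3p_arm3=oh[0], overhang_3p_arm5=oh[1])
        assert criterion_overhang(d, "strict2")[0] is strict
        assert criterion_overhang(d, "relaxed0to4")[0] is relaxed


def _hairpin_structure():
    import random

    from dictymir.formats import revcomp

    rng = random.Random(5)
    stem = "GG" + "".join(rng.choice("GA") for _ in range(28)) + "GGG"
    return fold(stem + "CCACCACC"[:8].replace("C", "A", 0) + revcomp(stem))


def _stack(counts, library_size=100_000, strand="+"):
    return ReadStack("loc", "c", (0, 100), strand, dict(counts), library_size)


class TestArms:
    def test_all_identical_reads_full_homogeneity(self):
        st = _hairpin_structure()
        stack = _stack({(2, 21): 40})
        a5, a3 = call_arms(stack, st)
        assert a5.homogeneity == 1.0 and a5.total == 40
        assert a3.total == 0

    def test_modal_share_arithmetic(self):
        st = _hairpin_structure()
        stack = _stack({(2, 21): 6, (3, 21): 2, (4, 21): 2})
        a5, _ = call_arms(stack, st)
        assert a5.homogeneity == 0.6 and a5.modal_start == 2

    def test_modal_tie_breaks_to_smaller_start_then_longer_read(self):
        st = _hairpin_structure()
        stack = _stack({(4, 21): 5, (2, 21): 5, (2, 22): 5})
        a5, _ = call_arms(stack, st)
        assert (a5.modal_start, a5.modal_length) == (2, 22)

    def test_multi_loop_window_raises(self):
        # two tandem stems -> not a simple hairpin
        seq = "GGGGAAAACCCC" + "GGGGAAAACCCC"
        st = fold(seq)
        with pytest.raises(NotASimpleHairpin):
            call_arms(_stack({(0, 21): 5}), st)

    def test_generator_homogeneity_recovered(self, default_sim, default_reads, default_calls):
        _, _, truth = default_sim
        for locus in truth.mirna_loci():
            if locus.is_mor:
                continue
            call = default_calls[locus.locus_id]
            assert call.arms is not None
            a5 = call.arms[0]
            assert a5.homogeneity == pytest.approx(locus.homogeneity, abs=0.15)


class TestFoldChanges:
    def test_identity_gives_zero(self):
        st = _hairpin_structure()
        wt = _stack({(2, 21): 50})
        ok, (fc5, _) = ko_dependence(wt, wt, st)
        assert fc5 == 0.0 and not ok

    def test_arithmetic_oracle(self):
        # wt 500 cpm vs ko 10 cpm with pseudocount 1: log2(11/501), both arms
        st = _hairpin_structure()
        n = len(st)
        wt = _stack({(2, 21): 500, (n - 23, 21): 500}, library_size=1_000_000)
        ko = _stack({(2, 21): 10, (n - 23, 21): 10}, library_size=1_000_000)
        ok, (fc5, fc3) = ko_dependence(wt, ko, st)
        assert fc5 == pytest.approx(math.log2(11 / 501))
        assert fc3 == pytest.approx(math.log2(11 / 501))
        assert ok

    def test_pseudocount_monotonicity(self):
        st = _hairpin_structure()
        a = _stack({(2, 21): 400})
        b = _stack({(2, 21): 50})
        prev = None
        for c in (0.5, 1.0, 2.0, 8.0):
            _, (fc, _) = developmental_regulation(a, b, st, pseudocount=c)
            if prev is not None:
                assert abs(fc) <= abs(prev)
            prev = fc

    def test_planted_developmental_fold_recovered(self):
        st = _hairpin_structure()
        s0 = _stack({(2, 21): 25}, library_size=100_000)
        s16 = _stack({(2, 21): 200}, library_size=100_000)
        flag, (fc5, _) = developmental_regulation(s0, s16, st)
        assert flag and fc5 == pytest.approx(3.0, abs=0.2)

    def test_repeat_loci_not_ko_dependent(self, default_sim, default_reads):
        """siRNA loci show |log2fc| < 1 between genotypes (cpm, pooled)."""
        _, _, truth = default_sim
        lib = {g: sum(len(default_reads[(g, t)]) for t in ("0h", "16h")) for g in ("wt", "ko")}
        for rep in truth.repeats:
            if rep.family != "DIRS1":
                continue
            lo, hi = rep.interval
            n = {}
            for g in ("wt", "ko"):
                n[g] = sum(1 for t in ("0h", "16h") for r in default_reads[(g, t)]
                           if lo <= r.start and r.end <= hi)
            fc = math.log2((n["ko"] * 1e6 / lib["ko"] + 1) / (n["wt"] * 1e6 / lib["wt"] + 1))
            assert abs(fc) < 1.0


class TestBuildStack:
    def test_no_overlapping_reads_empty(self):
        stack = build_stack([], (100, 200), "+", "c", 1000)
        assert stack.total == 0

    def test_counts_match_bruteforce_recount(self, small_sim):
        from dictymir.simulate import simulate_small_reads

        segment, _, truth = small_sim
        reads = simulate_small_reads(truth, "wt", "0h")
        locus = truth.mirna_loci()[0]
        win = (locus.hairpin[0] - 20, locus.hairpin[1] + 20)
        stack = build_stack(reads, win, locus.strand, "c", len(reads), segment_id="chr1")
        brute = sum(
            1 for r in reads
            if r.strand == locus.strand
            and (min(r.end, win[1]) - max(r.start, win[0])) >= 0.75 * (r.end - r.start)
        )
        assert stack.total == brute

    def test_minus_strand_flip(self):
        r = AlignedSmallRead("r", "A" * 21, "chr1", 150, 171, "-")
        stack = build_stack([r], (100, 200), "-", "c", 10)
        assert stack.counts == {(200 - 171, 21): 1}


class TestVerdicts:
    def test_recall_and_precision_on_default_scenario(self, default_sim, default_calls):
        _, _, truth = default_sim
        called = {lid for lid, c in default_calls.items()
                  if c.tier in ("high_confidence", "candidate")}
        true_ids = {l.locus_id for l in truth.mirna_loci()}
        tp = len(called & true_ids)
        assert tp / len(true_ids) >= 0.9
        assert tp / len(called) >= 0.9

    def test_each_decoy_fails_exactly_its_planted_criterion(self, default_sim, default_calls):
        _, _, truth = default_sim
        expected = {
            "read_support": "i_read_support", "overhang": "ii_overhang",
            "homogeneity": "iii_homogeneity", "energy": "iv_energy",
            "pairing": "v_pairing",
        }
        for decoy in truth.decoys():
            call = default_calls[decoy.locus_id]
            assert call.report.failed_names() == [expected[decoy.violation]], decoy.locus_id

    def test_read_support_failure_demotes_to_candidate(self, default_sim, default_calls):
        _, _, truth = default_sim
        for decoy in truth.decoys():
            tier = default_calls[decoy.locus_id].tier
            if decoy.violation == "read_support":
                assert tier == "candidate"
            else:
                assert tier == "reject"

    def test_mor_loci_yield_two_labelled_pairs(self, default_sim, default_calls):
        _, _, truth = default_sim
        for locus in truth.mirna_loci():
            call = default_calls[locus.locus_id]
            labels = [lab for lab, _, _ in call.mor_pairs]
            if locus.is_mor:
                assert labels == ["-1", "-2"]
                # the base-proximal pair is the primary (more abundant) one
                d1 = call.mor_pairs[0][1]
                assert d1.mir5p[0] < call.mor_pairs[1][1].mir5p[0]
            else:
                assert len(labels) <= 1

    def test_secondary_below_read_bar_rejected(self):
        st = _hairpin_structure()
        stack = _stack({(2, 21): 40, (40, 21): 9})
        a5, a3 = call_arms(stack, st)
        d = DuplexGeometry(mir5p=(2, 23), mir3p=(40, 61))
        pairs = detect_mor_pairs(stack, st, d, (a5, a3))
        assert len(pairs) == 1

    def test_verdict_invariant_under_read_order(self, default_sim, default_reads):
        """classify_locus is a pure function of the stack: permuting the read
        list never changes the verdict."""
        from dictymir.config import RunConfig
        from dictymir.report import call_all_loci

        segment, features, truth = default_sim
        lib = {c: len(r) for c, r in default_reads.items()}
        reversed_reads = {c: list(reversed(r)) for c, r in default_reads.items()}
        a = call_all_loci(segment, features, default_reads, lib, RunConfig())
        b = call_all_loci(segment, features, reversed_reads, lib, RunConfig())
        assert {k: v.tier for k, v in a.items()} == {k: v.tier for k, v in b.items()}

    def test_raising_thresholds_never_adds_calls(self, default_sim, default_reads):
        from dictymir.config import RunConfig
        from dictymir.report import call_all_loci

        segment, features, truth = default_sim
        lib = {c: len(r) for c, r in default_reads.items()}
        base = call_all_loci(segment, features, default_reads, lib, RunConfig())
        n_base = sum(1 for c in base.values() if c.tier == "high_confidence")
        stricter = RunConfig(min_reads=30, min_homogeneity=0.7, min_pairing=0.9)
        harder = call_all_loci(segment, features, default_reads, lib, stricter)
        n_hard = sum(1 for c in harder.values() if c.tier == "high_confidence")
        assert n_hard <= n_base
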