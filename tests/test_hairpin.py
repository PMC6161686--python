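"""Folding model against a brute-force oracle, and the structure-derived
criterion quantities."""

import random
from functools import lru_cache

import pytest

from dictymir.formats import revcomp
from dictymir.hairpin import (
    MIN_LOOP,
    DuplexGeometry,
    fold,
    hairpin_loops,
    mfe_per_nt,
    overhangs,
    pairing_fraction,
    passes_energy,
    passes_pairing,
    read_structure_file,
    write_structure_file,
    _PAIR_SCORE,
)


def oracle_best_score(seq, min_loop=MIN_LOOP):
    """Independent exhaustive recursion over the last base's pairing state."""
    seq = seq.upper().replace("U", "T")

    @lru_cache(maxsize=None)
    def rec(i, j):
        if j - i <= min_loop:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - min_loop):
            s = _PAIR_SCORE.get((seq[k], seq[j]), 0)
            if s:
                left = rec(i, k - 1) if k > i else 0
                best = max(best, left + rec(k + 1, j - 1) + s)
        return best

    return rec(0, len(seq) - 1)


def structure_is_legal(st):
    """Nested, min-loop-respecting, complementary pairing."""
    opened = []
    for i, p in enumerate(st.pair_map):
        if p is None:
            continue
        if p > i:
            opened.append((i, p))
    for i, j in opened:
        if j - i <= MIN_LOOP:
            return False
        if _PAIR_SCORE.get((st.seq[i], st.seq[j]), 0) == 0:
            return False
    for (i1, j1) in opened:
        for (i2, j2) in opened:
            if i1 < i2 < j1 < j2:
                return False
    return True


class TestFold:
    def test_no_complementarity_means_no_pairs(self):
        st = fold("A" * 24)
        assert st.n_pairs == 0 and st.energy == 0.0

    def test_simple_stem_score(self):
        # GGGG pairs CCCC across an AAAA loop: 4 G-C pairs at -2 each; the
        # window is padded with non-pairing spacers to reach the length floor
        st = fold("GGGGAAAACCCC" + "AAAAAAAA")
        assert st.energy == -8.0
        assert st.dotbracket.startswith("((((....))))")

    @pytest.mark.parametrize("lo,hi", [(8, 16), (20, 26)])
    def test_matches_bruteforce_on_random_sequences(self, lo, hi):
        rng = random.Random(lo)
        for _ in range(200):
            n = rng.randint(lo, hi)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            st = fold(seq)
            assert -st.energy == oracle_best_score(seq), seq
            assert structure_is_legal(st), seq

    def test_deterministic(self):
        seq = "GCGCAAAGCGCATATATGCGCTTTGCGC"
        assert fold(seq).dotbracket == fold(seq).dotbracket

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold("A" * 501)

    def test_illegal_alphabet(self):
        with pytest.raises(ValueError):
            fold("ACGTX" * 5)


class TestExternalStructures:
    def test_roundtrip(self, tmp_path):
        st = fold("GGGGAAAACCCC" + "CACACACA")
        p = tmp_path / "s.txt"
        write_structure_file(st, p)
        back = read_structure_file(p)
        assert back.dotbracket == st.dotbracket
        assert back.energy == st.energy
        assert back.backend == "external"

    def test_unbalanced_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("ACGUACGU\n((..)..\nenergy=-1.0\n")
        with pytest.raises(ValueError, match="unbalanced"):
            read_structure_file(p)


class TestEnergyCriterion:
    def test_boundary_is_strict(self):
        # external thermodynamic threshold: -0.2 kcal/mol/nt, strictly below
        st = _external("A" * 100, energy=-30.0)
        assert mfe_per_nt(st) == -0.30 and passes_energy(st)
        st = _external("A" * 100, energy=-20.0)
        assert mfe_per_nt(st) == -0.20 and not passes_energy(st)
        st = _external("A" * 100, energy=0.0)
        assert not passes_energy(st)


def _external(seq, energy):
    from dictymir.hairpin import HairpinStructure

    return HairpinStructure(
        locus_id="t", seq=seq, dotbracket="." * len(seq),
        pair_map=tuple([None] * len(seq)), energy=energy, backend="external",
    )


def _perfect_hairpin(arm=21, loop=8, a=2):
    """Palindromic stem hairpin with duplex planted at (2,2) overhangs."""
    rng = random.Random(3)
    stem = "".join(rng.choice("GA") for _ in range(arm + a))
    stem = "GG" + stem[2:-3] + "GGG"
    seq = stem + "CACACACA"[:loop] + revcomp(stem)
    st = fold(seq + "")
    n = len(seq)
    L = arm
    b = n + 2 - L - a
    d = DuplexGeometry(mir5p=(a, a + L), mir3p=(b, b + L))
    return st, d


class TestPairingFraction:
    def test_fully_paired_duplex(self):
        st, d = _perfect_hairpin()
        assert pairing_fraction(st, d) == 1.0
        assert passes_pairing(1.0)

    def test_boundary_inclusive_at_60_percent(self):
        assert passes_pairing(0.60)
        assert not passes_pairing(25 / 42)   # 0.595...

    def test_monotone_under_pair_deletion(self):
        st, d = _perfect_hairpin()
        pm = list(st.pair_map)
        frac0 = pairing_fraction(st, d)
        # delete pairs inside the duplex one by one
        from dictymir.hairpin import HairpinStructure

        deleted = 0
        prev = frac0
        for pos in range(*d.mir5p):
            p = pm[pos]
            if p is None:
                continue
            pm[pos] = None
            pm[p] = None
            db = "".join("." if q is None else ("(" if q > i else ")") for i, q in enumerate(pm))
            st2 = HairpinStructure("t", st.seq, db, tuple(pm), st.energy, "internal")
            frac = pairing_fraction(st2, d)
            assert frac <= prev
            prev = frac
            deleted += 1
        assert deleted > 0 and prev < frac0


class TestOverhangs:
    def test_planted_two_nt_overhangs(self):
        st, d = _perfect_hairpin()
        assert overhangs(st, d) == (2, 2)

    def test_blunt_duplex(self):
        st, _ = _perfect_hairpin()
        n = len(st)
        L = 21
        a = 2
        b = n - L - a   # a + b = n - L  ->  overhang 0 on both sides
        d = DuplexGeometry(mir5p=(a, a + L), mir3p=(b, b + L))
        assert overhangs(st, d) == (0, 0)

    def test_three_nt_overhang_passes_relaxed_only(self):
        from dictymir.mircall import criterion_overhang

        st, _ = _perfect_hairpin()
        n = len(st)
        L, a = 21, 2
        b = n + 3 - L - a
        d = DuplexGeometry(mir5p=(a, a + L), mir3p=(b, b + L))
        d.overhang_3p_arm3, d.overhang_3p_arm5 = overhangs(st, d)
        assert (d.overhang_3p_arm3, d.overhang_3p_arm5) == (3, 3)
        ok_strict, _ = criterion_overhang(d, "strict2")
        ok_relax, _ = criterion_overhang(d, "relaxed0to4")
        assert not ok_strict and ok_relax

    def test_invariant_under_unpaired_flank_extension(self):
        st, d = _perfect_hairpin()
        base = overhangs(st, d)
        flank = 12
        ext = fold("C" * flank + st.seq + "C" * flank)
        d2 = DuplexGeometry(
            mir5p=(d.mir5p[0] + flank, d.mir5p[1] + flank),
            mir3p=(d.mir3p[0] + flank, d.mir3p[1] + flank),
        )
        assert overhangs(ext, d2) == base


class TestLoops:
    def test_single_stem_loop_detected(self):
        st, _ = _perfect_hairpin()
        assert len(hairpin_loops(st)) == 1
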