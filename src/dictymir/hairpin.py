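"""Secondary structure of candidate hairpins and structure-derived criteria.

The internal folder is a deterministic base-pair maximisation (Nussinov-style
dynamic program) with weighted pair pseudo-energies GC = -2, AU = -1,
GU = -1 "kcal/mol", a minimum hairpin loop of 3 nt and a tie-break that pairs
the 5'-most position whenever an optimal structure allows it (partner chosen
3'-most).  It is *not* a thermodynamic nearest-neighbour model: criterion iv
against the internal model uses a recalibrated per-nucleotide threshold
(default -0.5 pseudo-kcal/mol/nt), while externally supplied structures with
real folding energies use the classical -0.2 kcal/mol/nt cut-off.

External structures are read from a three-line text file (sequence,
dot-bracket, ``energy=<float>``), compatible with common RNA-folding text
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "HairpinStructure",
    "DuplexGeometry",
    "fold",
    "read_structure_file",
    "write_structure_file",
    "mfe_per_nt",
    "passes_energy",
    "pairing_fraction",
    "passes_pairing",
    "overhangs",
    "hairpin_loops",
    "ENERGY_THRESHOLD_INTERNAL",
    "ENERGY_THRESHOLD_EXTERNAL",
]

MIN_LOOP = 3

#: pseudo-energy magnitudes per closing pair, internal model
_PAIR_SCORE = {
    ("G", "C"): 2, ("C", "G"): 2,
    ("A", "T"): 1, ("T", "A"): 1,
    ("A", "U"): 1, ("U", "A"): 1,
    ("G", "T"): 1, ("T", "G"): 1,
    ("G", "U"): 1, ("U", "G"): 1,
}

ENERGY_THRESHOLD_INTERNAL = -0.5   # pseudo-kcal/mol/nt, internal model
ENERGY_THRESHOLD_EXTERNAL = -0.2   # kcal/mol/nt, thermodynamic energies


@dataclass
class HairpinStructure:
    """Sequence, pairing map and (pseudo-)energy of one folded window."""

    locus_id: str
    seq: str
    dotbracket: str
    pair_map: tuple
    energy: float
    backend: str = "internal"

    def __post_init__(self) -> None:
        n = len(self.seq)
        if len(self.dotbracket) != n or len(self.pair_map) != n:
            raise ValueError("sequence / dot-bracket / pair map length mismatch")
        for i, j in enumerate(self.pair_map):
            if j is None:
                if self.dotbracket[i] not in ".":
                    raise ValueError("pair map inconsistent with dot-bracket")
                continue
            if self.pair_map[j] != i:
                raise ValueError("pair map not symmetric")
            if abs(j - i) <= MIN_LOOP:
                raise ValueError(f"pair ({i},{j}) violates minimum loop length")
        npairs = sum(1 for j in self.pair_map if j is not None) // 2
        if npairs > 0 and self.backend == "internal" and self.energy > 0:
            raise ValueError("internal model energy must be <= 0 when pairs exist")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_pairs(self) -> int:
        return sum(1 for j in self.pair_map if j is not None) // 2


@dataclass
class DuplexGeometry:
    """mir-5p / mir-3p intervals (hairpin-local, 0-based half-open) and the
    two 3' overhang lengths of the duplex (None where unresolvable)."""

    mir5p: tuple
    mir3p: tuple
    overhang_3p_arm3: Optional[int] = None
    overhang_3p_arm5: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.mir5p[1] <= self.mir3p[0]:
            raise ValueError("mir5p must lie entirely 5' of mir3p")


def _pairable(a: str, b: str) -> int:
    return _PAIR_SCORE.get((a, b), 0)


def fold(seq: str, locus_id: str = "", min_loop: int = MIN_LOOP) -> HairpinStructure:
    """Fold ``seq`` with the internal weighted pair-maximisation model.

    Returns the optimum-score structure; ties are broken deterministically by
    pairing the 5'-most position that any optimal structure pairs, with the
    3'-most admissible partner.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if not 1 <= n <= 500:
        raise ValueError(f"fold window length {n} outside [1, 500]")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal alphabet characters {sorted(bad)}")

    # score matrix sc[k, j] = pseudo-energy magnitude of pairing k with j
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    smap = np.zeros((256, 256), dtype=np.int32)
    for (a, b), v in _PAIR_SCORE.items():
        if "U" not in (a, b):
            smap[ord(a), ord(b)] = v
    sc = smap[codes[:, None], codes[None, :]]

    # W[i, j] = best score on [i, j]; invalid/empty intervals read as 0 via guards
    W = np.zeros((n, n), dtype=np.int32)
    ks_all = np.arange(n)
    for d in range(min_loop + 1, n):
        i_arr = np.arange(n - d)
        j_arr = i_arr + d
        for i, j in zip(i_arr, j_arr):
            best = W[i, j - 1]
            ks = ks_all[i : j - min_loop]
            pair_sc = sc[ks, j]
            ok = pair_sc > 0
            if ok.any():
                ks = ks[ok]
                left = np.where(ks > i, W[i, np.maximum(ks - 1, 0)], 0)
                inner = W[ks + 1, j - 1]
                inner = np.where(ks + 1 <= j - 1, inner, 0)
                cand = left + inner + pair_sc[ok]
                m = cand.max()
                if m > best:
                    best = m
            W[i, j] = best

    def _w(i: int, j: int) -> int:
        return int(W[i, j]) if i <= j else 0

    # deterministic traceback: 5'-most position paired when optimal, partner 3'-most
    pair_map: list = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if _w(i, j) == 0:
                break
            chosen = None
            for k in range(j, i + min_loop, -1):
                s = sc[i, k]
                if s == 0:
                    continue
                if s + _w(i + 1, k - 1) + _w(k + 1, j) == _w(i, j):
                    chosen = k
                    break
            if chosen is None:
                i += 1
                continue
            pair_map[i] = chosen
            pair_map[chosen] = i
            if chosen < j:
                stack.append((chosen + 1, j))
            j = chosen - 1
            i += 1

    db = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pair_map)
    )
    energy = -float(W[0, n - 1]) if n else 0.0
    return HairpinStructure(
        locus_id=locus_id, seq=seq, dotbracket=db, pair_map=tuple(pair_map), energy=energy, backend="internal"
    )


def _pair_map_from_dotbracket(db: str) -> tuple:
    stack: list = []
    pm: list = [None] * len(db)
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pm[i] = j
            pm[j] = i
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unclosed '(' at position {stack[-1]}")
    return tuple(pm)


def read_structure_file(path: Union[str, Path], locus_id: str = "") -> HairpinStructure:
    """Parse a three-line structure file: sequence, dot-bracket, energy=<float>."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 3 lines (sequence, dot-bracket, energy)")
    seq = lines[0].upper().replace("U", "T")
    db = lines[1]
    if not lines[2].startswith("energy="):
        raise ValueError(f"{path}: third line must be 'energy=<float>'")
    energy = float(lines[2].split("=", 1)[1])
    pm = _pair_map_from_dotbracket(db)
    return HairpinStructure(
        locus_id=locus_id or Path(path).stem, seq=seq, dotbracket=db, pair_map=pm, energy=energy, backend="external"
    )


def write_structure_file(structure: HairpinStructure, path: Union[str, Path]) -> None:
    Path(path).write_text(f"{structure.seq}\n{structure.dotbracket}\nenergy={structure.energy}\n")


def mfe_per_nt(structure: HairpinStructure) -> float:
    """Folding (pseudo-)energy divided by window length, kcal/mol/nt."""
    return structure.energy / len(structure)


def passes_energy(structure: HairpinStructure, threshold: Optional[float] = None) -> bool:
    """Criterion iv: energy density strictly below the threshold."""
    if threshold is None:
        threshold = (
            ENERGY_THRESHOLD_INTERNAL if structure.backend == "internal" else ENERGY_THRESHOLD_EXTERNAL
        )
    return mfe_per_nt(structure) < threshold


def pairing_fraction(structure: HairpinStructure, duplex: DuplexGeometry) -> float:
    """Fraction of duplex (mir5p union mir3p) positions that are paired."""
    positions = list(range(*duplex.mir5p)) + list(range(*duplex.mir3p))
    if not positions:
        raise ValueError("empty duplex")
    if min(positions) < 0 or max(positions) >= len(structure):
        raise ValueError("duplex outside structure window")
    paired = sum(1 for p in positions if structure.pair_map[p] is not None)
    return paired / len(positions)


def passes_pairing(fraction: float, threshold: float = 0.60) -> bool:
    """Criterion v: at least 60% of the duplex paired (inclusive)."""
    return fraction >= threshold


def _partner_near(pair_map: tuple, idx: int, max_scan: int = 3) -> Optional[int]:
    """Partner of ``idx``; if unpaired, scan inward (3'-ward) up to
    ``max_scan`` nt for the nearest paired position and correct the register
    by the offset.  None when unresolvable."""
    n = len(pair_map)
    for off in range(max_scan + 1):
        k = idx + off
        if k >= n:
            break
        p = pair_map[k]
        if p is not None:
            return p + off
    return None


def overhangs(structure: HairpinStructure, duplex: DuplexGeometry) -> tuple:
    """3' overhang lengths of the duplex, RNase III signature style.

    overhang_3p_arm3 = (mir3p 3'-end index) - partner(mir5p 5'-end)
    overhang_3p_arm5 = (mir5p 3'-end index) - partner(mir3p 5'-end)

    Unpaired termini are resolved by scanning inward up to 3 nt; a terminus
    with no paired position within reach yields None (criterion ii fails).
    """
    pm = structure.pair_map
    p5 = _partner_near(pm, duplex.mir5p[0])
    p3 = _partner_near(pm, duplex.mir3p[0])
    oh_arm3 = (duplex.mir3p[1] - 1) - p5 if p5 is not None else None
    oh_arm5 = (duplex.mir5p[1] - 1) - p3 if p3 is not None else None
    return oh_arm3, oh_arm5


def hairpin_loops(structure: HairpinStructure) -> list:
    """Closing pairs (i, j) of hairpin loops: pairs with no pair inside."""
    loops = []
    pm = structure.pair_map
    for i, j in enumerate(pm):
        if j is None or j <= i:
            continue
        if all(pm[k] is None for k in range(i + 1, j)):
            loops.append((i, j))
    return loops
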