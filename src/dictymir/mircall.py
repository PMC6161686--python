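"""The high-confidence miRNA criteria engine.

Per candidate hairpin locus this module builds strand- and orientation-
normalised read stacks, calls the mir-5p/mir-3p duplex from the modal reads
of each arm, evaluates the five structural/read criteria plus knockout
dependence, flags developmental regulation, detects secondary
(offset-RNA-style) duplex pairs, and emits a tiered per-locus verdict:

i)   at least 10 reads on each arm;
ii)  the modal duplex pairs with a 2-nt 3' overhang (strict mode; the
     relaxed mode accepts 0-4 nt);
iii) at least 50% of each arm's reads share a common 5' end;
iv)  folding energy density below the threshold (see :mod:`.hairpin`);
v)   at least 60% of the duplex paired in the precursor;
plus clear down-regulation in the Dicer-like knockout (log2 fold change
below a configurable bound, default -2, on both arms).

``high_confidence`` requires all six with the strict overhang;
``candidate`` tolerates a read-support failure (abundant siRNA backgrounds
can occlude rare arms) or an overhang that only passes the relaxed mode;
anything else is rejected.  The full per-criterion report is always kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .formats import AlignedSmallRead, Feature
from .hairpin import (
    DuplexGeometry,
    HairpinStructure,
    hairpin_loops,
    mfe_per_nt,
    overhangs,
    pairing_fraction,
    passes_energy,
)

__all__ = [
    "ReadStack",
    "ArmCall",
    "Criterion",
    "CriterionReport",
    "LocusCall",
    "NotASimpleHairpin",
    "build_stack",
    "call_arms",
    "criterion_read_support",
    "criterion_overhang",
    "criterion_homogeneity",
    "ko_dependence",
    "developmental_regulation",
    "detect_mor_pairs",
    "classify_locus",
]


class NotASimpleHairpin(ValueError):
    """The folded window has no, or more than one, apical loop."""


@dataclass
class ReadStack:
    """Pileup of read (5'-start, length) pairs in locus-forward window
    coordinates for one condition."""

    locus_id: str
    condition: str
    window: tuple                 # genomic (start, end)
    strand: str
    counts: dict                  # (start, length) -> count, window-local
    library_size: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ArmCall:
    """Modal read and 5'-end homogeneity of one arm."""

    arm: str                      # "5p" | "3p"
    modal_start: Optional[int]    # window-local
    modal_length: Optional[int]
    modal_count: int
    total: int
    homogeneity: float            # fraction of arm reads sharing the modal 5' start

    @property
    def modal_interval(self) -> Optional[tuple]:
        if self.modal_start is None:
            return None
        return (self.modal_start, self.modal_start + self.modal_length)


@dataclass
class Criterion:
    name: str
    value: object
    threshold: object
    passed: bool


@dataclass
class CriterionReport:
    criteria: dict = field(default_factory=dict)

    def add(self, name: str, value, threshold, passed: bool) -> None:
        self.criteria[name] = Criterion(name, value, threshold, bool(passed))

    def passed(self, name: str) -> bool:
        return self.criteria[name].passed

    def failed_names(self) -> list:
        return [n for n, c in self.criteria.items() if not c.passed]


@dataclass
class LocusCall:
    locus_id: str
    tier: str                     # high_confidence | candidate | reject
    duplex: Optional[DuplexGeometry]
    arms: Optional[tuple]         # (ArmCall 5p, ArmCall 3p)
    report: CriterionReport
    ko_log2fc: Optional[tuple] = None
    dev_log2fc: Optional[tuple] = None
    dev_regulated: Optional[bool] = None
    mor_pairs: list = field(default_factory=list)   # [(label, DuplexGeometry, (ArmCall, ArmCall))]
    error: Optional[str] = None


# ---------------------------------------------------------------------------
# stacks and arms
# ---------------------------------------------------------------------------

def build_stack(
    reads: Sequence[AlignedSmallRead],
    window: tuple,
    strand: str,
    condition: str,
    library_size: int,
    locus_id: str = "",
    segment_id: Optional[str] = None,
    min_overlap_frac: float = 0.75,
) -> ReadStack:
    """Stack reads overlapping the locus window by >= 75% of their templated
    span, flipped into locus-forward coordinates (the - strand is mirrored so
    position 0 is the window's 5' end on the locus strand)."""
    ws, we = window
    wlen = we - ws
    counts: dict = {}
    for r in reads:
        if r.strand != strand:
            continue
        if segment_id is not None and r.segment_id != segment_id:
            continue
        ov = min(r.end, we) - max(r.start, ws)
        if ov < min_overlap_frac * (r.end - r.start):
            continue
        if strand == "+":
            s = r.start - ws
        else:
            s = we - r.end
        key = (s, r.end - r.start)
        counts[key] = counts.get(key, 0) + 1
    return ReadStack(
        locus_id=locus_id, condition=condition, window=window, strand=strand,
        counts=counts, library_size=library_size,
    )


def _single_loop(structure: HairpinStructure) -> tuple:
    loops = hairpin_loops(structure)
    if len(loops) != 1:
        raise NotASimpleHairpin(
            f"not a simple hairpin: {len(loops)} apical loops in {structure.locus_id or 'window'}"
        )
    return loops[0]


def _arm_of(start: int, length: int, loop: tuple, n: int) -> Optional[str]:
    """Arm containing >= 50% of the read span; None for loop-straddlers."""
    p, q = loop
    end = start + length
    ov5 = max(0, min(end, p + 1) - max(start, 0))
    ov3 = max(0, min(end, n) - max(start, q))
    if ov5 >= ov3 and ov5 * 2 >= length:
        return "5p"
    if ov3 * 2 >= length:
        return "3p"
    return None


HOMOGENEITY_RADIUS = 5


def _arm_call(arm: str, items: list) -> ArmCall:
    """items: [((start, length), count)]; modal ties -> smaller start, then
    longer read.

    Homogeneity is the modal-5'-start share among reads starting within
    ``HOMOGENEITY_RADIUS`` nt of the modal start: it measures the precision
    of the modal product itself, so a second product elsewhere on the same
    arm (an immediately adjacent offset-RNA pair) does not count against it,
    while overlapping alternative 5' ends still do."""
    total = sum(c for _, c in items)
    if total == 0:
        return ArmCall(arm=arm, modal_start=None, modal_length=None,
                       modal_count=0, total=0, homogeneity=0.0)
    (ms, ml), mc = max(items, key=lambda kv: (kv[1], -kv[0][0], kv[0][1]))
    local = sum(c for (s, _l), c in items if abs(s - ms) <= HOMOGENEITY_RADIUS)
    same5 = sum(c for (s, _l), c in items if s == ms)
    return ArmCall(arm=arm, modal_start=ms, modal_length=ml, modal_count=mc,
                   total=total, homogeneity=same5 / local)


def call_arms(stack: ReadStack, structure: HairpinStructure) -> tuple:
    """Assign stacked reads to the two arms of the (single) stem-loop and
    call each arm's modal read and homogeneity."""
    loop = _single_loop(structure)
    n = len(structure)
    items5, items3 = [], []
    for (s, l), c in stack.counts.items():
        arm = _arm_of(s, l, loop, n)
        if arm == "5p":
            items5.append(((s, l), c))
        elif arm == "3p":
            items3.append(((s, l), c))
    return _arm_call("5p", items5), _arm_call("3p", items3)


def _arm_totals(stack: ReadStack, structure: HairpinStructure) -> tuple:
    loop = _single_loop(structure)
    n = len(structure)
    t5 = t3 = 0
    for (s, l), c in stack.counts.items():
        arm = _arm_of(s, l, loop, n)
        if arm == "5p":
            t5 += c
        elif arm == "3p":
            t3 += c
    return t5, t3


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def criterion_read_support(arms: tuple, min_reads: int = 10):
    """Criterion i: both arm totals at or above ``min_reads``."""
    a5, a3 = arms
    return (a5.total >= min_reads and a3.total >= min_reads), (a5.total, a3.total)


def criterion_overhang(duplex: DuplexGeometry, mode: str = "strict2"):
    """Criterion ii: strict mode requires both overhangs == 2; relaxed mode
    accepts 0-4 nt; an unresolvable overhang fails."""
    oh = (duplex.overhang_3p_arm3, duplex.overhang_3p_arm5)
    if oh[0] is None or oh[1] is None:
        return False, oh
    if mode == "strict2":
        return (oh[0] == 2 and oh[1] == 2), oh
    if mode == "relaxed0to4":
        return (0 <= oh[0] <= 4 and 0 <= oh[1] <= 4), oh
    raise ValueError(f"unknown overhang mode {mode!r}")


def criterion_homogeneity(arms: tuple, min_frac: float = 0.5):
    """Criterion iii: both arms' 5'-end homogeneity at or above ``min_frac``."""
    a5, a3 = arms
    return (a5.homogeneity >= min_frac and a3.homogeneity >= min_frac), (a5.homogeneity, a3.homogeneity)


def _cpm(count: float, library_size: int) -> float:
    if library_size <= 0:
        raise ValueError("missing or invalid library size")
    return count * 1e6 / library_size


def _log2fc(a_count, a_lib, b_count, b_lib, pseudocount: float) -> float:
    return math.log2((_cpm(a_count, a_lib) + pseudocount) / (_cpm(b_count, b_lib) + pseudocount))


def ko_dependence(
    stack_wt: ReadStack,
    stack_ko: ReadStack,
    structure: HairpinStructure,
    pseudocount: float = 1.0,
    max_log2fc: float = -2.0,
):
    """Knockout dependence: per-arm log2((ko_cpm + c) / (wt_cpm + c)); passes
    when the fold change is at or below ``max_log2fc`` on both arms."""
    wt5, wt3 = _arm_totals(stack_wt, structure)
    ko5, ko3 = _arm_totals(stack_ko, structure)
    fc5 = _log2fc(ko5, stack_ko.library_size, wt5, stack_wt.library_size, pseudocount)
    fc3 = _log2fc(ko3, stack_ko.library_size, wt3, stack_wt.library_size, pseudocount)
    return (fc5 <= max_log2fc and fc3 <= max_log2fc), (fc5, fc3)


def developmental_regulation(
    stack_0h: ReadStack,
    stack_16h: ReadStack,
    structure: HairpinStructure,
    pseudocount: float = 1.0,
    min_abs_log2fc: float = 1.0,
):
    """Developmental regulation flag: |log2fc(16h vs 0h)| at or above the
    threshold on the dominant (higher pooled count) arm."""
    a5, a3 = _arm_totals(stack_0h, structure)
    b5, b3 = _arm_totals(stack_16h, structure)
    fc5 = _log2fc(b5, stack_16h.library_size, a5, stack_0h.library_size, pseudocount)
    fc3 = _log2fc(b3, stack_16h.library_size, a3, stack_0h.library_size, pseudocount)
    dominant = fc5 if (a5 + b5) >= (a3 + b3) else fc3
    return (abs(dominant) >= min_abs_log2fc), (fc5, fc3)


# ---------------------------------------------------------------------------
# duplex construction and offset pairs
# ---------------------------------------------------------------------------

def _duplex_from_arms(arms: tuple, structure: HairpinStructure) -> Optional[DuplexGeometry]:
    a5, a3 = arms
    if a5.modal_start is None or a3.modal_start is None:
        return None
    if not a5.modal_interval[1] <= a3.modal_interval[0]:
        return None
    d = DuplexGeometry(mir5p=a5.modal_interval, mir3p=a3.modal_interval)
    d.overhang_3p_arm3, d.overhang_3p_arm5 = overhangs(structure, d)
    return d


def _interval_gap(a: tuple, b: tuple) -> int:
    """Gap between two intervals; negative when they overlap."""
    return max(a[0], b[0]) - min(a[1], b[1])


def detect_mor_pairs(
    stack: ReadStack,
    structure: HairpinStructure,
    primary_duplex: DuplexGeometry,
    primary_arms: tuple,
    min_reads: int = 10,
    min_homogeneity: float = 0.5,
    max_adjacent_gap: int = 3,
    mask_tolerance: int = 2,
):
    """Look for a second duplex immediately adjacent to the primary one
    (offset-RNA style): mask reads whose 5' start lies within
    ``mask_tolerance`` of either primary modal start, re-call arms on the
    residue, and accept the secondary pair only if both arms clear the read
    support and homogeneity bars and both secondary arms lie within
    ``max_adjacent_gap`` nt of (without overlapping) the primary arms.

    Returns labelled pairs sorted base-proximal first: the pair closest to
    the stem base is "-1", the loop-proximal one "-2".
    """
    p5, p3 = primary_arms
    masked: dict = {}
    for (s, l), c in stack.counts.items():
        if abs(s - p5.modal_start) <= mask_tolerance or abs(s - p3.modal_start) <= mask_tolerance:
            continue
        masked[(s, l)] = c
    residual = ReadStack(
        locus_id=stack.locus_id, condition=stack.condition, window=stack.window,
        strand=stack.strand, counts=masked, library_size=stack.library_size,
    )
    s5, s3 = call_arms(residual, structure)
    pairs = [("primary", primary_duplex, primary_arms)]
    ok = (
        s5.total >= min_reads and s3.total >= min_reads
        and s5.homogeneity >= min_homogeneity and s3.homogeneity >= min_homogeneity
    )
    secondary = _duplex_from_arms((s5, s3), structure) if ok else None
    if secondary is not None:
        g5 = _interval_gap(primary_duplex.mir5p, secondary.mir5p)
        g3 = _interval_gap(primary_duplex.mir3p, secondary.mir3p)
        if not (0 <= g5 <= max_adjacent_gap and 0 <= g3 <= max_adjacent_gap):
            secondary = None
    if secondary is not None:
        pairs.append(("secondary", secondary, (s5, s3)))
    # base-proximal pair (5'-most mir5p start) is "-1", loop-proximal "-2"
    pairs.sort(key=lambda t: t[1].mir5p[0])
    return [(f"-{i+1}", d, a) for i, (_, d, a) in enumerate(pairs)]


# ---------------------------------------------------------------------------
# verdict
# ---------------------------------------------------------------------------

@dataclass
class CallConfig:
    min_reads: int = 10
    min_homogeneity: float = 0.5
    overhang_mode: str = "strict2"
    energy_threshold: Optional[float] = None   # None: backend default
    min_pairing: float = 0.60
    pseudocount: float = 1.0
    ko_max_log2fc: float = -2.0
    dev_min_abs_log2fc: float = 1.0
    mor_max_gap: int = 3


def classify_locus(
    locus_id: str,
    structure: HairpinStructure,
    stack_wt: ReadStack,
    stack_ko: ReadStack,
    stack_0h: Optional[ReadStack] = None,
    stack_16h: Optional[ReadStack] = None,
    config: Optional[CallConfig] = None,
) -> LocusCall:
    """Evaluate all criteria on the pooled wild-type stack and emit the
    tiered verdict.  A pure function of its numeric inputs."""
    cfg = config or CallConfig()
    report = CriterionReport()
    try:
        arms = call_arms(stack_wt, structure)
    except NotASimpleHairpin as exc:
        return LocusCall(locus_id=locus_id, tier="reject", duplex=None, arms=None,
                         report=report, error=str(exc))

    ok_i, counts = criterion_read_support(arms, cfg.min_reads)
    report.add("i_read_support", counts, cfg.min_reads, ok_i)

    duplex = _duplex_from_arms(arms, structure)
    if duplex is None:
        report.add("ii_overhang", (None, None), cfg.overhang_mode, False)
        report.add("iii_homogeneity", (arms[0].homogeneity, arms[1].homogeneity),
                   cfg.min_homogeneity, False)
        report.add("iv_energy", mfe_per_nt(structure), cfg.energy_threshold, False)
        report.add("v_pairing", None, cfg.min_pairing, False)
        ok_ko, kofc = ko_dependence(stack_wt, stack_ko, structure,
                                    cfg.pseudocount, cfg.ko_max_log2fc)
        report.add("ko_dependence", kofc, cfg.ko_max_log2fc, ok_ko)
        return LocusCall(locus_id=locus_id, tier="reject", duplex=None, arms=arms,
                         report=report, ko_log2fc=kofc, error="no duplex callable")

    ok_strict, oh = criterion_overhang(duplex, "strict2")
    ok_relaxed, _ = criterion_overhang(duplex, "relaxed0to4")
    ok_ii = ok_strict if cfg.overhang_mode == "strict2" else ok_relaxed
    report.add("ii_overhang", oh, cfg.overhang_mode, ok_ii)

    ok_iii, hom = criterion_homogeneity(arms, cfg.min_homogeneity)
    report.add("iii_homogeneity", hom, cfg.min_homogeneity, ok_iii)

    ok_iv = passes_energy(structure, cfg.energy_threshold)
    report.add("iv_energy", mfe_per_nt(structure), cfg.energy_threshold, ok_iv)

    pf = pairing_fraction(structure, duplex)
    ok_v = pf >= cfg.min_pairing
    report.add("v_pairing", pf, cfg.min_pairing, ok_v)

    ok_ko, kofc = ko_dependence(stack_wt, stack_ko, structure,
                                cfg.pseudocount, cfg.ko_max_log2fc)
    report.add("ko_dependence", kofc, cfg.ko_max_log2fc, ok_ko)

    dev_fc = dev_flag = None
    if stack_0h is not None and stack_16h is not None:
        dev_flag, dev_fc = developmental_regulation(
            stack_0h, stack_16h, structure, cfg.pseudocount, cfg.dev_min_abs_log2fc)

    structural = ok_iii and ok_iv and ok_v and ok_ko
    if structural and ok_i and ok_strict:
        tier = "high_confidence"
    elif structural and ok_relaxed:
        # retained candidates: either arm support below the bar (abundant
        # siRNA backgrounds occlude rare arms) or only the relaxed 0-4 nt
        # overhang passes
        tier = "candidate"
    else:
        tier = "reject"

    mor_pairs = []
    if tier != "reject":
        mor_pairs = detect_mor_pairs(
            stack_wt, structure, duplex, arms,
            min_reads=cfg.min_reads, min_homogeneity=cfg.min_homogeneity,
            max_adjacent_gap=cfg.mor_max_gap,
        )

    return LocusCall(
        locus_id=locus_id, tier=tier, duplex=duplex, arms=arms, report=report,
        ko_log2fc=kofc, dev_log2fc=dev_fc, dev_regulated=dev_flag, mor_pairs=mor_pairs,
    )
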