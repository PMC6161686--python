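"""Untemplated oligo(A) tails and the T-run + G promoter motif.

Tail calling follows the maximal-templated-extension convention: a read is
matched against the genome from its anchored 5' end for as long as it
agrees; the unmatched 3' suffix is the untemplated tail.  When the
templated end itself lies in an A tract contiguous with an all-A suffix,
the true cleavage point cannot be placed exactly, so the tail length is
reported as a range (the last templated A is reported as the templated 3'
end, per the standard convention).

The promoter motif search scans a fixed window upstream of the 5'-most
covered position of a locus for maximal T-homopolymer runs immediately
followed by a G; the G position is the predicted transcription start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats import AlignedSmallRead, GenomeSegment, RelCoord, to_relative

__all__ = [
    "TailCall",
    "MotifHit",
    "PositionFrequencyMatrix",
    "detect_untemplated_tail",
    "tail_spectrum",
    "find_tss_motif",
    "build_pfm",
]


@dataclass
class TailCall:
    read_id: str
    templated_end: RelCoord          # last templated position, mir-5p-relative
    tail_seq: str
    tail_len_min: int
    tail_len_max: int                # upper bound under terminal-A ambiguity
    is_oligoA: bool

    def __post_init__(self) -> None:
        if self.tail_len_min > self.tail_len_max:
            raise ValueError("tail_len_min > tail_len_max")
        if self.is_oligoA and (not self.tail_seq or set(self.tail_seq) != {"A"}):
            raise ValueError("is_oligoA requires a non-empty all-A tail")


@dataclass
class MotifHit:
    locus_id: str
    t_run: tuple                     # genomic [start, end) of the T run, locus strand
    run_length: int
    predicted_tss: int               # genomic position of the G
    distance_to_anchor: int          # nt from the scan anchor to the G


@dataclass
class PositionFrequencyMatrix:
    """Columns -upstream_span..-1 then +1 (the G); each column sums to 1."""

    positions: list
    freqs: dict                      # position -> {base: frequency}
    n_loci: int

    def __post_init__(self) -> None:
        for pos in self.positions:
            s = sum(self.freqs[pos].values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"column {pos} sums to {s}")


def detect_untemplated_tail(
    read: AlignedSmallRead,
    genome: GenomeSegment,
    aligned_start: Optional[int] = None,
    anchor: Optional[int] = None,
    strand: Optional[str] = None,
    max_oligoa: int = 10,
) -> TailCall:
    """Maximal templated extension from the read's anchored 5' end.

    ``aligned_start`` is the genomic position of the read's 5' end on the
    locus strand (default: taken from the read record).  ``anchor``/
    ``strand`` fix the relative coordinate frame for the templated end
    (default: the read's own 5' anchor and strand).
    """
    strand = strand or read.strand
    if aligned_start is None:
        aligned_start = read.start if strand == "+" else read.end - 1
    glen = len(genome.sequence)
    seq = read.seq
    step = 1 if strand == "+" else -1

    # walk the genome 3'-ward from the 5' anchor
    matched = 0
    pos = aligned_start
    while matched < len(seq) and 0 <= pos < glen:
        g = genome.sequence[pos]
        if strand == "-":
            g = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[g]
        if g != seq[matched]:
            break
        matched += 1
        pos += step
    if matched == 0:
        raise ValueError(f"read {read.read_id!r} not anchored at {aligned_start}")

    tail = seq[matched:]
    tail_min = len(tail)
    # ambiguity: templated 3'-terminal A's contiguous with an all-A suffix
    extra = 0
    if tail and set(tail) == {"A"}:
        i = matched - 1
        while i >= 0 and seq[i] == "A":
            extra += 1
            i -= 1
    templated_end_pos = aligned_start + (matched - 1) * step
    return TailCall(
        read_id=read.read_id,
        templated_end=to_relative(templated_end_pos, anchor if anchor is not None else aligned_start, strand),
        tail_seq=tail,
        tail_len_min=tail_min,
        tail_len_max=tail_min + extra,
        is_oligoA=bool(tail) and set(tail) == {"A"} and 1 <= tail_min <= max_oligoa,
    )


def tail_spectrum(tailcalls: Sequence[TailCall]) -> dict:
    """2-D census of oligo(A) calls: (templated end, tail_len_min) -> count,
    deterministically ordered."""
    spec: dict = {}
    for tc in tailcalls:
        if not tc.is_oligoA:
            continue
        key = (tc.templated_end.value, tc.tail_len_min)
        spec[key] = spec.get(key, 0) + 1
    return dict(sorted(spec.items()))


def find_tss_motif(
    genome: GenomeSegment,
    anchor: int,
    strand: str,
    locus_id: str = "",
    window: int = 140,
    min_run: int = 8,
) -> list:
    """Scan ``window`` nt upstream of ``anchor`` (inclusive) on the locus
    strand for maximal T runs of length >= min_run immediately followed by
    G.  Hits are ranked by run length (desc), then distance to the anchor
    (asc).  The predicted TSS is the position of the G."""
    glen = len(genome.sequence)
    # genomic positions scanned, 5'->3' on the locus strand
    if strand == "+":
        lo, hi = max(0, anchor - window), min(glen - 1, anchor)
        positions = range(lo, hi + 1)
    else:
        lo, hi = max(0, anchor), min(glen - 1, anchor + window)
        positions = range(hi, lo - 1, -1)
    seq = "".join(
        genome.sequence[p] if strand == "+" else
        {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[genome.sequence[p]]
        for p in positions
    )
    positions = list(positions)
    hits = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] != "T":
            i += 1
            continue
        j = i
        while j < n and seq[j] == "T":
            j += 1
        run_len = j - i
        if run_len >= min_run and j < n and seq[j] == "G":
            g_pos = positions[j]
            t_lo = min(positions[i], positions[j - 1])
            hits.append(MotifHit(
                locus_id=locus_id,
                t_run=(t_lo, t_lo + run_len),
                run_length=run_len,
                predicted_tss=g_pos,
                distance_to_anchor=abs(anchor - g_pos),
            ))
        i = j
    hits.sort(key=lambda h: (-h.run_length, h.distance_to_anchor))
    return hits


def build_pfm(
    hits: Sequence[MotifHit],
    genome: GenomeSegment,
    strands: Optional[dict] = None,
    upstream_span: int = 30,
) -> PositionFrequencyMatrix:
    """Position frequency matrix of hit windows aligned at the G (+1).

    ``strands`` maps locus_id -> strand (default '+').  Loci whose upstream
    window would leave the segment are dropped.
    """
    if not hits:
        raise ValueError("no motif hits to build a PFM from")
    strands = strands or {}
    glen = len(genome.sequence)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    positions = list(range(-upstream_span, 0)) + [1]
    columns = {p: {"A": 0, "C": 0, "G": 0, "T": 0} for p in positions}
    used = 0
    for h in hits:
        strand = strands.get(h.locus_id, "+")
        step = 1 if strand == "+" else -1
        window_ok = True
        bases = {}
        for rel in positions:
            # +1 is the G itself; negative positions step upstream
            p = h.predicted_tss + (rel * step if rel < 0 else 0)
            if not 0 <= p < glen:
                window_ok = False
                break
            b = genome.sequence[p]
            if strand == "-":
                b = comp[b]
            bases[rel] = b
        if not window_ok:
            continue
        for rel, b in bases.items():
            if b in columns[rel]:
                columns[rel][b] += 1
        used += 1
    if used == 0:
        raise ValueError("all motif windows fall outside the segment")
    freqs = {p: {b: c / used for b, c in col.items()} for p, col in columns.items()}
    return PositionFrequencyMatrix(positions=positions, freqs=freqs, n_loci=used)
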