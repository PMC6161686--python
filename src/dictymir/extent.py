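"""Primary-transcript extents, knockout enrichment, and readthrough.

Transcript extents are taken from per-base long-RNA coverage depth (not
individual read ends) and reported in the signed mir-5p-relative coordinate
system; a separate end census handles discrete 3'-end observations
(RACE-clone style).  Readthrough detection walks coverage from the hairpin's
3' edge toward a downstream gene, tolerating zero-coverage gaps only where
they are short and the gapped genomic sequence is A-rich on the locus
strand (A-homopolymer tracts defeat both sequencing and poly(A) selection,
so a covered transcript can legitimately appear interrupted there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats import CoverageTrack, Feature, GenomeSegment, RelCoord, to_relative

__all__ = [
    "TranscriptExtent",
    "EnrichmentResult",
    "ReadthroughCall",
    "transcript_extent",
    "locus_enrichment",
    "detect_readthrough",
    "end_census",
]


@dataclass
class TranscriptExtent:
    locus_id: str
    condition: str
    five_prime_most: RelCoord
    three_prime_most: RelCoord
    min_depth: int

    def __post_init__(self) -> None:
        if self.five_prime_most.value >= self.three_prime_most.value:
            raise ValueError("extent must run 5' to 3'")


@dataclass
class EnrichmentResult:
    locus_id: str
    wt_cpm: float
    ko_cpm: float
    log2fc: float

    @property
    def direction(self) -> str:
        return "up_in_ko" if self.log2fc > 0 else ("down_in_ko" if self.log2fc < 0 else "unchanged")


@dataclass
class ReadthroughCall:
    locus_id: str
    bridged: bool
    gaps_tolerated: list          # genomic (start, end) zero-coverage runs crossed
    reached_feature: Optional[str]


def transcript_extent(
    track: CoverageTrack,
    window: tuple,
    anchor: int,
    strand: str,
    locus_id: str = "",
    condition: str = "",
    min_depth: int = 1,
) -> Optional[TranscriptExtent]:
    """5'-most and 3'-most positions with depth >= min_depth inside the
    genomic window, as mir-5p-relative coordinates.  None when nothing in
    the window is covered (undefined extent)."""
    ws, we = window
    depth = track.window(ws, we)
    covered = np.nonzero(depth >= min_depth)[0]
    if covered.size == 0:
        return None
    lo = ws + int(covered[0])
    hi = ws + int(covered[-1])
    if strand == "+":
        five, three = lo, hi
    else:
        five, three = hi, lo
    return TranscriptExtent(
        locus_id=locus_id, condition=condition,
        five_prime_most=to_relative(five, anchor, strand),
        three_prime_most=to_relative(three, anchor, strand),
        min_depth=min_depth,
    )


def locus_enrichment(
    track_wt: CoverageTrack,
    track_ko: CoverageTrack,
    window: tuple,
    locus_id: str = "",
    pseudocount: float = 1.0,
) -> EnrichmentResult:
    """Knockout-vs-wt coverage fold change over the locus window (cpm with a
    pseudocount; positive log2fc = enriched in the knockout)."""
    ws, we = window
    wt = float(track_wt.window(ws, we).sum()) * 1e6 / track_wt.library_size
    ko = float(track_ko.window(ws, we).sum()) * 1e6 / track_ko.library_size
    return EnrichmentResult(
        locus_id=locus_id, wt_cpm=wt, ko_cpm=ko,
        log2fc=float(np.log2((ko + pseudocount) / (wt + pseudocount))),
    )


def detect_readthrough(
    track: CoverageTrack,
    hairpin: tuple,
    downstream_feature: Feature,
    genome: GenomeSegment,
    strand: str,
    locus_id: str = "",
    max_gap: int = 50,
    a_frac: float = 0.8,
    min_depth: int = 1,
) -> ReadthroughCall:
    """Walk coverage from the hairpin 3' edge toward the downstream feature.

    Zero-depth runs are tolerated iff they are at most ``max_gap`` nt long
    and the gapped genomic sequence has A fraction >= ``a_frac`` on the
    locus strand; the locus is bridged iff a covered position inside the
    feature is reached without hitting an untolerated gap.
    """
    if strand == "+":
        if downstream_feature.start < hairpin[1]:
            raise ValueError("downstream feature is not 3' of the hairpin")
        path = range(hairpin[1], downstream_feature.end)
        in_feature = lambda p: p >= downstream_feature.start
    else:
        if downstream_feature.end > hairpin[0]:
            raise ValueError("downstream feature is not 3' of the hairpin")
        path = range(hairpin[0] - 1, downstream_feature.start - 1, -1)
        in_feature = lambda p: p < downstream_feature.end

    gaps: list = []
    gap_run: list = []

    def _gap_ok(run: list) -> bool:
        if len(run) > max_gap:
            return False
        lo, hi = min(run), max(run) + 1
        seq = genome.slice(lo, hi, strand)
        return seq.count("A") / len(seq) >= a_frac

    for p in path:
        if track.depth_at(p) >= min_depth:
            if gap_run:
                if not _gap_ok(gap_run):
                    return ReadthroughCall(locus_id=locus_id, bridged=False,
                                           gaps_tolerated=gaps, reached_feature=None)
                gaps.append((min(gap_run), max(gap_run) + 1))
                gap_run = []
            if in_feature(p):
                return ReadthroughCall(locus_id=locus_id, bridged=True,
                                       gaps_tolerated=gaps,
                                       reached_feature=downstream_feature.id)
        else:
            gap_run.append(p)
    return ReadthroughCall(locus_id=locus_id, bridged=False,
                           gaps_tolerated=gaps, reached_feature=None)


def end_census(ends: Sequence, counts: Optional[Sequence[int]] = None) -> dict:
    """Census of discrete 3'-end observations (clone or read ends).

    ``ends`` are relative coordinates (ints or RelCoords); returns
    ``{"counts": {value: n}, "dominant": value, "total": n}`` with the
    dominant end being the most observed, ties resolved 3'-most.  Empty
    input yields an empty census.
    """
    vals = [e.value if isinstance(e, RelCoord) else int(e) for e in ends]
    if counts is None:
        counts = [1] * len(vals)
    tally: dict = {}
    for v, c in zip(vals, counts):
        tally[v] = tally.get(v, 0) + c
    if not tally:
        return {"counts": {}, "dominant": None, "total": 0}
    dominant = max(sorted(tally), key=lambda v: (tally[v], v))
    return {"counts": dict(sorted(tally.items())), "dominant": dominant,
            "total": sum(tally.values())}
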