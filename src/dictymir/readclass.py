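"""Size distribution and hierarchical classification of small-RNA reads.

Reads are assigned to the single highest-priority annotation class among the
features they overlap by at least half of their length; mRNA overlap is
split by strand into sense/antisense; reads overlapping no qualifying
feature are intergenic (which is where miRNA-locus reads land, since
candidate hairpins are not an annotation class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .formats import AlignedSmallRead, Feature, MIN_READ_LEN, MAX_READ_LEN

__all__ = [
    "DEFAULT_PRIORITY",
    "CATEGORIES",
    "SizeHistogram",
    "ClassFractions",
    "FeatureIndex",
    "size_histogram",
    "classify_read",
    "category_fractions",
]

#: Default class priority.  Structured ncRNAs first (unambiguous
#: annotations), then repeats before mRNA so that the dominant
#: retrotransposon class absorbs reads that also touch gene models.
DEFAULT_PRIORITY = (
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "SRP",
    "classI",
    "DIRS1",
    "complex_repeat",
    "mRNA_sense",
    "mRNA_antisense",
    "intergenic",
)

CATEGORIES = DEFAULT_PRIORITY

# feature types folded into the mRNA sense/antisense categories
_MRNA_TYPES = {"mRNA", "exon", "intron"}
# feature types that are never classification categories
_IGNORED_TYPES = {"hairpin_candidate", "gene_downstream"}


@dataclass
class SizeHistogram:
    """Read counts per length over the library window (18-40 nt)."""

    counts: dict
    condition: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def modal_length(self) -> int:
        return max(self.counts, key=lambda k: (self.counts[k], -k))


@dataclass
class ClassFractions:
    """Per-category fraction of (length-filtered) reads; sums to 1."""

    fractions: dict
    n_reads: float
    length_filter: Optional[int] = 21

    def __post_init__(self) -> None:
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {s}, not 1")


class FeatureIndex:
    """Per-segment interval index over annotation features."""

    def __init__(self, features: Iterable[Feature]):
        self._trees: dict = {}
        for f in features:
            if f.ftype in _IGNORED_TYPES:
                continue
            self._trees.setdefault(f.segment_id, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, segment_id: str, start: int, end: int) -> list:
        tree = self._trees.get(segment_id)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def size_histogram(reads: Sequence[AlignedSmallRead], condition: str = "") -> SizeHistogram:
    """Exhaustive, non-overlapping binning of reads by read length."""
    counts = {n: 0 for n in range(MIN_READ_LEN, MAX_READ_LEN + 1)}
    for r in reads:
        counts[len(r.seq)] += 1
    return SizeHistogram(counts=counts, condition=condition)


def _category_of(feature: Feature, read_strand: str) -> str:
    if feature.ftype in _MRNA_TYPES:
        return "mRNA_sense" if feature.strand == read_strand else "mRNA_antisense"
    if feature.ftype == "DIRS1" or feature.family == "DIRS1":
        return "DIRS1"
    return feature.ftype


def classify_read(
    read: AlignedSmallRead,
    index: FeatureIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> str:
    """Single category of a read: the highest-priority class among features
    overlapped by >= 50% of the read's templated span; else intergenic."""
    span = read.end - read.start
    half = span / 2.0
    hits = set()
    for f in index.overlapping(read.segment_id, read.start, read.end):
        ov = min(read.end, f.end) - max(read.start, f.start)
        if ov >= half:
            hits.add(_category_of(f, read.strand))
    for cat in priority:
        if cat == "intergenic":
            return "intergenic"
        if cat in hits:
            return cat
    return "intergenic"


def category_fractions(
    reads: Sequence[AlignedSmallRead],
    features: Iterable[Feature],
    length_filter: Optional[int] = 21,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    weight_by_hits: bool = False,
    index: Optional[FeatureIndex] = None,
) -> ClassFractions:
    """Per-category fractions of reads passing the length filter.

    Multimappers are counted once at their reported placement by default;
    ``weight_by_hits`` switches to fractional 1/hits weighting.
    """
    index = index if index is not None else FeatureIndex(features)
    weights: dict = {c: 0.0 for c in priority}
    total = 0.0
    for r in reads:
        if length_filter is not None and len(r.seq) != length_filter:
            continue
        w = 1.0 / r.hits if weight_by_hits else 1.0
        weights[classify_read(r, index, priority)] += w
        total += w
    if total == 0:
        raise ValueError("empty denominator: no reads pass the length filter")
    return ClassFractions(
        fractions={c: weights[c] / total for c in priority},
        n_reads=total,
        length_filter=length_filter,
    )
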