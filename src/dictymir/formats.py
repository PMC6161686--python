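"""External representations and coordinate conventions.

Everything downstream works in 0-based half-open genomic intervals on named
segments.  The signed, zero-free coordinate system used for reporting
(position +1 is the first nucleotide of mir-5p, upstream positions are
negative, there is no position 0) exists only at the boundary, via
:func:`to_relative` / :func:`from_relative` / :func:`span_length`.

File formats handled here: FASTA (genome), GFF3 (features), SAM or a TSV
dialect (small-RNA alignments), bedGraph (per-base coverage), TSV (reports).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "GenomeSegment",
    "Feature",
    "AlignedSmallRead",
    "CoverageTrack",
    "RelCoord",
    "FEATURE_TYPES",
    "FormatError",
    "to_relative",
    "from_relative",
    "span_length",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_alignments",
    "write_alignments",
    "read_bedgraph",
    "write_bedgraph",
    "write_report",
    "revcomp",
]

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature classes recognised in GFF3 column 3.
FEATURE_TYPES = frozenset(
    {
        "tRNA",
        "rRNA",
        "snoRNA",
        "snRNA",
        "SRP",
        "classI",
        "mRNA",
        "exon",
        "intron",
        "DIRS1",
        "complex_repeat",
        "hairpin_candidate",
        "gene_downstream",
    }
)

# Small-RNA library insert window (sequencing protocol bound).
MIN_READ_LEN = 18
MAX_READ_LEN = 40


class FormatError(ValueError):
    """Raised for malformed external files, with position information."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSegment:
    """A named DNA sequence (chromosome, contig or synthetic segment)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("segment id must be non-empty")
        if not self.sequence:
            raise ValueError(f"segment {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"segment {self.id!r}: illegal character {self.sequence[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) read in the orientation of ``strand``."""
        s = self.sequence[start:end]
        return s if strand == "+" else revcomp(s)


@dataclass
class Feature:
    """An annotated interval: ncRNA class, repeat, exon, or candidate hairpin."""

    id: str
    ftype: str
    segment_id: str
    start: int
    end: int
    strand: str
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"feature {self.id!r}: unknown ftype {self.ftype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.id!r}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignedSmallRead:
    """One small-RNA read placed on the genome.

    ``start``/``end`` delimit the aligned (templated) span; ``seq`` is the full
    read and may extend past the templated span at the 3' end (untemplated
    tail, soft-clip convention).  ``hits`` is the number of genomic placements
    of the read; this record is its reported (primary) placement.
    """

    read_id: str
    seq: str
    segment_id: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    hits: int = 1

    def __post_init__(self) -> None:
        n = len(self.seq)
        if not (MIN_READ_LEN <= n <= MAX_READ_LEN):
            raise ValueError(f"read {self.read_id!r}: length {n} outside [{MIN_READ_LEN}, {MAX_READ_LEN}]")
        if not (0 <= self.start < self.end):
            raise ValueError(f"read {self.read_id!r}: bad interval [{self.start}, {self.end})")
        if self.end - self.start > n:
            raise ValueError(f"read {self.read_id!r}: templated span longer than read")
        if self.strand not in "+-":
            raise ValueError(f"read {self.read_id!r}: bad strand {self.strand!r}")
        if self.mismatches < 0 or self.hits < 1:
            raise ValueError(f"read {self.read_id!r}: bad mismatches/hits")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Strand-specific per-base depth over one segment (or a window of it).

    ``counts[i]`` is the depth at genomic position ``start + i``.
    ``library_size`` is the total number of mapped reads in the library and is
    used for per-million scaling; it need not equal the sum over the window.
    """

    segment_id: str
    strand: str
    counts: np.ndarray
    start: int = 0
    library_size: int = 1_000_000

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("coverage counts must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def depth_at(self, pos: int) -> int:
        i = pos - self.start
        if 0 <= i < len(self.counts):
            return int(self.counts[i])
        return 0

    def window(self, start: int, end: int) -> np.ndarray:
        """Depth array over genomic [start, end), zero-padded outside the track."""
        out = np.zeros(end - start, dtype=np.int64)
        lo = max(start, self.start)
        hi = min(end, self.start + len(self.counts))
        if lo < hi:
            out[lo - start : hi - start] = self.counts[lo - self.start : hi - self.start]
        return out


@dataclass(frozen=True)
class RelCoord:
    """Signed, zero-free position relative to the first nucleotide of mir-5p.

    +1 is the anchor itself; upstream (5' of the anchor in transcription
    sense) is negative.  There is no position 0.
    """

    value: int
    anchor: int
    strand: str

    def __post_init__(self) -> None:
        if self.value == 0:
            raise ValueError("RelCoord value 0 is forbidden")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def to_relative(pos: int, anchor: int, strand: str) -> RelCoord:
    """Convert a 0-based genomic position to the mir-5p-relative system.

    On the + strand ``pos == anchor`` maps to +1 and ``pos == anchor - 1`` to
    -1; the - strand is mirrored so that +1 is always the mir-5p first
    nucleotide and upstream of it (in transcription sense) is negative.
    """
    if strand == "+":
        value = pos - anchor + 1 if pos >= anchor else pos - anchor
    elif strand == "-":
        value = anchor - pos + 1 if pos <= anchor else anchor - pos
    else:
        raise ValueError(f"bad strand {strand!r}")
    return RelCoord(value=value, anchor=anchor, strand=strand)


def from_relative(rel: RelCoord) -> int:
    """Inverse of :func:`to_relative`."""
    v, anchor = rel.value, rel.anchor
    if rel.strand == "+":
        return anchor + v - 1 if v > 0 else anchor + v
    return anchor - v + 1 if v > 0 else anchor - v


def _relvalue(x: Union[int, RelCoord]) -> int:
    return x.value if isinstance(x, RelCoord) else int(x)


def span_length(a: Union[int, RelCoord], b: Union[int, RelCoord]) -> int:
    """Length in nt of the inclusive run of relative positions from a to b.

    The relative axis has no position 0, so a span straddling the origin is
    one shorter than plain inclusive arithmetic would give: for a < 0 < b the
    length is abs(a) + b, otherwise b - a + 1.
    """
    av, bv = _relvalue(a), _relvalue(b)
    if av == 0 or bv == 0:
        raise ValueError("relative coordinates cannot be 0")
    if av >= bv:
        raise ValueError(f"span requires a < b, got ({av}, {bv})")
    if av < 0 < bv:
        return -av + bv
    return bv - av + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[GenomeSegment]:
    """Read a FASTA file; sequences are upper-cased and U is mapped to T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    segments = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _DNA
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(f"{path}: record {rec.id!r}: illegal character {seq[pos]!r} at position {pos}")
        segments.append(GenomeSegment(id=rec.id, sequence=seq))
    return segments


def write_fasta(segments: Iterable[GenomeSegment], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.id}\n")
            for i in range(0, len(seg.sequence), width):
                fh.write(seg.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: Union[str, Path]) -> list[Feature]:
    """Read features from GFF3; ftype in column 3, family in the attributes."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            try:
                feats.append(
                    Feature(
                        id=attr.get("ID", f"feat{lineno}"),
                        ftype=ftype,
                        segment_id=seqid,
                        start=start,
                        end=end,
                        strand=strand,
                        family=attr.get("family"),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return feats


def write_gff3(features: Iterable[Feature], path: Union[str, Path], header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(f"# {header}\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.family:
                attrs += f";family={f.family}"
            fh.write(
                "\t".join(
                    [f.segment_id, "dictymir", f.ftype, str(f.start + 1), str(f.end), ".", f.strand, ".", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Alignments: TSV dialect and SAM
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["read_id", "segment", "start", "end", "strand", "seq", "mismatches", "hits"]


def read_alignments(path: Union[str, Path], dialect: str = "tsv") -> list[AlignedSmallRead]:
    """Read small-RNA alignments.

    dialect "tsv": the package's lossless tabular dialect (header required).
    dialect "sam": mapped primary records only; NM/NH tags give mismatches
    and placement counts when present.
    """
    if dialect == "tsv":
        return _read_alignments_tsv(path)
    if dialect == "sam":
        return _read_alignments_sam(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_alignments_tsv(path: Union[str, Path]) -> list[AlignedSmallRead]:
    reads: list[AlignedSmallRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return []
        if header.split("\t") != _TSV_COLUMNS:
            raise FormatError(f"{path}:1: bad header, expected {_TSV_COLUMNS}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            try:
                reads.append(
                    AlignedSmallRead(
                        read_id=cols[0],
                        segment_id=cols[1],
                        start=int(cols[2]),
                        end=int(cols[3]),
                        strand=cols[4],
                        seq=cols[5],
                        mismatches=int(cols[6]),
                        hits=int(cols[7]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def _read_alignments_sam(path: Union[str, Path]) -> list[AlignedSmallRead]:
    reads: list[AlignedSmallRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = (rec.query_sequence or "").upper()
            if rec.is_reverse:
                # store the read in genome-forward orientation? no: keep the
                # read sequence as sequenced (locus sense); pysam returns the
                # forward-genome sequence, so flip back for - strand reads.
                seq = revcomp(seq)
            reads.append(
                AlignedSmallRead(
                    read_id=rec.query_name,
                    seq=seq,
                    segment_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    hits=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
                )
            )
    return reads


def write_alignments(reads: Iterable[AlignedSmallRead], path: Union[str, Path]) -> None:
    """Write the TSV alignment dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                "\t".join(
                    [r.read_id, r.segment_id, str(r.start), str(r.end), r.strand, r.seq, str(r.mismatches), str(r.hits)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: Union[str, Path],
    segment_id: str,
    segment_length: int,
    strand: str,
    library_size: int = 1_000_000,
) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-base track (one strand)."""
    counts = np.zeros(segment_length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            seg, s, e, v = cols
            if seg != segment_id:
                continue
            try:
                counts[int(s) : int(e)] = int(float(v))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return CoverageTrack(segment_id=segment_id, strand=strand, counts=counts, library_size=library_size)


def write_bedgraph(track: CoverageTrack, path: Union[str, Path], name: Optional[str] = None) -> None:
    """Write a dense track as run-length-collapsed bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        c = track.counts
        n = len(c)
        i = 0
        while i < n:
            j = i
            while j < n and c[j] == c[i]:
                j += 1
            if c[i] != 0:
                fh.write(f"{track.segment_id}\t{track.start + i}\t{track.start + j}\t{int(c[i])}\n")
            i = j


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(rows: Sequence, path: Union[str, Path], header_comment: Optional[str] = None) -> None:
    """Write dataclass instances or dicts as a TSV report."""
    rows = list(rows)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if not rows:
            return
        first = rows[0]
        if dataclasses.is_dataclass(first):
            rows = [dataclasses.asdict(r) for r in rows]
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
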