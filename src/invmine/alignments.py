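"""Alignment-record domain model and SAM/BAM input/output.

All coordinates inside the package are 0-based, half-open.  SAM's 1-based
POS is converted at the pysam boundary; VCF POS likewise in
:mod:`invmine.candidates`.  Only the fields of the SAM record that carry
inversion evidence are modelled: flags, CIGAR, mapping quality, template
length (the observed insert size, ISPE) and the ``XT``/``NM``/``XA``
optional tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam

#: CIGAR operations that consume query (read) bases.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("MDN=X")

_OPS = "MIDNSHP=X"


class InsufficientDataError(RuntimeError):
    """Raised when too few usable records are available for an estimate."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def padded(self, pad: int) -> "GenomicInterval":
        """Interval enlarged by ``pad`` on both sides, clamped at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance between two intervals on the same chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        return max(0, max(other.start - self.end, self.start - other.end))


@dataclass(frozen=True)
class LibraryStats:
    """Summary of the sequencing library: insert-size distribution and read length."""

    ispe_mean: float
    ispe_sd: float
    read_length_mode: int

    def __post_init__(self) -> None:
        if self.ispe_mean <= 0 or self.ispe_sd < 0:
            raise ValueError("ispe_mean must be > 0 and ispe_sd >= 0")


@dataclass
class AlignmentRecord:
    """One mapped (or placed-unmapped) read.

    ``template_length`` follows SAM TLEN conventions: signed, positive for the
    leftmost mate of a mapped pair, 0 when undefined.  ``tags`` holds optional
    tags keyed by their 2-character name; ``XT`` ('U' unique / 'R' repeat),
    ``NM`` (edit distance) and ``XA`` (alternative hits) are honored downstream.
    """

    query_name: str
    chrom: str
    pos: int
    mapq: int = 0
    cigar: list = field(default_factory=list)  # [(op_char, length), ...]
    is_reverse: bool = False
    mate_is_reverse: bool = False
    mate_is_unmapped: bool = False
    is_unmapped: bool = False
    is_paired: bool = True
    is_read1: bool = True
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    template_length: int = 0
    read_length: int = 0
    mate_pos: int = -1
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for {self.query_name}")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"MAPQ {self.mapq} outside [0, 255]")
        if not self.read_length and self.cigar:
            self.read_length = self.query_length_from_cigar
        if self.cigar and self.read_length != self.query_length_from_cigar:
            raise ValueError(
                f"read_length {self.read_length} inconsistent with CIGAR "
                f"{self.cigar_string} for {self.query_name}"
            )

    @property
    def query_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    @property
    def reference_span(self) -> int:
        """Reference bases consumed by the alignment (0 if unmapped)."""
        if self.is_unmapped:
            return 0
        return sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) or "*"

    @property
    def clipped_bases(self) -> int:
        return sum(n for op, n in self.cigar if op == "S")

    def overlaps(self, interval: GenomicInterval) -> bool:
        """Any mapped base inside ``interval``; placed-unmapped reads by position."""
        if self.chrom != interval.chrom:
            return False
        if self.is_unmapped:
            return interval.start <= self.pos < interval.end
        return self.pos < interval.end and self.reference_end > interval.start


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [(_OPS[op], n) for op, n in (seg.cigartuples or [])]
    if cigar:
        read_length = sum(n for op, n in cigar if op in QUERY_OPS)
    else:
        read_length = seg.query_length or 0
    tags = {tag: value for tag, value in seg.get_tags()}
    return AlignmentRecord(
        query_name=seg.query_name,
        chrom=seg.reference_name or "*",
        pos=max(0, seg.reference_start),
        mapq=seg.mapping_quality,
        cigar=cigar,
        is_reverse=seg.is_reverse,
        mate_is_reverse=seg.mate_is_reverse if seg.is_paired else False,
        mate_is_unmapped=seg.mate_is_unmapped if seg.is_paired else False,
        is_unmapped=seg.is_unmapped,
        is_paired=seg.is_paired,
        is_read1=(not seg.is_paired) or seg.is_read1,
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
        is_duplicate=seg.is_duplicate,
        template_length=seg.template_length,
        read_length=read_length,
        mate_pos=seg.next_reference_start if seg.is_paired else -1,
        tags=tags,
    )


def _to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.query_name
    seg.reference_id = header.get_tid(rec.chrom) if not rec.is_unmapped or rec.mate_pos >= 0 else -1
    if seg.reference_id < 0 and rec.chrom != "*":
        seg.reference_id = header.get_tid(rec.chrom)
    seg.reference_start = rec.pos
    seg.mapping_quality = rec.mapq
    seg.is_paired = rec.is_paired
    seg.is_unmapped = rec.is_unmapped
    seg.is_reverse = rec.is_reverse
    seg.is_secondary = rec.is_secondary
    seg.is_supplementary = rec.is_supplementary
    seg.is_duplicate = rec.is_duplicate
    if rec.is_paired:
        seg.is_read1 = rec.is_read1
        seg.is_read2 = not rec.is_read1
        seg.mate_is_reverse = rec.mate_is_reverse
        seg.mate_is_unmapped = rec.mate_is_unmapped
        seg.next_reference_id = header.get_tid(rec.chrom) if rec.mate_pos >= 0 else -1
        seg.next_reference_start = rec.mate_pos
    seg.template_length = rec.template_length
    if rec.cigar:
        seg.cigartuples = [(_OPS.index(op), n) for op, n in rec.cigar]
    elif rec.read_length:
        # unmapped mate placed at its partner: no CIGAR, carry length via SEQ
        seg.query_sequence = "N" * rec.read_length
    if rec.tags:
        for tag, value in sorted(rec.tags.items()):
            seg.set_tag(tag, value)
    return seg


def read_alignments(
    path, region: Optional[GenomicInterval] = None
) -> Iterator[AlignmentRecord]:
    """Iterate records from a SAM/BAM file, optionally restricted to ``region``.

    With an index (BAM + .bai) the regional query uses it; otherwise the file
    is streamed and filtered.  A record overlaps the region when any mapped
    base falls inside it; placed-unmapped mates count by their placement.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as handle:
        use_index = region is not None and handle.has_index()
        iterator = (
            handle.fetch(region.chrom, region.start, region.end)
            if use_index
            else handle
        )
        for i, seg in enumerate(iterator):
            try:
                rec = _from_pysam(seg)
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed alignment record #{i} in {path}: {exc}")
            if region is not None and not use_index and not rec.overlaps(region):
                continue
            yield rec


def write_alignments(records: Iterable[AlignmentRecord], path, chrom: str, chrom_length: int) -> None:
    """Write records as coordinate-sorted SAM (or BAM if the path ends in .bam)."""
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(chrom_length)}],
    }
    mode = "wb" if path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rec in records:
            out.write(_to_pysam(rec, out.header))


def records_overlapping(
    records: Iterable[AlignmentRecord], interval: GenomicInterval
) -> list:
    """Subset of in-memory records overlapping ``interval``."""
    return [rec for rec in records if rec.overlaps(interval)]


def estimate_library_stats(
    alignments: Iterable[AlignmentRecord],
    max_records: int = 200_000,
    tlen_cap: int = 10_000,
    min_pairs: int = 50,
    include_secondary: bool = False,
) -> LibraryStats:
    """Estimate the insert-size distribution from concordantly oriented pairs.

    Uses |TLEN| of opposite-strand, both-mapped primary pairs with
    0 < |TLEN| < ``tlen_cap`` (each pair counted once, at its leftmost mate),
    among the first ``max_records`` records.  The cap excludes chimeric and
    inter-chromosomal artifacts.
    """
    tlens = []
    read_lengths: Counter = Counter()
    seen = 0
    for rec in alignments:
        if seen >= max_records:
            break
        seen += 1
        if rec.is_unmapped:
            continue
        if not include_secondary and (rec.is_secondary or rec.is_supplementary):
            continue
        if rec.read_length:
            read_lengths[rec.read_length] += 1
        if not rec.is_paired or rec.mate_is_unmapped:
            continue
        if rec.is_reverse == rec.mate_is_reverse:
            continue
        tlen = rec.template_length
        if 0 < tlen < tlen_cap:  # leftmost mate only: counts each pair once
            tlens.append(tlen)
    if len(tlens) < min_pairs:
        raise InsufficientDataError(
            f"only {len(tlens)} usable pairs (need >= {min_pairs}) "
            f"in first {seen} records"
        )
    arr = np.asarray(tlens, dtype=float)
    mode_rl = read_lengths.most_common(1)[0][0] if read_lengths else 0
    return LibraryStats(
        ispe_mean=float(arr.mean()),
        ispe_sd=float(arr.std(ddof=0)),
        read_length_mode=int(mode_rl),
    )
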