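"""Candidate inversion sites: ingestion from upstream callers, union, filters.

Upstream structural-variant callers (Pindel, Delly, Lumpy, ...) are consumed
as files only — VCF records with ``SVTYPE=INV`` or plain BED intervals.  The
candidate set is the union of all calls, with near-duplicate breakpoint pairs
collapsed, and candidates shorter than the library mean insert size dropped
(such events cannot perturb the insert-size distribution and are outside the
model's assumptions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pysam

from .alignments import GenomicInterval, LibraryStats

logger = logging.getLogger(__name__)


@dataclass
class CandidateInversion:
    region: GenomicInterval
    sources: set
    ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("candidate must name at least one source caller")


def read_caller_calls(path, caller_name: str) -> List[CandidateInversion]:
    """Load one caller's inversion calls from VCF (SVTYPE=INV) or BED.

    VCF coordinates convert to 0-based half-open as [POS-1, END); when END is
    absent, SVLEN defines the span; records with neither are skipped with a
    counted warning.  BED intervals are taken as-is.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path, caller_name)
    return _read_bed(path, caller_name)


def _read_vcf(path: str, caller: str) -> List[CandidateInversion]:
    from cyvcf2 import VCF

    out: List[CandidateInversion] = []
    skipped = 0
    for i, variant in enumerate(VCF(path)):
        if variant.INFO.get("SVTYPE") != "INV":
            continue
        start = variant.POS - 1
        end = variant.INFO.get("END")
        if end is None:
            svlen = variant.INFO.get("SVLEN")
            if svlen is None:
                skipped += 1
                continue
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            end = start + abs(int(svlen))
        record_id = variant.ID or f"{caller}:{i}"
        out.append(
            CandidateInversion(
                region=GenomicInterval(str(variant.CHROM), start, int(end)),
                sources={caller},
                ids={record_id},
            )
        )
    if skipped:
        logger.warning(
            "%s: skipped %d INV record(s) lacking both END and SVLEN", path, skipped
        )
    return out


def _read_bed(path: str, caller: str) -> List[CandidateInversion]:
    out: List[CandidateInversion] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            record_id = fields[3] if len(fields) > 3 else f"{caller}:{i}"
            out.append(
                CandidateInversion(
                    region=GenomicInterval(chrom, start, end),
                    sources={caller},
                    ids={record_id},
                )
            )
    return out


def merge_candidates(
    calls: Sequence[CandidateInversion], eps: int = 10
) -> List[CandidateInversion]:
    """Union of calls with near-duplicates collapsed.

    Two calls collapse when both breakpoints agree within ``eps`` bp; the
    first-seen call's breakpoints are kept and sources/ids are unioned.
    ``eps=0`` collapses exact duplicates only.  Output sorted by position.
    The operation is idempotent.
    """
    merged: List[CandidateInversion] = []
    for call in calls:
        hit = None
        for existing in merged:
            if (
                existing.region.chrom == call.region.chrom
                and abs(existing.region.start - call.region.start) <= eps
                and abs(existing.region.end - call.region.end) <= eps
            ):
                hit = existing
                break
        if hit is not None:
            hit.sources |= call.sources
            hit.ids |= call.ids
        else:
            merged.append(
                CandidateInversion(
                    region=call.region,
                    sources=set(call.sources),
                    ids=set(call.ids),
                )
            )
    merged.sort(key=lambda c: (c.region.chrom, c.region.start, c.region.end))
    return merged


def filter_by_length(
    calls: Sequence[CandidateInversion], stats: LibraryStats
) -> List[CandidateInversion]:
    """Keep candidates at least as long as the library mean insert size."""
    return [c for c in calls if c.region.length >= stats.ispe_mean]


# ---------------------------------------------------------------------------
# output formats

def write_candidates_bed(calls: Sequence[CandidateInversion], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsources\n")
        for c in calls:
            fh.write(
                f"{c.region.chrom}\t{c.region.start}\t{c.region.end}\t"
                f"{','.join(sorted(c.sources))}\n"
            )


def write_calls_vcf(
    calls: Sequence[CandidateInversion], path, contigs: Dict[str, int]
) -> None:
    """Write final inversion calls as VCF v4.2 with SVTYPE=INV records."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={int(length)}>")
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line(
        '##INFO=<ID=SOURCES,Number=.,Type=String,Description="Supporting caller(s)">'
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, c in enumerate(calls):
            rec = out.new_record(
                contig=c.region.chrom,
                start=c.region.start,
                stop=c.region.end,
                alleles=("N", "<INV>"),
                id=f"inv{i + 1}",
            )
            rec.info["SVTYPE"] = "INV"
            rec.info["SOURCES"] = ",".join(sorted(c.sources))
            out.write(rec)


def pseudo_caller(
    truth_inversions: Sequence[GenomicInterval],
    decoys: Sequence[GenomicInterval] = (),
    jitter: int = 30,
    seed: int = 0,
    name: str = "pseudo",
) -> List[CandidateInversion]:
    """Derive jittered candidates from known inversions, plus decoy intervals.

    Stands in for upstream callers when exercising the pipeline offline:
    every true inversion appears with breakpoints offset by up to ``jitter``
    bp, and each decoy (typically a wild-type window) appears verbatim.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    out: List[CandidateInversion] = []
    for i, iv in enumerate(truth_inversions):
        if jitter > 0:
            ds, de = rng.integers(-jitter, jitter + 1, size=2)
        else:
            ds = de = 0
        start = max(0, iv.start + int(ds))
        end = iv.end + int(de)
        out.append(
            CandidateInversion(
                region=GenomicInterval(iv.chrom, start, max(end, start + 1)),
                sources={name},
                ids={f"{name}_inv{i}"},
            )
        )
    for i, iv in enumerate(decoys):
        out.append(
            CandidateInversion(region=iv, sources={name}, ids={f"{name}_decoy{i}"})
        )
    return out
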