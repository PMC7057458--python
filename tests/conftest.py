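import numpy as np
import pytest

from invmine import (
    AlignmentRecord,
    GenomicInterval,
    LibraryStats,
    SimulationConfig,
    simulate_sample,
)


def make_pair(
    qname,
    pos1,
    pos2,
    rl=100,
    reverse1=False,
    reverse2=True,
    mapq=60,
    nm=0,
    chrom="sim",
    cigar1=None,
    cigar2=None,
    tags_extra=None,
):
    """A both-mapped read pair with consistent mate fields and TLEN."""
    cigar1 = cigar1 or [("M", rl)]
    cigar2 = cigar2 or [("M", rl)]
    span1 = sum(n for op, n in cigar1 if op in "MDN=X")
    span2 = sum(n for op, n in cigar2 if op in "MDN=X")
    tlen = max(pos1 + span1, pos2 + span2) - min(pos1, pos2)
    sign1 = 1 if pos1 <= pos2 else -1
    tags = {"XT": "U", "NM": nm}
    if tags_extra:
        tags.update(tags_extra)
    r1 = AlignmentRecord(
        query_name=qname, chrom=chrom, pos=pos1, mapq=mapq, cigar=cigar1,
        is_reverse=reverse1, mate_is_reverse=reverse2, is_read1=True,
        template_length=sign1 * tlen, mate_pos=pos2, tags=dict(tags),
    )
    r2 = AlignmentRecord(
        query_name=qname, chrom=chrom, pos=pos2, mapq=mapq, cigar=cigar2,
        is_reverse=reverse2, mate_is_reverse=reverse1, is_read1=False,
        template_length=-sign1 * tlen, mate_pos=pos1, tags=dict(tags),
    )
    return r1, r2


def make_single(
    qname, pos, rl=100, reverse=False, mapq=60, nm=0, chrom="sim", cigar=None,
    mate_unmapped=True, mate_reverse=False, tlen=0, tags_extra=None,
):
    """One mapped read without its mate record (mate unmapped by default)."""
    tags = {"XT": "U", "NM": nm}
    if tags_extra:
        tags.update(tags_extra)
    return AlignmentRecord(
        query_name=qname, chrom=chrom, pos=pos, mapq=mapq,
        cigar=cigar or [("M", rl)], is_reverse=reverse,
        mate_is_reverse=mate_reverse, mate_is_unmapped=mate_unmapped,
        template_length=tlen, mate_pos=pos, tags=tags,
    )


@pytest.fixture
def pair_factory():
    return make_pair


@pytest.fixture
def single_factory():
    return make_single


@pytest.fixture(scope="session")
def sim_config():
    """A small mixed-zygosity sample used across tests."""
    return SimulationConfig(
        ref_length=40_000,
        inversions=[
            (GenomicInterval("sim", 3_000, 5_000), "hom"),
            (GenomicInterval("sim", 14_000, 16_500), "het"),
            (GenomicInterval("sim", 30_000, 31_200), "hom"),
        ],
        ispe_mean=400.0,
        ispe_sd=30.0,
        error_rate=0.004,
        read_length=100,
        depth=15.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def sim_sample(sim_config):
    records, truth = simulate_sample(sim_config)
    return records, truth


@pytest.fixture(scope="session")
def sim_stats(sim_sample):
    from invmine import estimate_library_stats

    records, _ = sim_sample
    return estimate_library_stats(records)


@pytest.fixture
def default_stats():
    return LibraryStats(ispe_mean=400.0, ispe_sd=30.0, read_length_mode=100)
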