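"""Paired-end alignment simulator for genomes carrying inversions.

The simulator samples fragments from a synthetic diploid donor and emits
the alignment records a short-read mapper would produce on the reference,
rather than raw reads: a read wholly inside an inverted segment is placed at
the mirrored reference position on the opposite strand (yielding same-strand
pairs when exactly one mate lies inside), a read crossing a breakpoint is
soft-clipped at the breakpoint when its mapped anchor is long enough, and is
emitted as a placed-unmapped mate otherwise.  This keeps every inversion
signature controllable and the package self-contained.

The default parameter ranges used by :func:`random_config` describe the
training conditions: inversion length 500-6000 bp, mean insert size (ISPE)
300-500, base error rate 0.003-0.005, read length 70-150, depth 4-25, and
a 20-30 bp jitter on the recorded truth breakpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignments import (
    AlignmentRecord,
    GenomicInterval,
    LibraryStats,
    write_alignments,
)
from .features import padded_window

CHROM = "sim"

ZYGOSITIES = ("het", "hom")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated sample.

    ``inversions`` is a list of ``(interval, zygosity)`` with zygosity
    ``"het"`` (one haplotype) or ``"hom"`` (both).  Every inversion must be
    at least ``ispe_mean`` long: shorter events do not perturb the insert
    size distribution and are out of the model's reach.  ``jitter_range``
    is the magnitude range of the uniform offset applied to the *recorded*
    truth breakpoints (the implanted event itself is exact); ``(0, 0)``
    disables it.
    """

    ref_length: int
    inversions: List[Tuple[GenomicInterval, str]]
    ispe_mean: float = 400.0
    ispe_sd: float = 40.0
    error_rate: float = 0.004
    read_length: int = 100
    depth: float = 10.0
    min_anchor: int = 20
    crossing_fail_rate: float = 0.15
    jitter_range: Tuple[int, int] = (20, 30)
    seed: int = 0

    def validate(self) -> None:
        if self.ref_length <= 0:
            raise ConfigError("ref_length must be positive")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.min_anchor >= self.read_length:
            raise ConfigError("min_anchor must be < read_length")
        if not 0 <= self.crossing_fail_rate < 1:
            raise ConfigError("crossing_fail_rate must be in [0, 1)")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.jitter_range[0] > self.jitter_range[1] or self.jitter_range[0] < 0:
            raise ConfigError("invalid jitter_range")
        prev_end = None
        for iv, zyg in sorted(self.inversions, key=lambda t: t[0].start):
            if zyg not in ZYGOSITIES:
                raise ConfigError(f"unknown zygosity {zyg!r}")
            if iv.end > self.ref_length:
                raise ConfigError(
                    f"inversion {iv.start}-{iv.end} extends past ref_length"
                )
            if iv.length < self.ispe_mean:
                raise ConfigError(
                    f"inversion length {iv.length} shorter than mean ISPE "
                    f"{self.ispe_mean}"
                )
            if prev_end is not None and iv.start < prev_end:
                raise ConfigError("inversions overlap")
            prev_end = iv.end

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inversions"] = [
            [iv.chrom, iv.start, iv.end, zyg] for iv, zyg in self.inversions
        ]
        d["jitter_range"] = list(self.jitter_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["inversions"] = [
            (GenomicInterval(str(c), int(s), int(e)), str(z))
            for c, s, e, z in d["inversions"]
        ]
        d["jitter_range"] = tuple(d.get("jitter_range", (20, 30)))
        return cls(**d)


@dataclass
class TruthSet:
    """Recorded ground truth of one simulated sample.

    Wild-type windows are guaranteed to lie at least ``2 * ispe_mean`` away
    from every implanted inversion, so their feature windows never touch
    inversion evidence.
    """

    inversions: List[Tuple[GenomicInterval, str]]
    wild_type_windows: List[GenomicInterval]


# ---------------------------------------------------------------------------
# read placement

def _map_read(a: int, b: int, forward: bool, invs: Sequence[GenomicInterval], min_anchor: int):
    """Place a donor-coordinate read [a, b) on the reference.

    Returns ``None`` for an unmappable read, else a dict with ``pos``,
    ``cigar``, ``is_reverse`` and ``span`` (reference bases consumed).
    Donor coordinates coincide with reference coordinates outside inversions
    (inversions are balanced).  Inversions are assumed longer than a read and
    farther apart than a read, so a read meets at most one breakpoint.
    """
    hit = None
    for iv in invs:
        if iv.start < b and a < iv.end:
            hit = iv
            break
    length = b - a
    if hit is None:
        return {"pos": a, "cigar": [("M", length)], "is_reverse": not forward, "span": length}
    s, e = hit.start, hit.end
    if a >= s and b <= e:
        # fully inside: mirrored placement, strand flipped
        return {"pos": s + e - b, "cigar": [("M", length)], "is_reverse": forward, "span": length}
    if a < s:
        out_len, in_len = s - a, b - s
        if out_len >= in_len:
            if out_len < min_anchor:
                return None
            return {
                "pos": a,
                "cigar": [("M", out_len), ("S", in_len)],
                "is_reverse": not forward,
                "span": out_len,
            }
        if in_len < min_anchor:
            return None
        # inside anchor [s, b) mirrors to [s+e-b, e); clip beyond e
        return {
            "pos": s + e - b,
            "cigar": [("M", in_len), ("S", out_len)],
            "is_reverse": forward,
            "span": in_len,
        }
    # a < e < b: crossing the right breakpoint
    in_len, out_len = e - a, b - e
    if out_len >= in_len:
        if out_len < min_anchor:
            return None
        return {
            "pos": e,
            "cigar": [("S", in_len), ("M", out_len)],
            "is_reverse": not forward,
            "span": out_len,
        }
    if in_len < min_anchor:
        return None
    # inside anchor [a, e) mirrors to [s, s+e-a); clip before s
    return {
        "pos": s,
        "cigar": [("S", out_len), ("M", in_len)],
        "is_reverse": forward,
        "span": in_len,
    }


def _mapped_read_coords(cigar) -> Tuple[int, int]:
    """Read-coordinate range covered by M ops (for NM accounting)."""
    offset = 0
    for op, n in cigar:
        if op == "M":
            return offset, offset + n
        offset += n
    return 0, 0


def _jittered(iv: GenomicInterval, rng: np.random.Generator, jitter: Tuple[int, int], ref_length: int) -> GenomicInterval:
    lo, hi = jitter
    if hi <= 0:
        return iv
    mags = rng.integers(lo, hi + 1, size=2)
    signs = rng.choice(np.array([-1, 1]), size=2)
    start = int(max(0, iv.start + signs[0] * mags[0]))
    end = int(min(ref_length, iv.end + signs[1] * mags[1]))
    if end <= start:  # pragma: no cover - inversions far exceed jitter
        return iv
    return GenomicInterval(iv.chrom, start, end)


def _wild_type_windows(
    inversions: Sequence[GenomicInterval],
    lengths: Sequence[int],
    ispe_mean: float,
    ref_length: int,
    separation: int = 200,
) -> List[GenomicInterval]:
    """Place one wild-type window per requested length, >= 2*ISPE from any inversion."""
    guard = int(round(2 * ispe_mean))
    blocked = sorted(
        (max(0, iv.start - guard), min(ref_length, iv.end + guard)) for iv in inversions
    )
    gaps = []
    cursor = 0
    for s, e in blocked:
        if s > cursor:
            gaps.append([cursor, s])
        cursor = max(cursor, e)
    if cursor < ref_length:
        gaps.append([cursor, ref_length])

    windows: List[GenomicInterval] = []
    for length in lengths:
        placed = False
        for gap in gaps:
            if gap[1] - gap[0] >= length + separation:
                start = gap[0] + separation // 2
                windows.append(GenomicInterval(CHROM, start, start + length))
                gap[0] = start + length + separation
                placed = True
                break
        if not placed:
            break  # reference too crowded; emit what fits
    return windows


def simulate_sample(config: SimulationConfig) -> Tuple[List[AlignmentRecord], TruthSet]:
    """Simulate one sample: aligned records plus the recorded truth.

    Fragment count is ``depth * ref_length / (2 * read_length)`` so the
    expected per-base depth across both haplotypes equals ``depth``.
    Fragment length is Normal(ispe_mean, ispe_sd) truncated below at
    ``2 * read_length``.  Each fragment is assigned to one haplotype with
    probability 1/2; haplotype 0 carries all inversions, haplotype 1 only
    the homozygous ones.  Records are returned position-sorted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L, rl = config.ref_length, config.read_length

    invs_sorted = sorted((iv for iv, _ in config.inversions), key=lambda iv: iv.start)
    invs_hom = sorted(
        (iv for iv, z in config.inversions if z == "hom"), key=lambda iv: iv.start
    )

    # recorded truth (jitter drawn first so the read stream is unaffected by it)
    recorded = [
        (_jittered(iv, rng, config.jitter_range, L), zyg)
        for iv, zyg in sorted(config.inversions, key=lambda t: t[0].start)
    ]
    wt = _wild_type_windows(
        invs_sorted, [iv.length for iv in invs_sorted], config.ispe_mean, L
    )
    truth = TruthSet(inversions=recorded, wild_type_windows=wt)

    n_frags = int(round(config.depth * L / (2 * rl)))
    flens = np.clip(
        np.rint(rng.normal(config.ispe_mean, config.ispe_sd, n_frags)).astype(int),
        2 * rl,
        L,
    )
    starts = rng.integers(0, L - flens + 1)
    on_hap1 = rng.random(n_frags) < 0.5

    records: List[AlignmentRecord] = []
    for idx in range(n_frags):
        s0, flen = int(starts[idx]), int(flens[idx])
        invs = invs_hom if on_hap1[idx] else invs_sorted
        qname = f"frag{idx:07d}"
        # read 1 from the forward donor strand at the fragment start,
        # read 2 from the reverse donor strand at the fragment end
        ends = [
            _map_read(s0, s0 + rl, True, invs, config.min_anchor),
            _map_read(s0 + flen - rl, s0 + flen, False, invs, config.min_anchor),
        ]
        # breakpoint-crossing reads occasionally defeat the mapper's seeding
        # even with an adequate anchor; emulated by a per-read failure rate
        if config.crossing_fail_rate > 0:
            for i, m in enumerate(ends):
                if (
                    m is not None
                    and any(op == "S" for op, _ in m["cigar"])
                    and rng.random() < config.crossing_fail_rate
                ):
                    ends[i] = None
        if ends[0] is None and ends[1] is None:
            continue  # unreachable when min_anchor <= read_length / 2

        # sequencing errors: count the ones landing in mapped bases (NM)
        nms = []
        for m in ends:
            n_err = int(rng.binomial(rl, config.error_rate))
            if m is None or n_err == 0:
                nms.append(0)
                continue
            positions = rng.choice(rl, size=n_err, replace=False)
            m_lo, m_hi = _mapped_read_coords(m["cigar"])
            nms.append(int(np.sum((positions >= m_lo) & (positions < m_hi))))

        pair: List[Optional[AlignmentRecord]] = [None, None]
        if ends[0] is not None and ends[1] is not None:
            left_start = min(m["pos"] for m in ends)
            right_end = max(m["pos"] + m["span"] for m in ends)
            tlen_mag = right_end - left_start
            leftmost = 0 if ends[0]["pos"] <= ends[1]["pos"] else 1
            for i, m in enumerate(ends):
                other = ends[1 - i]
                pair[i] = AlignmentRecord(
                    query_name=qname,
                    chrom=CHROM,
                    pos=m["pos"],
                    mapq=60,
                    cigar=m["cigar"],
                    is_reverse=m["is_reverse"],
                    mate_is_reverse=other["is_reverse"],
                    mate_is_unmapped=False,
                    is_unmapped=False,
                    is_read1=(i == 0),
                    template_length=tlen_mag if i == leftmost else -tlen_mag,
                    read_length=rl,
                    mate_pos=other["pos"],
                    tags={"XT": "U", "NM": nms[i]},
                )
        else:
            mapped_i = 0 if ends[0] is not None else 1
            m = ends[mapped_i]
            mapped = AlignmentRecord(
                query_name=qname,
                chrom=CHROM,
                pos=m["pos"],
                mapq=60,
                cigar=m["cigar"],
                is_reverse=m["is_reverse"],
                mate_is_reverse=False,
                mate_is_unmapped=True,
                is_read1=(mapped_i == 0),
                template_length=0,
                read_length=rl,
                mate_pos=m["pos"],
                tags={"XT": "U", "NM": nms[mapped_i]},
            )
            shadow = AlignmentRecord(
                query_name=qname,
                chrom=CHROM,
                pos=m["pos"],
                mapq=0,
                cigar=[],
                is_reverse=False,
                mate_is_reverse=m["is_reverse"],
                mate_is_unmapped=False,
                is_unmapped=True,
                is_read1=(mapped_i != 0),
                template_length=0,
                read_length=rl,
                mate_pos=m["pos"],
                tags={},
            )
            pair[mapped_i], pair[1 - mapped_i] = mapped, shadow

        records.extend(p for p in pair if p is not None)

    records.sort(key=lambda r: (r.pos, r.query_name, not r.is_read1))
    return records, truth


def expected_stats(config: SimulationConfig) -> LibraryStats:
    """Nominal library statistics implied by a configuration."""
    return LibraryStats(
        ispe_mean=config.ispe_mean,
        ispe_sd=config.ispe_sd,
        read_length_mode=config.read_length,
    )


def build_training_windows(
    truth: TruthSet, stats: LibraryStats
) -> List[Tuple[GenomicInterval, int]]:
    """Labeled feature windows: one per inversion (1) and wild-type window (0)."""
    if not truth.inversions and not truth.wild_type_windows:
        raise ValueError("empty truth set")
    windows = [(padded_window(iv, stats), 1) for iv, _ in truth.inversions]
    windows += [(padded_window(w, stats), 0) for w in truth.wild_type_windows]
    return windows


def random_config(seed: int, n_inversions: int = 5) -> SimulationConfig:
    """Draw one parameter set within the canonical training ranges.

    The reference length is derived from the draws so that every inversion
    has room for a same-length wild-type window at least 2*ISPE away.
    """
    rng = np.random.default_rng(seed)
    ispe = float(rng.uniform(300, 500))
    ispe_sd = float(rng.uniform(0.05, 0.12) * ispe)
    error_rate = float(rng.uniform(0.003, 0.005))
    read_length = int(rng.integers(70, 151))
    depth = float(rng.uniform(4, 25))
    lengths = np.maximum(
        rng.integers(500, 6001, size=n_inversions), int(np.ceil(ispe))
    )

    pad = int(round(ispe))
    cursor = 3 * pad
    inversions = []
    for length in lengths:
        iv = GenomicInterval(CHROM, cursor, cursor + int(length))
        zyg = "hom" if rng.random() < 0.5 else "het"
        inversions.append((iv, zyg))
        # leave room for the paired wild-type window plus 2*ISPE guards
        cursor = iv.end + 4 * pad + int(length) + 600
    ref_length = cursor + 3 * pad

    return SimulationConfig(
        ref_length=ref_length,
        inversions=inversions,
        ispe_mean=ispe,
        ispe_sd=ispe_sd,
        error_rate=error_rate,
        read_length=read_length,
        depth=depth,
        jitter_range=(20, 30),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# on-disk artifacts

def write_truth_bed(truth: TruthSet, path) -> None:
    """Truth as BED: chrom, start, end, zygosity ('wt' for wild-type windows)."""
    with open(path, "w") as fh:
        for iv, zyg in truth.inversions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{zyg}\n")
        for w in truth.wild_type_windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\twt\n")


def read_truth_bed(path) -> TruthSet:
    inversions, wt = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, kind = line.split("\t")[:4]
            iv = GenomicInterval(chrom, int(start), int(end))
            if kind == "wt":
                wt.append(iv)
            else:
                inversions.append((iv, kind))
    return TruthSet(inversions=inversions, wild_type_windows=wt)


def simulate_to_dir(config: SimulationConfig, out_dir) -> dict:
    """Run the simulator and write sample.sam, truth.bed and config.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_sample(config)
    sam = out / "sample.sam"
    write_alignments(records, sam, CHROM, config.ref_length)
    write_truth_bed(truth, out / "truth.bed")
    # inversions alone, for use as an evaluation benchmark
    with open(out / "inversions.bed", "w") as fh:
        for iv, zyg in truth.inversions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{zyg}\n")
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return {
        "sam": str(sam),
        "truth": str(out / "truth.bed"),
        "benchmark": str(out / "inversions.bed"),
        "config": str(out / "config.json"),
        "n_records": len(records),
    }
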