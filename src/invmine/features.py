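"""Extraction of the 15 alignment-signature features around inversion breakpoints.

An inversion leaves characteristic traces in paired-end alignments near its
two breakpoints: read pairs mapped on the same strand, pairs with an abnormal
insert size (ISPE), soft-clipped reads, and pairs with one end unmapped.
Because an inversion is a balanced event, read depth itself is uninformative
and is deliberately not a feature.

Features are counted over a window obtained by padding the candidate
interval by the library mean insert size on both sides, so that the
breakpoint-crossing evidence is fully covered.

Feature catalogue (IDs 1..15):

====  =============================================
  1   uniquely mapped reads
  2   multiply mapped reads
  3   read pairs with one end unmapped
  4   clipped reads (soft-clip >= ``min_clip`` bases)
  5   reads mapped error-free (NM == 0)
  6   reads mapped with errors (NM > 0)
  7   concordant pairs (opposite strand, normal ISPE)
  8   discordant pairs (both mapped, otherwise)
  9   sum of mapping quality
 10   low-MAPQ reads
 11   middle-MAPQ reads
 12   high-MAPQ reads
 13   pairs with both ends on the reverse strand
 14   pairs with both ends on the forward strand
 15   pairs with both ends on the same strand (13 + 14)
====  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord, GenomicInterval, LibraryStats

N_FEATURES = 15
FEATURE_IDS = tuple(range(1, N_FEATURES + 1))

FEATURE_NAMES = {
    1: "uniquely mapped reads",
    2: "multiply mapped reads",
    3: "pairs with one end unmapped",
    4: "clipped reads",
    5: "mapped error-free",
    6: "mapped with error",
    7: "concordant pairs (normal ISPE)",
    8: "discordant pairs (abnormal ISPE)",
    9: "sum of mapping quality",
    10: "low mapping quality reads",
    11: "middle mapping quality reads",
    12: "high mapping quality reads",
    13: "pairs both on reverse strand",
    14: "pairs both on forward strand",
    15: "pairs both on same strand",
}


class WindowContractError(ValueError):
    """A record was passed that does not overlap the feature window."""


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of feature counting.

    MAPQ bins follow conventional BWA regimes: low < 20, high >= 40, middle
    otherwise.  A pair is concordant when its ends map on opposite strands
    and |TLEN| lies within ``ispe_mean +/- concordant_k * ispe_sd``.
    """

    mq_low_max: int = 20
    mq_high_min: int = 40
    concordant_k: float = 3.0
    min_clip: int = 5
    count_duplicates: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.mq_low_max <= self.mq_high_min <= 255:
            raise ValueError("require 0 < mq_low_max <= mq_high_min <= 255")
        if self.concordant_k <= 0:
            raise ValueError("concordant_k must be > 0")
        if self.min_clip < 1:
            raise ValueError("min_clip must be >= 1")


@dataclass
class FeatureVector:
    """The 15 feature counts for one breakpoint window.

    ``region`` is the unpadded candidate/inversion interval, ``window`` the
    padded interval the counts were taken over.  ``label`` is 1 (inversion),
    0 (wild-type) or -1 (unknown).
    """

    region: GenomicInterval
    window: GenomicInterval
    f: np.ndarray
    label: int = -1

    def __getitem__(self, feature_id: int) -> float:
        return float(self.f[feature_id - 1])


def padded_window(region: GenomicInterval, stats: LibraryStats) -> GenomicInterval:
    """The feature window: the region enlarged by the mean ISPE on both sides."""
    pad = int(round(stats.ispe_mean))
    return region.padded(pad)


def _is_multiply_mapped(rec: AlignmentRecord) -> bool:
    xt = rec.tags.get("XT")
    if xt == "U":
        return False
    if xt == "R":
        return True
    # XT absent (e.g. BWA-MEM): fall back on alternative hits / zero MAPQ
    return "XA" in rec.tags or rec.mapq == 0


def extract_features(
    records: Iterable[AlignmentRecord],
    region: GenomicInterval,
    stats: LibraryStats,
    fcfg: FeatureConfig = FeatureConfig(),
    label: int = -1,
) -> FeatureVector:
    """Count the 15 features over records overlapping the padded window.

    Per-read features (1-6, 9-12) are counted once per mapped primary record.
    Pair-level features (7-8, 13-15) are counted once per pair with both ends
    mapped, using the symmetric pair flags so the result is invariant under
    permutation of the record stream.  Reads lacking an NM tag are excluded
    from features 5/6.
    """
    window = padded_window(region, stats)
    f = np.zeros(N_FEATURES, dtype=float)
    lo = stats.ispe_mean - fcfg.concordant_k * stats.ispe_sd
    hi = stats.ispe_mean + fcfg.concordant_k * stats.ispe_sd
    seen_pairs: set = set()

    for rec in records:
        if not rec.overlaps(window):
            raise WindowContractError(
                f"record {rec.query_name} at {rec.chrom}:{rec.pos} does not "
                f"overlap window {window.chrom}:{window.start}-{window.end}"
            )
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.is_duplicate and not fcfg.count_duplicates:
            continue

        # 1/2: unique vs multiple placement
        if _is_multiply_mapped(rec):
            f[1] += 1
        else:
            f[0] += 1
        # 3: one end unmapped
        if rec.is_paired and rec.mate_is_unmapped:
            f[2] += 1
        # 4: soft-clipped
        if rec.clipped_bases >= fcfg.min_clip:
            f[3] += 1
        # 5/6: edit distance
        nm = rec.tags.get("NM")
        if nm is not None:
            f[4 if nm == 0 else 5] += 1
        # 9-12: mapping quality
        f[8] += rec.mapq
        if rec.mapq < fcfg.mq_low_max:
            f[9] += 1
        elif rec.mapq >= fcfg.mq_high_min:
            f[11] += 1
        else:
            f[10] += 1

        # 7/8, 13/14: once per both-mapped pair; flags are mate-symmetric
        if rec.is_paired and not rec.mate_is_unmapped and rec.query_name not in seen_pairs:
            seen_pairs.add(rec.query_name)
            tlen = abs(rec.template_length)
            opposite = rec.is_reverse != rec.mate_is_reverse
            if opposite and 0 < tlen and lo <= tlen <= hi:
                f[6] += 1
            else:
                f[7] += 1
            if rec.is_reverse and rec.mate_is_reverse:
                f[12] += 1
            elif not rec.is_reverse and not rec.mate_is_reverse:
                f[13] += 1

    f[14] = f[12] + f[13]
    return FeatureVector(region=region, window=window, f=f, label=label)


# ---------------------------------------------------------------------------
# feature-matrix persistence (TSV)

_META_COLUMNS = ["region_chrom", "region_start", "region_end", "label"]
_F_COLUMNS = [f"f{i}" for i in FEATURE_IDS]
COLUMNS = _META_COLUMNS + _F_COLUMNS


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    rows = []
    for v in vectors:
        row = [v.region.chrom, v.region.start, v.region.end, v.label]
        row.extend(v.f.tolist())
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def write_feature_tsv(vectors_or_frame, path) -> None:
    frame = (
        vectors_or_frame
        if isinstance(vectors_or_frame, pd.DataFrame)
        else feature_frame(vectors_or_frame)
    )
    frame.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns {missing}")
    return frame


def matrix_from_frame(
    frame: pd.DataFrame, feature_ids: Optional[Sequence[int]] = None
):
    """(X, y) arrays from a feature frame; columns ordered by ``feature_ids``."""
    ids = list(feature_ids) if feature_ids is not None else list(FEATURE_IDS)
    X = frame[[f"f{i}" for i in ids]].to_numpy(dtype=float)
    y = frame["label"].to_numpy(dtype=int)
    return X, y
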