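"""Pipeline helpers wiring the modules into the train-on-simulation /
call-on-candidates workflow.  The CLI is a thin shell over these."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignments import (
    AlignmentRecord,
    GenomicInterval,
    LibraryStats,
    estimate_library_stats,
    read_alignments,
    records_overlapping,
)
from .candidates import CandidateInversion, filter_by_length, merge_candidates
from .classify import TrainedClassifier, apply_model, fit_model
from .features import (
    FEATURE_IDS,
    FeatureConfig,
    FeatureVector,
    extract_features,
    feature_frame,
    matrix_from_frame,
)
from .selection import (
    CURATED_IDS,
    DEFAULT_FEATURE_SET,
    SelectionResult,
    chi2_scores,
    select_features,
)
from .simulate import TruthSet, build_training_windows, read_truth_bed


def labeled_feature_vectors(
    records: Sequence[AlignmentRecord],
    truth: TruthSet,
    stats: LibraryStats,
    fcfg: FeatureConfig = FeatureConfig(),
) -> List[FeatureVector]:
    """One labeled feature vector per inversion and wild-type window."""
    vectors = []
    for iv, label in [(iv, 1) for iv, _ in truth.inversions] + [
        (w, 0) for w in truth.wild_type_windows
    ]:
        window_records = records_overlapping(records, iv.padded(int(round(stats.ispe_mean))))
        vectors.append(
            extract_features(window_records, iv, stats, fcfg=fcfg, label=label)
        )
    return vectors


def training_frame_from_dirs(
    sim_dirs: Sequence, fcfg: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Stack labeled feature rows from simulated-sample directories."""
    frames = []
    for sim_dir in sim_dirs:
        sim_dir = Path(sim_dir)
        records = list(read_alignments(sim_dir / "sample.sam"))
        stats = estimate_library_stats(records)
        truth = read_truth_bed(sim_dir / "truth.bed")
        frames.append(feature_frame(labeled_feature_vectors(records, truth, stats, fcfg)))
    return pd.concat(frames, ignore_index=True)


def train_from_frame(
    frame: pd.DataFrame,
    feature_mode: str = "chi2",
    k: int = 8,
    curated: Sequence[int] = CURATED_IDS,
    kernel: str = "linear",
    C: float = 0.1,
    gamma: float = 20.0,
    seed: int = 0,
    scaling_mode: str = "joint",
) -> Tuple[TrainedClassifier, Optional[SelectionResult]]:
    """Feature selection + SVM fit on a labeled feature frame.

    ``feature_mode``: ``chi2`` selects top-k by chi-square plus the curated
    IDs; ``paper`` uses the fixed published 10-feature set; ``all`` keeps
    all 15.
    """
    X_all, y = matrix_from_frame(frame)
    selection: Optional[SelectionResult] = None
    if feature_mode == "chi2":
        selection = select_features(chi2_scores(X_all, y), k=k, curated=curated)
        ids = selection.selected_ids
    elif feature_mode == "paper":
        ids = list(DEFAULT_FEATURE_SET)
    elif feature_mode == "all":
        ids = list(FEATURE_IDS)
    else:
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    X, _ = matrix_from_frame(frame, ids)
    model = fit_model(
        X, y, selected_ids=ids, kernel=kernel, C=C, gamma=gamma, seed=seed,
        scaling_mode=scaling_mode,
    )
    return model, selection


def call_candidates(
    records: Sequence[AlignmentRecord],
    stats: LibraryStats,
    candidates: Sequence[CandidateInversion],
    model: TrainedClassifier,
    fcfg: FeatureConfig = FeatureConfig(),
    eps: int = 10,
) -> Tuple[List[CandidateInversion], np.ndarray, pd.DataFrame]:
    """Merge, length-filter, featurize and classify candidate sites.

    Returns (surviving candidates, 0/1 labels, per-candidate feature frame).
    Candidates labeled 1 are the final inversion calls.
    """
    kept = filter_by_length(merge_candidates(candidates, eps=eps), stats)
    vectors = []
    for cand in kept:
        window_records = records_overlapping(
            records, cand.region.padded(int(round(stats.ispe_mean)))
        )
        vectors.append(extract_features(window_records, cand.region, stats, fcfg=fcfg))
    frame = feature_frame(vectors)
    if not kept:
        return [], np.zeros(0, dtype=int), frame
    X, _ = matrix_from_frame(frame, model.selected_ids)
    labels = apply_model(model, X)
    frame = frame.assign(predicted=labels)
    return kept, labels, frame
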