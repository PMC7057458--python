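"""Chi-square feature mining.

Each of the 15 count features is scored against the binary inversion label
with the count-data chi-square statistic

    x^2 = sum_c (O_c - E_c)^2 / E_c

where, for a feature column, O_c is its total over rows of class c and
E_c = p_c * total is the expectation under class-independence (p_c the class
proportion).  The higher the statistic, the stronger the association between
the feature and the label.  The top-k features are kept and a small curated
set is force-included: the published selection keeps the 8 highest-scoring
features and adds one-end-unmapped (3) and summed mapping quality (9),
dropping the 9th-ranked discordant-pair count as redundant with the
concordant-pair count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .features import FEATURE_IDS

#: The 10-feature set used for calling (top-8 by chi-square plus {3, 9}).
CURATED_IDS = (3, 9)
DEFAULT_FEATURE_SET = (2, 3, 4, 6, 8, 9, 11, 13, 14, 15)


class DegenerateLabelsError(ValueError):
    """Labels contain a single class."""


@dataclass
class SelectionResult:
    chi2_by_feature: Dict[int, float]
    ranked_ids: List[int]
    selected_ids: List[int]
    curated_ids: Tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "chi2_by_feature": {str(k): v for k, v in self.chi2_by_feature.items()},
            "ranked_ids": self.ranked_ids,
            "selected_ids": self.selected_ids,
            "curated_ids": list(self.curated_ids),
        }


def chi2_scores(X, y) -> Dict[int, float]:
    """Chi-square statistic of each feature column against binary labels.

    Feature IDs are 1-based column positions.  Columns summing to zero get a
    score of 0.  Raises on negative entries or single-class labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if np.any(X < 0):
        raise ValueError("chi-square scoring requires non-negative features")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError("labels must contain both classes")

    n = len(y)
    scores: Dict[int, float] = {}
    for j in range(X.shape[1]):
        col = X[:, j]
        total = col.sum()
        if total == 0:
            scores[j + 1] = 0.0
            continue
        stat = 0.0
        for c in classes:
            mask = y == c
            observed = col[mask].sum()
            expected = (mask.sum() / n) * total
            if expected > 0:
                stat += (observed - expected) ** 2 / expected
        scores[j + 1] = float(stat)
    return scores


def rank_features(scores: Dict[int, float]) -> List[int]:
    """IDs sorted by descending score; ties broken by ascending ID."""
    return sorted(scores, key=lambda i: (-scores[i], i))


def select_features(
    scores: Dict[int, float],
    k: int = 8,
    curated: Iterable[int] = CURATED_IDS,
) -> SelectionResult:
    """Top-k features by chi-square, unioned with the curated IDs.

    The selected set is de-duplicated and sorted ascending; it therefore has
    between k and k + |curated| members.
    """
    expected = set(FEATURE_IDS)
    if set(scores) != expected:
        raise ValueError(f"scores must cover feature IDs {min(expected)}..{max(expected)}")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of scored features")
    curated = tuple(sorted(set(curated)))
    if not set(curated) <= expected:
        raise ValueError("curated IDs outside the feature catalogue")
    ranked = rank_features(scores)
    selected = sorted(set(ranked[:k]) | set(curated))
    return SelectionResult(
        chi2_by_feature=dict(scores),
        ranked_ids=ranked,
        selected_ids=selected,
        curated_ids=curated,
    )
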