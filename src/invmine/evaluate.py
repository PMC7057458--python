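"""Benchmark evaluation and cross-validation of inversion calls.

A predicted inversion matches a benchmark entry when both of its breakpoints
lie within ``k * ISPE`` of the benchmark breakpoints (k typically 1, 2 or 3).
Counts follow

    FP = No.Calls - TP          FN = benchmark - TP0

where TP counts matching calls and TP0 counts *distinct* matched benchmark
entries (repeated hits on one entry inflate TP, not TP0), and

    Precision = TP / No.Calls   Recall = TP0 / benchmark
    F1 = 2 * Precision * Recall / (Precision + Recall).

In cross-validation mode there is no benchmark denominator — confusion
counts come from validation-fold labels — so recall is TP / (TP + FN).
Percentages are rounded half-up to 2 decimals at report time only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .alignments import GenomicInterval, LibraryStats
from .candidates import CandidateInversion
from .classify import train as train_svm
from .selection import DegenerateLabelsError


def percent(fraction: float) -> float:
    """A fraction as a percentage rounded half-up to 2 decimals (0.3256134 -> 32.56)."""
    return float(
        Decimal(repr(float(fraction) * 100)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def metrics_from_counts(
    tp: float,
    fp: float,
    fn: float,
    tp0: Optional[float] = None,
    no_calls: Optional[float] = None,
    benchmark_n: Optional[float] = None,
) -> Tuple[float, float, float]:
    """(precision, recall, f1) as exact fractions.

    Precision is TP / No.Calls (No.Calls defaulting to TP + FP).  Recall is
    TP0 / benchmark when both are available (whole-set evaluation), else
    TP / (TP + FN) (cross-validation mode).  Degenerate denominators give 0
    with a warning.
    """
    for name, value in (("tp", tp), ("fp", fp), ("fn", fn)):
        if value < 0:
            raise ValueError(f"negative count {name}={value}")
    if no_calls is None:
        no_calls = tp + fp
    if no_calls > 0:
        precision = tp / no_calls
    else:
        warnings.warn("no calls: precision defined as 0")
        precision = 0.0
    if tp0 is not None and benchmark_n:
        recall = tp0 / benchmark_n
    elif tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("no positives: recall defined as 0")
        recall = 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


@dataclass
class EvaluationResult:
    """Confusion counts and metrics for one whole-set evaluation."""

    no_calls: int
    tp: int
    tp0: int
    fp: int
    fn: int
    benchmark_n: int
    precision: float
    recall: float
    f1: float

    def __post_init__(self) -> None:
        if self.fp != self.no_calls - self.tp:
            raise ValueError("FP must equal No.Calls - TP")
        if self.fn != self.benchmark_n - self.tp0:
            raise ValueError("FN must equal benchmark - TP0")
        if self.tp0 > min(self.tp, self.benchmark_n):
            raise ValueError("TP0 cannot exceed min(TP, benchmark)")

    @classmethod
    def from_counts(
        cls, no_calls: int, tp: int, tp0: int, benchmark_n: int
    ) -> "EvaluationResult":
        precision, recall, f1 = metrics_from_counts(
            tp,
            no_calls - tp,
            benchmark_n - tp0,
            tp0=tp0,
            no_calls=no_calls,
            benchmark_n=benchmark_n,
        )
        return cls(
            no_calls=no_calls,
            tp=tp,
            tp0=tp0,
            fp=no_calls - tp,
            fn=benchmark_n - tp0,
            benchmark_n=benchmark_n,
            precision=precision,
            recall=recall,
            f1=f1,
        )

    def to_dict(self) -> dict:
        return {
            "no_calls": self.no_calls,
            "tp": self.tp,
            "tp0": self.tp0,
            "fp": self.fp,
            "fn": self.fn,
            "benchmark_n": self.benchmark_n,
            "precision_pct": percent(self.precision),
            "recall_pct": percent(self.recall),
            "f1_pct": percent(self.f1),
        }


def match_calls(
    calls: Sequence[CandidateInversion],
    benchmark: Sequence[GenomicInterval],
    stats: LibraryStats,
    k: int = 3,
) -> EvaluationResult:
    """Match calls to benchmark entries under the k*ISPE breakpoint threshold.

    A call matches an entry on the same chromosome when both breakpoint
    distances are <= k * ispe_mean; among several admissible entries the
    nearest by summed breakpoint distance wins (ties to the earlier entry).
    Several calls may match the same entry: each raises TP, only the first
    raises TP0.
    """
    if k not in (1, 2, 3):
        warnings.warn(f"threshold multiplier k={k} outside the conventional 1-3")
    threshold = k * stats.ispe_mean
    tp = 0
    matched: set = set()
    for call in calls:
        best: Optional[Tuple[float, int]] = None
        for j, bench in enumerate(benchmark):
            if bench.chrom != call.region.chrom:
                continue
            ds = abs(call.region.start - bench.start)
            de = abs(call.region.end - bench.end)
            if ds <= threshold and de <= threshold:
                distance = ds + de
                if best is None or distance < best[0]:
                    best = (distance, j)
        if best is not None:
            tp += 1
            matched.add(best[1])
    return EvaluationResult.from_counts(
        no_calls=len(calls), tp=tp, tp0=len(matched), benchmark_n=len(benchmark)
    )


@dataclass
class CVReport:
    """Mean per-fold confusion counts and metrics over repeated k-fold CV."""

    n_repeats: int
    n_folds: int
    tp: float
    tn: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "precision_pct": percent(self.precision),
            "recall_pct": percent(self.recall),
            "f1_pct": percent(self.f1),
            "seed": self.seed,
        }


def cross_validate(
    X,
    y,
    model_spec: Optional[Dict] = None,
    n_folds: int = 10,
    n_repeats: int = 100,
    seed: int = 0,
    eval_mask=None,
) -> CVReport:
    """Repeated, shuffled k-fold cross-validation of the SVM.

    Per repeat the rows are shuffled (seeded) and split into ``n_folds``
    near-equal parts; each part serves once as the validation fold for a
    model trained on the rest.  Confusion counts accumulate on validation
    rows only, optionally restricted to ``eval_mask`` (e.g. to score only a
    designated subset while training on everything).  Reported counts are
    means per fold.  A repeat whose training split collapses to one class is
    reshuffled under the next derived seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    spec = {"kernel": "linear", "C": 0.1, "gamma": 20.0}
    if model_spec:
        spec.update(model_spec)
    n = len(y)
    if n < n_folds:
        raise ValueError("fewer rows than folds")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("labels must contain both classes")
    if eval_mask is not None:
        eval_mask = np.asarray(eval_mask, dtype=bool)

    totals = np.zeros(4, dtype=float)  # tp, tn, fp, fn
    for rep in range(n_repeats):
        for attempt in range(64):
            rng = np.random.default_rng([seed, rep, attempt])
            order = rng.permutation(n)
            folds = np.array_split(order, n_folds)
            ok = all(
                np.unique(y[np.concatenate([f for j, f in enumerate(folds) if j != i])]).size == 2
                for i in range(n_folds)
            )
            if ok:
                break
        else:  # pragma: no cover - pathological label balance
            raise DegenerateLabelsError("could not form two-class training folds")
        for i in range(n_folds):
            val_idx = folds[i]
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            model = train_svm(
                X[train_idx],
                y[train_idx],
                kernel=spec["kernel"],
                C=spec["C"],
                gamma=spec["gamma"],
                seed=seed,
            )
            if eval_mask is not None:
                val_idx = val_idx[eval_mask[val_idx]]
                if val_idx.size == 0:
                    continue
            pred = model.predict(X[val_idx])
            truth = y[val_idx]
            totals[0] += np.sum((pred == 1) & (truth == 1))
            totals[1] += np.sum((pred == 0) & (truth == 0))
            totals[2] += np.sum((pred == 1) & (truth == 0))
            totals[3] += np.sum((pred == 0) & (truth == 1))

    means = totals / (n_repeats * n_folds)
    precision, recall, f1 = metrics_from_counts(means[0], means[2], means[3])
    return CVReport(
        n_repeats=n_repeats,
        n_folds=n_folds,
        tp=float(means[0]),
        tn=float(means[1]),
        fp=float(means[2]),
        fn=float(means[3]),
        precision=precision,
        recall=recall,
        f1=f1,
        seed=seed,
    )
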