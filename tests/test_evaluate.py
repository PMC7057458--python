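"""Breakpoint matching, confusion arithmetic, and cross-validation harness."""

import numpy as np
import pytest

from invmine import (
    CandidateInversion,
    GenomicInterval,
    LibraryStats,
    cross_validate,
    match_calls,
    metrics_from_counts,
    percent,
)
from invmine.evaluate import EvaluationResult
from invmine.selection import DegenerateLabelsError


def _call(start, end, chrom="11"):
    return CandidateInversion(region=GenomicInterval(chrom, start, end), sources={"t"})


def _bench(start, end, chrom="11"):
    return GenomicInterval(chrom, start, end)


class TestMatchCalls:
    def test_perfect_calls(self, default_stats):
        bench = [_bench(1000, 3000), _bench(8000, 9500)]
        calls = [_call(1000, 3000), _call(8000, 9500)]
        res = match_calls(calls, bench, default_stats, k=1)
        assert (res.tp, res.tp0, res.fp, res.fn) == (2, 2, 0, 0)
        assert res.precision == res.recall == res.f1 == 1.0

    def test_threshold_multiplier_gates_matches(self, default_stats):
        # one breakpoint off by 2.5 * ispe_mean: matches only at k=3
        offset = int(2.5 * default_stats.ispe_mean)
        bench = [_bench(10_000, 20_000)]
        calls = [_call(10_000 + offset, 20_000)]
        for k, expect_tp in ((1, 0), (2, 0), (3, 1)):
            res = match_calls(calls, bench, default_stats, k=k)
            assert res.tp == expect_tp, f"k={k}"

    def test_repeated_hits_raise_tp_not_tp0(self, default_stats):
        bench = [_bench(10_000, 20_000)]
        calls = [_call(10_000, 20_000), _call(10_050, 20_050)]
        res = match_calls(calls, bench, default_stats, k=1)
        assert res.tp == 2 and res.tp0 == 1
        assert res.fn == 0 and res.fp == 0

    def test_nearest_benchmark_entry_wins(self, default_stats):
        bench = [_bench(10_000, 20_000), _bench(10_200, 20_200)]
        calls = [_call(10_190, 20_190)]
        res = match_calls(calls, bench, default_stats, k=1)
        assert res.tp == 1 and res.tp0 == 1 and res.fn == 1

    def test_chromosome_must_agree(self, default_stats):
        res = match_calls([_call(1000, 3000, "12")], [_bench(1000, 3000, "11")],
                          default_stats, k=3)
        assert res.tp == 0 and res.fn == 1

    def test_permutation_invariance(self, default_stats):
        rng = np.random.default_rng(0)
        bench = [_bench(int(s), int(s) + 2000) for s in rng.integers(0, 500_000, 20)]
        calls = [
            _call(b.start + int(rng.integers(-500, 500)), b.end + int(rng.integers(-500, 500)))
            for b in bench
        ] + [_call(900_000, 905_000)]
        base = match_calls(calls, bench, default_stats, k=2)
        perm_calls = [calls[i] for i in rng.permutation(len(calls))]
        perm_bench = [bench[i] for i in rng.permutation(len(bench))]
        shuffled = match_calls(perm_calls, perm_bench, default_stats, k=2)
        assert (base.tp, base.tp0, base.fp, base.fn) == (
            shuffled.tp, shuffled.tp0, shuffled.fp, shuffled.fn
        )

    def test_unconventional_k_warns_but_runs(self, default_stats):
        with pytest.warns(UserWarning):
            match_calls([_call(1000, 3000)], [_bench(1000, 3000)], default_stats, k=5)


class TestMetricsFromCounts:
    def test_benchmark_mode_recall_uses_tp0(self):
        p, r, f1 = metrics_from_counts(
            tp=478, fp=990, fn=70, tp0=168, no_calls=1468, benchmark_n=238
        )
        assert percent(p) == 32.56
        assert percent(r) == 70.59

    def test_cv_mode_recall_uses_tp_over_tp_plus_fn(self):
        p, r, f1 = metrics_from_counts(tp=111, fp=19, fn=51)
        assert percent(p) == 85.38
        assert percent(r) == 68.52
        assert percent(f1) == 76.03

    def test_degenerate_zero_counts(self):
        with pytest.warns(UserWarning):
            p, r, f1 = metrics_from_counts(tp=0, fp=0, fn=5)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(tp=-1, fp=0, fn=0)

    def test_percent_rounds_half_up(self):
        assert percent(0.325) == 32.5
        assert percent(0.70585) == 70.59  # 70.585 rounds up
        assert percent(1.0) == 100.0


class TestEvaluationResultInvariants:
    def test_identities_enforced(self):
        with pytest.raises(ValueError):
            EvaluationResult(
                no_calls=10, tp=4, tp0=3, fp=5, fn=2, benchmark_n=5,
                precision=0.4, recall=0.6, f1=0.48,
            )

    def test_from_counts_builds_consistent_result(self):
        res = EvaluationResult.from_counts(no_calls=10, tp=4, tp0=3, benchmark_n=5)
        assert res.fp == 6 and res.fn == 2
        assert 0 <= res.precision <= 1 and 0 <= res.recall <= 1 and 0 <= res.f1 <= 1

    def test_random_matchings_satisfy_identities(self, default_stats):
        rng = np.random.default_rng(3)
        for _ in range(25):
            bench = [
                _bench(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 10**6, 15), rng.integers(500, 5000, 15))
            ]
            calls = [
                _call(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 10**6, 25), rng.integers(500, 5000, 25))
            ]
            res = match_calls(calls, bench, default_stats, k=3)
            assert res.fp == res.no_calls - res.tp
            assert res.fn == res.benchmark_n - res.tp0
            assert res.tp0 <= min(res.tp, res.benchmark_n)
            for value in (res.precision, res.recall, res.f1):
                assert 0.0 <= value <= 1.0


class TestCrossValidate:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(12, 1, (n, 3))])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separable_data_perfect_metrics(self):
        X, y = self._separable()
        report = cross_validate(X, y, n_repeats=3, seed=5)
        assert report.precision == 1.0 and report.recall == 1.0
        assert report.fp == 0.0 and report.fn == 0.0

    def test_partition_conserves_counts(self):
        X, y = self._separable(n=55)
        report = cross_validate(X, y, n_folds=10, n_repeats=2, seed=1)
        per_fold_total = report.tp + report.tn + report.fp + report.fn
        assert per_fold_total == pytest.approx(len(y) / report.n_folds)
        assert report.tp + report.fn == pytest.approx(y.sum() / report.n_folds)

    def test_deterministic_under_seed(self):
        X, y = self._separable(n=30, seed=2)
        X[:10] += 6  # some class overlap so predictions are non-trivial
        a = cross_validate(X, y, n_repeats=4, seed=9)
        b = cross_validate(X, y, n_repeats=4, seed=9)
        assert a == b

    def test_eval_mask_restricts_scoring(self):
        X, y = self._separable(n=40)
        mask = np.zeros(len(y), dtype=bool)
        mask[: len(y) // 2] = True  # score only the first half's rows
        full = cross_validate(X, y, n_repeats=2, seed=3)
        masked = cross_validate(X, y, n_repeats=2, seed=3, eval_mask=mask)
        total_masked = masked.tp + masked.tn + masked.fp + masked.fn
        assert total_masked == pytest.approx((mask.sum()) / masked.n_folds)
        assert total_masked < full.tp + full.tn + full.fp + full.fn

    def test_single_class_labels_rejected(self):
        X = np.ones((20, 2))
        with pytest.raises(DegenerateLabelsError):
            cross_validate(X, np.zeros(20, dtype=int), n_repeats=1)

    def test_fewer_rows_than_folds_rejected(self):
        X, y = self._separable(n=3)
        with pytest.raises(ValueError):
            cross_validate(X, y, n_folds=10, n_repeats=1)
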