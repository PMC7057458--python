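"""Simulator contracts: signatures, depth, determinism, truth bookkeeping."""

import numpy as np
import pytest

from invmine import (
    GenomicInterval,
    LibraryStats,
    SimulationConfig,
    build_training_windows,
    random_config,
    simulate_sample,
)
from invmine.simulate import ConfigError, read_truth_bed, simulate_to_dir, write_truth_bed


def _same_strand_pairs(records):
    out = {}
    for r in records:
        if r.is_unmapped or r.mate_is_unmapped or not r.is_paired:
            continue
        if r.is_reverse == r.mate_is_reverse:
            out.setdefault(r.query_name, []).append(r)
    return out


class TestConfigValidation:
    def test_inversion_past_reference_end(self):
        cfg = SimulationConfig(
            ref_length=5000,
            inversions=[(GenomicInterval("sim", 4000, 6000), "hom")],
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_inversion_shorter_than_ispe(self):
        cfg = SimulationConfig(
            ref_length=20_000,
            inversions=[(GenomicInterval("sim", 5000, 5300), "hom")],
            ispe_mean=400.0,
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_overlapping_inversions(self):
        cfg = SimulationConfig(
            ref_length=20_000,
            inversions=[
                (GenomicInterval("sim", 1000, 2000), "hom"),
                (GenomicInterval("sim", 1500, 2600), "het"),
            ],
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_round_trips_through_dict(self):
        cfg = random_config(5)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestNoInversionNull:
    def test_all_pairs_opposite_strand_with_normal_insert(self):
        cfg = SimulationConfig(
            ref_length=30_000, inversions=[], error_rate=0.0, depth=10.0, seed=3
        )
        records, truth = simulate_sample(cfg)
        assert truth.inversions == []
        assert not _same_strand_pairs(records)
        tlens = [r.template_length for r in records if r.template_length > 0]
        assert len(tlens) * 2 == len(records)  # every pair fully mapped
        assert min(tlens) >= 2 * cfg.read_length  # truncation support
        for r in records:
            assert not r.is_unmapped and not r.mate_is_unmapped
            assert r.tags["NM"] == 0


class TestInversionSignatures:
    def test_same_strand_pairs_flank_each_breakpoint(self, sim_sample, sim_config):
        records, _ = sim_sample
        pairs = _same_strand_pairs(records)
        assert pairs
        for iv, zyg in sim_config.inversions:
            for bp in (iv.start, iv.end):
                window = GenomicInterval("sim", bp - 600, bp + 600)
                near = [
                    q for q, recs in pairs.items()
                    if any(r.overlaps(window) for r in recs)
                ]
                assert near, f"no same-strand pair near breakpoint {bp}"

    def test_same_strand_pairs_confined_to_inversions(self, sim_sample, sim_config):
        records, _ = sim_sample
        guard = int(2 * sim_config.ispe_mean)
        zones = [
            GenomicInterval("sim", max(0, iv.start - guard), iv.end + guard)
            for iv, _ in sim_config.inversions
        ]
        for recs in _same_strand_pairs(records).values():
            assert any(r.overlaps(z) for r in recs for z in zones)

    def test_no_pair_with_both_ends_unmapped(self, sim_sample):
        records, _ = sim_sample
        by_name = {}
        for r in records:
            by_name.setdefault(r.query_name, []).append(r)
        for recs in by_name.values():
            assert not all(r.is_unmapped for r in recs)

    def test_soft_clips_occur_only_at_breakpoints(self, sim_sample, sim_config):
        records, _ = sim_sample
        rl = sim_config.read_length
        breakpoints = [bp for iv, _ in sim_config.inversions for bp in (iv.start, iv.end)]
        clipped = [r for r in records if r.clipped_bases > 0]
        assert clipped
        for r in clipped:
            assert any(abs(r.pos - bp) <= rl or abs(r.reference_end - bp) <= rl
                       for bp in breakpoints)

    def test_depth_conservation(self, sim_sample, sim_config):
        records, _ = sim_sample
        total_bases = sum(r.read_length for r in records)
        expected = sim_config.depth * sim_config.ref_length
        # fragments are Poisson-ish; 5 sigma on the fragment count, plus the
        # few fragments dropped at breakpoints
        n_frag = expected / (2 * sim_config.read_length)
        slack = 5 * np.sqrt(n_frag) * 2 * sim_config.read_length + 0.02 * expected
        assert abs(total_bases - expected) < slack


class TestDeterminism:
    def test_identical_seed_identical_stream(self, sim_config):
        a, _ = simulate_sample(sim_config)
        b, _ = simulate_sample(sim_config)
        assert a == b

    def test_sam_bytes_stable(self, tmp_path, sim_config):
        d1 = simulate_to_dir(sim_config, tmp_path / "a")
        d2 = simulate_to_dir(sim_config, tmp_path / "b")
        assert (tmp_path / "a" / "sample.sam").read_bytes() == (
            tmp_path / "b" / "sample.sam"
        ).read_bytes()
        assert d1["n_records"] == d2["n_records"]


class TestTruthSet:
    def test_wild_type_windows_are_far_from_inversions(self, sim_sample, sim_config):
        _, truth = sim_sample
        assert truth.wild_type_windows
        guard = 2 * sim_config.ispe_mean
        for w in truth.wild_type_windows:
            for iv, _ in truth.inversions:
                assert w.gap_to(iv) >= guard - 2 * 30  # recorded bps jittered <= 30

    def test_recorded_breakpoints_jittered_within_range(self, sim_sample, sim_config):
        _, truth = sim_sample
        lo, hi = sim_config.jitter_range
        for (rec, _), (true, _) in zip(truth.inversions, sim_config.inversions):
            assert lo <= abs(rec.start - true.start) <= hi
            assert lo <= abs(rec.end - true.end) <= hi

    def test_truth_bed_round_trip(self, tmp_path, sim_sample):
        _, truth = sim_sample
        path = tmp_path / "truth.bed"
        write_truth_bed(truth, path)
        back = read_truth_bed(path)
        assert back.inversions == truth.inversions
        assert back.wild_type_windows == truth.wild_type_windows


class TestTrainingWindows:
    def test_labels_and_padding(self, sim_sample, sim_stats):
        _, truth = sim_sample
        windows = build_training_windows(truth, sim_stats)
        n_inv = len(truth.inversions)
        assert [label for _, label in windows[:n_inv]] == [1] * n_inv
        assert all(label == 0 for _, label in windows[n_inv:])
        pad = int(round(sim_stats.ispe_mean))
        iv = truth.inversions[1][0]
        assert windows[1][0] == GenomicInterval("sim", iv.start - pad, iv.end + pad)

    def test_positive_window_count_scales_with_samples(self, default_stats):
        # 13 samples x 5 inversions -> 65 positive windows in aggregate
        from invmine.simulate import TruthSet

        total = 0
        for s in range(13):
            inversions = [
                (GenomicInterval("sim", 10_000 * (i + 1), 10_000 * (i + 1) + 2000), "hom")
                for i in range(5)
            ]
            truth = TruthSet(inversions=inversions, wild_type_windows=[])
            total += sum(
                label for _, label in build_training_windows(truth, default_stats)
            )
        assert total == 65

    def test_windows_never_overlap_across_labels(self, sim_sample, sim_stats):
        _, truth = sim_sample
        windows = build_training_windows(truth, sim_stats)
        positives = [w for w, label in windows if label == 1]
        negatives = [w for w, label in windows if label == 0]
        for p in positives:
            for n in negatives:
                assert not p.overlaps(n)


class TestRandomConfig:
    @pytest.mark.parametrize("seed", range(13))
    def test_parameters_within_canonical_ranges(self, seed):
        cfg = random_config(seed)
        cfg.validate()
        assert 300 <= cfg.ispe_mean <= 500
        assert 0.003 <= cfg.error_rate <= 0.005
        assert 70 <= cfg.read_length <= 150
        assert 4 <= cfg.depth <= 25
        for iv, _ in cfg.inversions:
            assert max(500, cfg.ispe_mean) <= iv.length <= 6000
        assert cfg.jitter_range == (20, 30)
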