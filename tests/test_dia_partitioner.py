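import math

import numpy as np
import pytest
from helpers import make_read, write_bam
from hypothesis import given, settings
from hypothesis import strategies as st

from redikit.alignment_io import GenomicInterval, ReadFilters, open_alignment
from redikit.dia_partitioner import (
    CoverageTrack,
    TimeModel,
    coverage_track,
    default_max_width,
    dynamic_intervals,
    fit_time_model,
    naive_intervals,
    position_cost,
    total_cost,
    weigh_intervals,
)
from redikit.errors import DegenerateFitError

IDENTITY = TimeModel(floor=0.0, scale=1.0, exponent=1.0)  # cost == coverage


def track_from_costs(costs, bin_size=1, name="chr1"):
    """Track whose per-bin cost under IDENTITY equals ``costs``."""
    costs = np.asarray(costs, dtype=float)
    return CoverageTrack(
        bin_size=bin_size,
        chromosomes=[(name, bin_size * len(costs))],
        coverage={name: costs},
    )


class TestTimeModel:
    def test_floor_at_zero_coverage(self):
        assert position_cost(0.0, TimeModel(floor=1, scale=1, exponent=3)) == 1.0

    def test_cubic_closed_form(self):
        assert position_cost(2.0, TimeModel(floor=0, scale=1, exponent=3)) == 8.0

    def test_monotone_in_coverage(self):
        rng = np.random.default_rng(0)
        model = TimeModel(floor=0.5, scale=2.0, exponent=3.0)
        covs = rng.uniform(0, 100, size=1000)
        for c in covs:
            assert position_cost(c + 1, model) >= position_cost(c, model)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            TimeModel(floor=-1)
        with pytest.raises(ValueError):
            TimeModel(scale=0)


class TestCoverageTrack:
    def test_empty_bam_all_zero(self, tmp_path):
        path = write_bam(str(tmp_path / "e.bam"), [("chr1", 100)], [])
        with open_alignment(path) as h:
            track = coverage_track(h, bin_size=10)
        assert np.all(track.coverage["chr1"] == 0)
        assert len(track.coverage["chr1"]) == 10

    def test_single_full_span_read(self, tmp_path):
        path = write_bam(
            str(tmp_path / "one.bam"),
            [("chr1", 100)],
            [make_read("r", 0, 0, "100M", "A" * 100)],
        )
        with open_alignment(path) as h:
            track = coverage_track(h, bin_size=1)
        assert np.all(track.coverage["chr1"] == 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_interval_stabbing_oracle(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        reads = [
            make_read(f"r{i}", 0, int(rng.integers(0, 260)), "40M", "A" * 40)
            for i in range(80)
        ]
        path = write_bam(str(tmp_path / "r.bam"), [("chr1", 300)], reads)
        depth = np.zeros(300)
        for r in reads:
            depth[r.reference_start : r.reference_start + 40] += 1
        with open_alignment(path) as h:
            track = coverage_track(
                h, bin_size=1, filters=ReadFilters(min_mapq=0)
            )
        assert np.array_equal(track.coverage["chr1"], depth)

    def test_bin_means(self, tmp_path):
        path = write_bam(
            str(tmp_path / "m.bam"),
            [("chr1", 10)],
            [make_read("r", 0, 0, "5M", "AAAAA")],
        )
        with open_alignment(path) as h:
            track = coverage_track(h, bin_size=4, filters=ReadFilters(min_mapq=0))
        # bins [0,4) [4,8) [8,10): depths 1,1,1,1 | 1,0,0,0 | 0,0
        assert track.coverage["chr1"] == pytest.approx([1.0, 0.25, 0.0])


class TestTotalCost:
    def test_all_zero_track_floor_only(self):
        track = track_from_costs([0] * 70)
        assert total_cost(track, TimeModel(floor=1, scale=1, exponent=3)) == 70.0

    def test_hand_sum(self):
        track = track_from_costs([1, 2, 3])
        assert total_cost(track, IDENTITY) == 6.0

    def test_random_track_matches_direct_summation(self):
        rng = np.random.default_rng(42)
        covs = rng.uniform(0, 50, size=200)
        track = track_from_costs(covs)
        model = TimeModel(floor=1.0, scale=0.5, exponent=3.0)
        expected = sum(1.0 + 0.5 * c**3 for c in covs)
        assert total_cost(track, model) == pytest.approx(expected)

    def test_additive_over_chromosomes(self):
        covs = {"chr1": np.array([1.0, 2.0]), "chr2": np.array([3.0])}
        track = CoverageTrack(
            bin_size=1, chromosomes=[("chr1", 2), ("chr2", 1)], coverage=covs
        )
        assert total_cost(track, IDENTITY) == 6.0


class TestDynamicIntervals:
    def test_uniform_track_even_quarters(self):
        track = track_from_costs([1.0] * 100)
        plan = dynamic_intervals(track, n=4, model=IDENTITY)
        assert [(iv.start, iv.end) for iv in plan.intervals] == [
            (0, 25), (25, 50), (50, 75), (75, 100),
        ]
        assert plan.weights == pytest.approx([25.0] * 4)
        assert plan.ideal_cost == pytest.approx(25.0)

    def test_hotspot_hand_run(self):
        costs = [1.0] * 50 + [1000.0] + [1.0] * 49
        track = track_from_costs(costs)
        plan = dynamic_intervals(track, n=2, model=IDENTITY)
        assert plan.ideal_cost == pytest.approx(549.5)
        assert [(iv.start, iv.end) for iv in plan.intervals] == [(0, 51), (51, 100)]
        assert plan.weights == pytest.approx([1050.0, 49.0])

    def test_never_spans_chromosomes(self):
        covs = {"chr1": np.full(60, 1.0), "chr2": np.full(40, 1.0)}
        track = CoverageTrack(
            bin_size=1, chromosomes=[("chr1", 60), ("chr2", 40)], coverage=covs
        )
        plan = dynamic_intervals(track, n=1, model=IDENTITY)
        assert len(plan.intervals) >= 2
        for iv in plan.intervals:
            assert iv.chrom in ("chr1", "chr2")
        plan.validate(track.chromosomes)

    def test_max_width_closes_before_violation(self):
        track = track_from_costs([0.0] * 100)  # zero cost, only width binds
        plan = dynamic_intervals(
            track, n=1, max_width=30, model=TimeModel(floor=0.001)
        )
        plan.validate(track.chromosomes)
        assert max(iv.width for iv in plan.intervals) <= 30

    def test_uniform_cost_with_width_cap_is_ceil_tiling(self):
        track = track_from_costs([1.0] * 100)
        plan = dynamic_intervals(track, n=1, max_width=30, model=IDENTITY)
        assert [(iv.start, iv.end) for iv in plan.intervals] == [
            (0, 30), (30, 60), (60, 90), (90, 100),
        ]

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            dynamic_intervals(track_from_costs([1.0]), n=0)

    def test_greedy_overshoot_bound(self):
        rng = np.random.default_rng(7)
        costs = rng.uniform(0.1, 5.0, size=200)
        costs[50] = 300.0  # hotspot
        track = track_from_costs(costs)
        plan = dynamic_intervals(track, n=8, model=IDENTITY)
        bound = plan.ideal_cost + costs.max()
        assert max(plan.weights) <= bound + 1e-9

    @settings(max_examples=40, deadline=None)
    @given(
        costs=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=120),
        n=st.integers(1, 10),
    )
    def test_tiling_property(self, costs, n):
        track = track_from_costs(costs)
        plan = dynamic_intervals(track, n=n, model=TimeModel(floor=1.0))
        plan.validate(track.chromosomes)
        # disjoint, sorted, exact tiling
        assert plan.intervals[0].start == 0
        assert plan.intervals[-1].end == len(costs)
        for a, b in zip(plan.intervals, plan.intervals[1:]):
            assert a.end == b.start
        assert sum(plan.weights) == pytest.approx(plan.total_cost, rel=1e-9)

    def test_binned_track_bounds(self):
        covs = {"chr1": np.array([2.0, 2.0, 2.0, 2.0])}  # 4 bins of 10, len 35
        track = CoverageTrack(bin_size=10, chromosomes=[("chr1", 35)], coverage=covs)
        plan = dynamic_intervals(track, n=2, model=IDENTITY)
        plan.validate(track.chromosomes)
        assert plan.intervals[-1].end == 35


class TestNaiveIntervals:
    def test_even_split(self):
        plan = naive_intervals([("chr1", 100)], 4)
        assert [(iv.start, iv.end) for iv in plan.intervals] == [
            (0, 25), (25, 50), (50, 75), (75, 100),
        ]

    def test_ceil_rule_short_tail(self):
        plan = naive_intervals([("chr1", 10)], 3)
        assert [iv.width for iv in plan.intervals] == [4, 4, 2]

    def test_hotspot_balance_dia_no_worse_than_naive(self):
        costs = np.full(200, 1.0)
        costs[90:110] = 100.0
        track = track_from_costs(list(costs))
        dia = dynamic_intervals(track, n=5, model=IDENTITY)
        naive = naive_intervals(track.chromosomes, 5)
        naive_w = [
            iv.weight for iv in weigh_intervals(naive.intervals, track, IDENTITY)
        ]
        assert max(dia.weights) <= max(naive_w)
        dia_ratio = max(dia.weights) / np.mean(dia.weights)
        naive_ratio = max(naive_w) / np.mean(naive_w)
        assert dia_ratio <= naive_ratio

    def test_default_max_width(self):
        assert default_max_width(100, 4) == 50
        assert default_max_width(10, 3) == 8


class TestFitTimeModel:
    def test_noiseless_cubic_recovered_exactly(self):
        obs = [(x, float(x) ** 3) for x in range(1, 11)]
        model = fit_time_model(obs)
        assert model.exponent == pytest.approx(3.0, abs=1e-9)
        assert model.scale == pytest.approx(1.0, abs=1e-9)

    def test_two_point_interpolation(self):
        model = fit_time_model([(1.0, 1.0), (2.0, 8.0)])
        assert model.exponent == pytest.approx(3.0, abs=1e-12)
        assert model.scale == pytest.approx(1.0, abs=1e-12)

    def test_noisy_cubic_within_band(self):
        rng = np.random.default_rng(123)
        x = rng.uniform(1.0, 50.0, size=1000)
        y = 2.0 * x**3 * np.exp(rng.normal(0, 0.1, size=1000))
        model = fit_time_model(list(zip(x, y)))
        assert 2.8 <= model.exponent <= 3.2

    def test_floor_from_zero_coverage_observations(self):
        obs = [(0.0, 0.4), (0.0, 0.6), (1.0, 1.0), (2.0, 8.0)]
        model = fit_time_model(obs)
        assert model.floor == pytest.approx(0.5)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_time_model([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)])
        with pytest.raises(DegenerateFitError):
            fit_time_model([(1.0, 1.0)])


class TestWeighIntervals:
    def test_weight_splits_partial_bins(self):
        covs = {"chr1": np.array([2.0, 4.0])}
        track = CoverageTrack(bin_size=10, chromosomes=[("chr1", 20)], coverage=covs)
        ivs = weigh_intervals(
            [GenomicInterval("chr1", 5, 15)], track, IDENTITY
        )
        assert ivs[0].weight == pytest.approx(5 * 2.0 + 5 * 4.0)

    def test_total_weight_conserved_over_partition(self):
        rng = np.random.default_rng(5)
        covs = rng.uniform(0, 10, size=50)
        track = track_from_costs(list(covs))
        pieces = [
            GenomicInterval("chr1", lo, hi)
            for lo, hi in zip([0, 13, 27], [13, 27, 50])
        ]
        weights = [iv.weight for iv in weigh_intervals(pieces, track, IDENTITY)]
        assert sum(weights) == pytest.approx(total_cost(track, IDENTITY))
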