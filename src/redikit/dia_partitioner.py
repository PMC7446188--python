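"""Dynamic Interval Analysis: coverage-cost-balanced genome partitioning.

Per-position processing cost is modelled as ``t(c) = floor + scale * c**d``
(``d`` cubic by default). The partitioner computes the whole-genome cost
estimate GC, the ideal per-interval cost AC = GC / n, and greedily closes
intervals on three stop conditions: accumulated weight reaching AC,
interval width reaching a threshold, or a chromosome end.

The partitioner operates on a binned coverage track for tractability; bin
cost is bin width times the positional cost at the bin's mean coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import (
    AlignmentHandle,
    GenomicInterval,
    ReadFilters,
    fetch_overlapping,
    read_passes_filters,
)
from .errors import DegenerateFitError


@dataclass(frozen=True)
class TimeModel:
    """Positional cost as a power law of coverage plus a constant floor."""

    floor: float = 1.0
    scale: float = 1.0
    exponent: float = 3.0

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.scale <= 0 or self.exponent <= 0:
            raise ValueError("scale and exponent must be > 0")

    def cost(self, coverage: float) -> float:
        return self.floor + self.scale * coverage ** self.exponent


@dataclass
class CoverageTrack:
    """Mean coverage per fixed-size bin, per chromosome, in genome order."""

    bin_size: int
    chromosomes: List[Tuple[str, int]]
    coverage: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, length in self.chromosomes:
            expect = math.ceil(length / self.bin_size)
            if len(self.coverage[chrom]) != expect:
                raise ValueError(
                    f"{chrom}: expected {expect} bins, got {len(self.coverage[chrom])}"
                )

    def bin_bounds(self, chrom: str, b: int) -> Tuple[int, int]:
        length = dict(self.chromosomes)[chrom]
        start = b * self.bin_size
        return start, min(start + self.bin_size, length)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class IntervalPlan:
    """A genome partition with per-interval cost weights (the set D)."""

    intervals: List[GenomicInterval]
    n_target: int
    total_cost: float  # GC
    ideal_cost: float  # AC = GC / n_target
    max_width: Optional[int] = None

    @property
    def weights(self) -> List[float]:
        return [iv.weight if iv.weight is not None else 0.0 for iv in self.intervals]

    def validate(self, chromosomes: Sequence[Tuple[str, int]]) -> None:
        """Assert the plan tiles the genome exactly, raising on violation."""
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        if set(by_chrom) != {c for c, _ in chromosomes}:
            raise ValueError("plan chromosomes do not match genome")
        for chrom, length in chromosomes:
            ivs = by_chrom[chrom]
            if ivs[0].start != 0 or ivs[-1].end != length:
                raise ValueError(f"{chrom} not fully tiled")
            for a, b in zip(ivs, ivs[1:]):
                if a.end != b.start:
                    raise ValueError(f"gap or overlap at {chrom}:{a.end}")
            if self.max_width is not None:
                for iv in ivs:
                    if iv.width > self.max_width:
                        raise ValueError(f"{iv} wider than {self.max_width}")


def coverage_track(
    handle: AlignmentHandle,
    bin_size: int = 1000,
    filters: Optional[ReadFilters] = None,
) -> CoverageTrack:
    """Per-bin mean depth from passing reads' reference spans, single pass.

    Uses a start/end difference array per chromosome; bins with no reads
    have coverage 0.
    """
    if filters is None:
        filters = ReadFilters()
    chromosomes = handle.chromosomes
    coverage: Dict[str, np.ndarray] = {}
    for chrom, length in chromosomes:
        diff = np.zeros(length + 1, dtype=np.int64)
        for read in fetch_overlapping(handle, GenomicInterval(chrom, 0, length)):
            if not read_passes_filters(read, filters):
                continue
            diff[read.start] += 1
            diff[min(read.reference_end, length)] -= 1
        depth = np.cumsum(diff[:length])
        nbins = math.ceil(length / bin_size)
        edges = np.arange(nbins) * bin_size
        sums = np.add.reduceat(depth, edges) if length else np.zeros(0)
        widths = np.minimum(edges + bin_size, length) - edges
        coverage[chrom] = sums / widths
    return CoverageTrack(bin_size=bin_size, chromosomes=chromosomes, coverage=coverage)


def position_cost(cov: float, model: TimeModel) -> float:
    """Estimated processing cost of one position with coverage ``cov``."""
    if cov < 0:
        raise ValueError("coverage must be >= 0")
    return model.cost(cov)


def total_cost(track: CoverageTrack, model: TimeModel) -> float:
    """Whole-genome cost estimate GC: sum of bin_width * t(bin coverage)."""
    gc = 0.0
    for chrom, length in track.chromosomes:
        covs = track.coverage[chrom]
        for b, cov in enumerate(covs):
            lo, hi = track.bin_bounds(chrom, b)
            gc += (hi - lo) * model.cost(float(cov))
    return gc


def dynamic_intervals(
    track: CoverageTrack,
    n: int,
    max_width: Optional[int] = None,
    model: Optional[TimeModel] = None,
) -> IntervalPlan:
    """Greedy cost-balanced partition of the genome into ~n intervals.

    Scans bins in genome order accumulating weight; an interval closes
    immediately after the bin whose addition brings its weight to at least
    AC (max-weight), before a bin that would push its width past
    ``max_width`` (max-width), and at every chromosome end
    (single-chromosome-span). The number of intervals produced may differ
    from ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model is None:
        model = TimeModel()
    if max_width is not None and max_width < track.bin_size:
        raise ValueError("max_width must be >= bin_size")
    gc = total_cost(track, model)
    ac = gc / n
    intervals: List[GenomicInterval] = []
    for chrom, length in track.chromosomes:
        covs = track.coverage[chrom]
        cur_start = 0
        cur_weight = 0.0
        for b, cov in enumerate(covs):
            lo, hi = track.bin_bounds(chrom, b)
            cost = (hi - lo) * model.cost(float(cov))
            if (
                max_width is not None
                and lo > cur_start
                and hi - cur_start > max_width
            ):
                intervals.append(
                    GenomicInterval(chrom, cur_start, lo, weight=cur_weight)
                )
                cur_start, cur_weight = lo, 0.0
            cur_weight += cost
            if cur_weight >= ac:
                intervals.append(
                    GenomicInterval(chrom, cur_start, hi, weight=cur_weight)
                )
                cur_start, cur_weight = hi, 0.0
        if cur_start < length:
            intervals.append(
                GenomicInterval(chrom, cur_start, length, weight=cur_weight)
            )
    return IntervalPlan(
        intervals=intervals,
        n_target=n,
        total_cost=gc,
        ideal_cost=ac,
        max_width=max_width,
    )


def default_max_width(genome_length: int, n: int) -> int:
    """Default interval width cap: twice the naive equal-split width."""
    return 2 * math.ceil(genome_length / n)


def naive_intervals(
    chromosomes: Sequence[Tuple[str, int]], n: int
) -> IntervalPlan:
    """Equal-width tiling baseline: width = ceil(genome length / n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    genome_length = sum(length for _, length in chromosomes)
    width = math.ceil(genome_length / n)
    intervals: List[GenomicInterval] = []
    for chrom, length in chromosomes:
        for start in range(0, length, width):
            intervals.append(GenomicInterval(chrom, start, min(start + width, length)))
    return IntervalPlan(
        intervals=intervals,
        n_target=n,
        total_cost=float("nan"),
        ideal_cost=float("nan"),
        max_width=width,
    )


def weigh_intervals(
    intervals: Sequence[GenomicInterval],
    track: CoverageTrack,
    model: TimeModel,
) -> List[GenomicInterval]:
    """Attach estimated cost weights to arbitrary intervals using a track."""
    out: List[GenomicInterval] = []
    for iv in intervals:
        covs = track.coverage[iv.chrom]
        b0 = iv.start // track.bin_size
        b1 = (iv.end - 1) // track.bin_size
        weight = 0.0
        for b in range(b0, b1 + 1):
            lo, hi = track.bin_bounds(iv.chrom, b)
            overlap = min(hi, iv.end) - max(lo, iv.start)
            weight += overlap * model.cost(float(covs[b]))
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, weight=weight))
    return out


def fit_time_model(
    observations: Sequence[Tuple[float, float]],
    default_floor: float = 1.0,
) -> TimeModel:
    """Fit t(c) = floor + scale * c**d from (mean coverage, elapsed time).

    Log-log least squares on the positive-coverage observations gives the
    exponent and scale; the floor is the mean time of zero-coverage
    observations when present, else ``default_floor``.
    """
    zero = [t for c, t in observations if c == 0]
    pos = [(c, t) for c, t in observations if c > 0 and t > 0]
    if len(pos) < 2:
        raise DegenerateFitError("need at least 2 positive observations")
    logc = np.log([c for c, _ in pos])
    logt = np.log([t for _, t in pos])
    if np.ptp(logc) == 0:
        raise DegenerateFitError("all observations share one coverage value")
    slope, intercept = np.polyfit(logc, logt, 1)
    floor = float(np.mean(zero)) if zero else default_floor
    return TimeModel(floor=floor, scale=float(np.exp(intercept)), exponent=float(slope))
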