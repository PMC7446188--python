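"""Single-load pileup traversal.

The traversal retrieves each alignment record from storage exactly once:
when a read is first encountered its qualifying bases are added to
per-position tallies for the whole interval, after which the record is
dropped. This contrasts with position-by-position engines that re-fetch a
read once per covered position. Instrumentation (`TraversalStats`) records
the number of loads per read and the peak number of reads that a
position-incremental buffer would have held simultaneously.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

import numpy as np

from .alignment_io import (
    AlignedRead,
    AlignmentHandle,
    GenomicInterval,
    ReadFilters,
    fetch_overlapping,
    read_passes_filters,
)
from .errors import PositionOutsideReadError

# ASCII -> base code (A=0, C=1, G=2, T=3, everything else -1)
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PileupConfig:
    """Per-base quality gate plus the read-level filters."""

    min_base_quality: int = 25
    read_filters: ReadFilters = field(default_factory=ReadFilters)
    count_soft_clipped: bool = False  # reserved; soft clips are never counted

    def __post_init__(self) -> None:
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


@dataclass
class PositionPileup:
    """Filtered base/quality/strand tallies at one genomic position."""

    chrom: str
    pos: int  # 0-based
    counts: Tuple[int, int, int, int]  # A, C, G, T
    qual_sum: int
    forward: int
    reverse: int

    @property
    def coverage(self) -> int:
        return sum(self.counts)


@dataclass
class TraversalStats:
    """Instrumentation for the single-load contract."""

    loads: int = 0
    peak_active: int = 0
    per_read: Counter = field(default_factory=Counter)

    def record_load(self, read: AlignedRead) -> None:
        self.loads += 1
        self.per_read[(read.query_name, read.chrom, read.start, read.is_reverse)] += 1

    @property
    def max_loads_per_read(self) -> int:
        return max(self.per_read.values(), default=0)

    @property
    def distinct_reads(self) -> int:
        return len(self.per_read)


def base_at(read: AlignedRead, gpos: int) -> Optional[Tuple[str, int]]:
    """Resolve the query base aligned to genomic position ``gpos``.

    Returns ``(base, quality)`` when ``gpos`` falls in an aligned (M/=/X)
    segment, ``None`` when it falls in a deletion or reference skip.
    Insertions and soft clips consume query only and never map to ``gpos``.
    """
    if gpos < read.start or gpos >= read.reference_end:
        raise PositionOutsideReadError(
            f"position {gpos} outside read span "
            f"[{read.start}, {read.reference_end})"
        )
    qpos = 0
    rpos = read.start
    for op, n in read.cigar:
        if op in ("M", "=", "X"):
            if rpos <= gpos < rpos + n:
                off = qpos + (gpos - rpos)
                return read.seq[off], int(read.quals[off])
            qpos += n
            rpos += n
        elif op in ("I", "S"):
            qpos += n
        elif op in ("D", "N"):
            if rpos <= gpos < rpos + n:
                return None
            rpos += n
    raise PositionOutsideReadError(f"position {gpos} not resolved by CIGAR")


def _tally_read(
    read: AlignedRead,
    interval: GenomicInterval,
    min_base_quality: int,
    counts: np.ndarray,
    qual_sum: np.ndarray,
    forward: np.ndarray,
    reverse: np.ndarray,
) -> None:
    """Add the read's qualifying bases inside ``interval`` to the tallies."""
    seq = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)
    quals = read.quals
    strand = reverse if read.is_reverse else forward
    for gstart, qstart, n in read.aligned_segments():
        g0 = max(gstart, interval.start)
        g1 = min(gstart + n, interval.end)
        if g0 >= g1:
            continue
        q0 = qstart + (g0 - gstart)
        codes = _BASE_CODE[seq[q0 : q0 + (g1 - g0)]]
        qs = quals[q0 : q0 + (g1 - g0)]
        ok = (qs >= min_base_quality) & (codes >= 0)
        if not ok.any():
            continue
        idx = np.arange(g0 - interval.start, g1 - interval.start)[ok]
        counts[codes[ok], idx] += 1  # idx unique within one segment
        qual_sum[idx] += qs[ok]
        strand[idx] += 1


def traverse(
    handle: AlignmentHandle,
    interval: GenomicInterval,
    config: Optional[PileupConfig] = None,
    dense: bool = False,
    stats: Optional[TraversalStats] = None,
) -> Iterator[PositionPileup]:
    """Emit per-position pileups over ``interval`` loading each read once.

    Positions are yielded in increasing order; in the default sparse mode
    positions with zero passing coverage are skipped, ``dense=True`` emits
    every position. Reads starting before ``interval.start`` contribute to
    the positions they cover inside the interval.
    """
    if config is None:
        config = PileupConfig()
    width = interval.width
    counts = np.zeros((4, width), dtype=np.int64)
    qual_sum = np.zeros(width, dtype=np.int64)
    forward = np.zeros(width, dtype=np.int64)
    reverse = np.zeros(width, dtype=np.int64)
    occupancy = np.zeros(width + 1, dtype=np.int64)

    for read in fetch_overlapping(handle, interval):
        if not read_passes_filters(read, config.read_filters):
            continue
        if stats is not None:
            stats.record_load(read)
        _tally_read(
            read, interval, config.min_base_quality, counts, qual_sum, forward, reverse
        )
        s = max(read.start, interval.start) - interval.start
        e = min(read.reference_end, interval.end) - interval.start
        if e > s:
            occupancy[s] += 1
            occupancy[e] -= 1

    if stats is not None and width:
        stats.peak_active = max(
            stats.peak_active, int(occupancy.cumsum()[:width].max(initial=0))
        )

    coverage = counts.sum(axis=0)
    for i in range(width):
        if not dense and coverage[i] == 0:
            continue
        yield PositionPileup(
            chrom=interval.chrom,
            pos=interval.start + i,
            counts=(
                int(counts[0, i]),
                int(counts[1, i]),
                int(counts[2, i]),
                int(counts[3, i]),
            ),
            qual_sum=int(qual_sum[i]),
            forward=int(forward[i]),
            reverse=int(reverse[i]),
        )


def peak_active_reads(stats: TraversalStats) -> int:
    """Maximum simultaneous size of the active-read buffer during traversal."""
    return stats.peak_active
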