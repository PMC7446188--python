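"""Reading and filtering alignments and reference windows.

Coordinates are 0-based half-open everywhere in this package; the output
table converts to 1-based positions at serialization time only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .errors import (
    IntervalBoundsError,
    MissingIndexError,
    UnknownContigError,
    UnsortedBamError,
)

_CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")

#: Flag names accepted by :class:`ReadFilters.exclude_flags`.
FLAG_NAMES = ("unmapped", "secondary", "supplementary", "duplicate", "qcfail")

DEFAULT_EXCLUDE_FLAGS = frozenset(FLAG_NAMES)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a single chromosome, optionally weighted."""

    chrom: str
    start: int
    end: int
    weight: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise IntervalBoundsError(
                f"empty or negative interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # samtools-style, 1-based inclusive
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class ReadFilters:
    """Mapping-quality and flag gate applied to every read."""

    min_mapq: int = 25
    exclude_flags: frozenset = DEFAULT_EXCLUDE_FLAGS

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        unknown = set(self.exclude_flags) - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"unknown flag names: {sorted(unknown)}")


@dataclass
class AlignedRead:
    """One alignment record, decoded from BAM.

    ``seq`` is stored in genome-forward orientation (as in BAM); ``quals``
    is a numpy int array parallel to ``seq``.
    """

    query_name: str
    chrom: str
    start: int
    cigar: Tuple[Tuple[str, int], ...]
    seq: str
    quals: np.ndarray
    mapq: int
    is_reverse: bool = False
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_qcfail: bool = False

    @property
    def reference_end(self) -> int:
        """One past the last reference position consumed by the alignment."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)

    def flag_set(self, name: str) -> bool:
        return getattr(self, f"is_{name}")

    def aligned_segments(self) -> Iterator[Tuple[int, int, int]]:
        """Yield (ref_start, query_start, length) for each M/=/X run."""
        qpos = 0
        gpos = self.start
        for op, n in self.cigar:
            if op in ("M", "=", "X"):
                yield gpos, qpos, n
                qpos += n
                gpos += n
            elif op in ("I", "S"):
                qpos += n
            elif op in ("D", "N"):
                gpos += n
            # H and P consume neither sequence


@dataclass(frozen=True)
class ReferenceWindow:
    interval: GenomicInterval
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != self.interval.width:
            raise ValueError("reference window length does not match interval width")


def _to_aligned_read(a: pysam.AlignedSegment) -> AlignedRead:
    quals = a.query_qualities
    return AlignedRead(
        query_name=a.query_name or "",
        chrom=a.reference_name or "",
        start=a.reference_start,
        cigar=tuple((_CIGAR_OPS[op], n) for op, n in (a.cigartuples or ())),
        seq=a.query_sequence or "",
        quals=np.asarray(quals, dtype=np.int32)
        if quals is not None
        else np.zeros(0, dtype=np.int32),
        mapq=a.mapping_quality,
        is_reverse=a.is_reverse,
        is_unmapped=a.is_unmapped,
        is_secondary=a.is_secondary,
        is_supplementary=a.is_supplementary,
        is_duplicate=a.is_duplicate,
        is_qcfail=a.is_qcfail,
    )


class AlignmentHandle:
    """Open coordinate-sorted, indexed BAM exposing region fetches."""

    def __init__(self, path: str):
        self.path = str(path)
        self._af = pysam.AlignmentFile(self.path, "rb")
        try:
            if not self._af.has_index():
                raise MissingIndexError(f"index required: no index found for {path}")
            so = (self._af.header.get("HD") or {}).get("SO")
            if so != "coordinate":
                raise UnsortedBamError(
                    f"{path} is not coordinate-sorted (SO={so!r})"
                )
        except Exception:
            self._af.close()
            raise

    @property
    def chromosomes(self) -> List[Tuple[str, int]]:
        """(name, length) pairs in header order."""
        return list(zip(self._af.references, self._af.lengths))

    @property
    def references(self) -> Tuple[str, ...]:
        return tuple(self._af.references)

    def chromosome_length(self, chrom: str) -> int:
        if chrom not in self._af.references:
            raise UnknownContigError(f"unknown chromosome {chrom!r}")
        return self._af.lengths[self._af.references.index(chrom)]

    def fetch(self, interval: GenomicInterval) -> Iterator[AlignedRead]:
        if interval.chrom not in self._af.references:
            raise UnknownContigError(f"unknown chromosome {interval.chrom!r}")
        for a in self._af.fetch(interval.chrom, interval.start, interval.end):
            yield _to_aligned_read(a)

    def close(self) -> None:
        self._af.close()

    def __enter__(self) -> "AlignmentHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_alignment(path: str) -> AlignmentHandle:
    """Open a coordinate-sorted, indexed BAM file.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MissingIndexError
        If no companion ``.bai``/``.csi`` index is present.
    UnsortedBamError
        If the header does not declare ``SO:coordinate``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return AlignmentHandle(path)


def fetch_overlapping(
    handle: AlignmentHandle, interval: GenomicInterval
) -> Iterator[AlignedRead]:
    """Yield every stored read whose span intersects ``interval``.

    Reads arrive in non-decreasing start order (BAM coordinate order), each
    exactly once per call.
    """
    return handle.fetch(interval)


def read_passes_filters(read: AlignedRead, filters: ReadFilters) -> bool:
    """True unless the read is unmapped, excluded by flag, or low-mapq."""
    if read.is_unmapped:
        return False
    if read.mapq < filters.min_mapq:
        return False
    for name in filters.exclude_flags:
        if read.flag_set(name):
            return False
    return True


def reference_window(fasta: str, interval: GenomicInterval) -> ReferenceWindow:
    """Fetch an upper-cased reference subsequence for ``interval``."""
    with pysam.FastaFile(str(fasta)) as fa:
        if interval.chrom not in fa.references:
            raise UnknownContigError(f"unknown chromosome {interval.chrom!r}")
        length = fa.get_reference_length(interval.chrom)
        if interval.end > length:
            raise IntervalBoundsError(
                f"{interval} exceeds chromosome length {length}"
            )
        bases = fa.fetch(interval.chrom, interval.start, interval.end).upper()
    return ReferenceWindow(interval=interval, bases=bases)


def parse_region(region: str, handle: Optional[AlignmentHandle] = None) -> GenomicInterval:
    """Parse a samtools-style region string (1-based inclusive) to an interval."""
    if ":" not in region:
        if handle is None:
            raise ValueError(f"bare chromosome {region!r} needs a handle for its length")
        return GenomicInterval(region, 0, handle.chromosome_length(region))
    chrom, _, span = region.partition(":")
    lo, _, hi = span.partition("-")
    return GenomicInterval(chrom, int(lo.replace(",", "")) - 1, int(hi.replace(",", "")))


def read_bed(path: str) -> List[GenomicInterval]:
    """Read 3+ column BED (0-based half-open); a 5th column is the weight."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            weight = float(parts[4]) if len(parts) >= 5 else None
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), weight=weight)
            )
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str) -> None:
    """Write intervals as BED with name and weight columns."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            w = f"{iv.weight:.6g}" if iv.weight is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tinterval_{i}\t{w}\n")
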