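"""Candidate editing-site calling and the tabular output format.

Each output row describes one genomic position: chromosome, 1-based
position, reference base, strand code (1 plus, 0 minus, 2 undefined),
quality-filtered coverage, mean base quality, the four base counts, the
observed substitutions and the frequency of the dominant substitution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import (
    InvalidReferenceBaseError,
    MissingTemporaryError,
    UnsortedRecordsError,
    ZeroCoverageError,
)
from .pileup_engine import PositionPileup

_BASES = "ACGT"

STRAND_PLUS = 1
STRAND_MINUS = 0
STRAND_UNDEFINED = 2


@dataclass(frozen=True)
class CallerConfig:
    min_coverage: int = 10
    min_alt_reads: int = 3
    min_frequency: float = 0.10
    strandedness: str = "unstranded"  # unstranded | forward | reverse
    emit_all: bool = False

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if not 0.0 <= self.min_frequency <= 1.0:
            raise ValueError("min_frequency must be in [0, 1]")
        if self.strandedness not in ("unstranded", "forward", "reverse"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")


@dataclass
class EditingSiteRecord:
    region: str
    position: int  # 1-based in the table
    reference: str
    strand: int
    coverage: int
    mean_q: float
    base_count: Tuple[int, int, int, int]
    all_subs: Tuple[str, ...]  # empty tuple renders as "-"
    frequency: float

    def to_row(self) -> str:
        bc = "[{}, {}, {}, {}]".format(*self.base_count)
        subs = " ".join(self.all_subs) if self.all_subs else "-"
        return (
            f"{self.region}\t{self.position}\t{self.reference}\t{self.strand}\t"
            f"{self.coverage}\t{self.mean_q:.2f}\t{bc}\t{subs}\t{self.frequency:.2f}"
        )

    @classmethod
    def from_row(cls, row: str) -> "EditingSiteRecord":
        f = row.rstrip("\n").split("\t")
        counts = tuple(int(x) for x in f[6].strip("[]").split(","))
        subs = tuple() if f[7] == "-" else tuple(f[7].split(" "))
        return cls(
            region=f[0],
            position=int(f[1]),
            reference=f[2],
            strand=int(f[3]),
            coverage=int(f[4]),
            mean_q=float(f[5]),
            base_count=counts,  # type: ignore[arg-type]
            all_subs=subs,
            frequency=float(f[8]),
        )


def table_header(min_base_quality: int = 25) -> str:
    return (
        "Region\tPosition\tReference\tStrand\t"
        f"Coverage-q{min_base_quality}\tMeanQ\tBaseCount[A,C,G,T]\tAllSubs\tFrequency"
    )


def substitution_frequencies(
    base_count: Sequence[int], reference: str
) -> List[Tuple[str, int, float]]:
    """Observed substitutions at a position, ordered by count then label.

    Returns one ``(label, count, frequency)`` per non-reference base with a
    positive count; frequency is count over total qualifying coverage.
    """
    total = sum(base_count)
    if total <= 0:
        raise ZeroCoverageError("no qualifying bases at position")
    if reference not in _BASES:
        raise InvalidReferenceBaseError(f"invalid reference base {reference!r}")
    subs = [
        (reference + b, int(c), c / total)
        for b, c in zip(_BASES, base_count)
        if b != reference and c > 0
    ]
    subs.sort(key=lambda s: (-s[1], s[0]))
    return subs


def infer_strand(strand_counts: Tuple[int, int], strandedness: str) -> int:
    """Map read-orientation counts to a strand code.

    Unstranded libraries carry no strand information (always 2). In the
    ``forward`` protocol the majority read orientation is the transcript
    strand; ``reverse`` flips the mapping. Ties and zero coverage give 2.
    """
    if strandedness == "unstranded":
        return STRAND_UNDEFINED
    fwd, rev = strand_counts
    if fwd == rev:
        return STRAND_UNDEFINED
    plus_wins = fwd > rev
    if strandedness == "reverse":
        plus_wins = not plus_wins
    return STRAND_PLUS if plus_wins else STRAND_MINUS


def call_site(
    pileup: PositionPileup, reference: str, config: CallerConfig
) -> Optional[EditingSiteRecord]:
    """Turn one pileup column into a candidate record, or drop it.

    Bases and substitution labels are reported on the plus strand of the
    genome regardless of the inferred transcript strand.
    """
    reference = reference.upper()
    if reference == "N":
        return None
    if reference not in _BASES:
        raise InvalidReferenceBaseError(f"invalid reference base {reference!r}")
    coverage = pileup.coverage
    if coverage < config.min_coverage:
        return None
    subs = substitution_frequencies(pileup.counts, reference)
    qualifying = [
        s
        for s in subs
        if s[1] >= config.min_alt_reads and s[2] >= config.min_frequency
    ]
    if not qualifying and not config.emit_all:
        return None
    return EditingSiteRecord(
        region=pileup.chrom,
        position=pileup.pos + 1,
        reference=reference,
        strand=infer_strand((pileup.forward, pileup.reverse), config.strandedness),
        coverage=coverage,
        mean_q=pileup.qual_sum / coverage,
        base_count=pileup.counts,
        all_subs=tuple(s[0] for s in qualifying),
        frequency=qualifying[0][2] if qualifying else 0.0,
    )


def write_table(
    records: Iterable[EditingSiteRecord],
    sink: Union[str, os.PathLike, IO[str]],
    min_base_quality: int = 25,
) -> int:
    """Serialize records as TSV with a single header row; returns row count.

    Records must arrive sorted by (region in order of first appearance,
    position); violation raises :class:`UnsortedRecordsError`.
    """
    own = isinstance(sink, (str, os.PathLike))
    fh: IO[str] = open(sink, "w") if own else sink  # type: ignore[arg-type]
    count = 0
    try:
        fh.write(table_header(min_base_quality) + "\n")
        seen_regions: List[str] = []
        last_pos = 0
        for rec in records:
            if not seen_regions or rec.region != seen_regions[-1]:
                if rec.region in seen_regions:
                    raise UnsortedRecordsError(
                        f"region {rec.region} appears in two runs"
                    )
                seen_regions.append(rec.region)
                last_pos = 0
            if rec.position < last_pos:
                raise UnsortedRecordsError(
                    f"{rec.region}:{rec.position} after position {last_pos}"
                )
            last_pos = rec.position
            fh.write(rec.to_row() + "\n")
            count += 1
    finally:
        if own:
            fh.close()
    return count


def read_table(path: Union[str, os.PathLike]) -> List[EditingSiteRecord]:
    """Parse a table written by :func:`write_table` back into records."""
    records: List[EditingSiteRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("Region\t"):
            raise ValueError(f"{path} does not look like an editing table")
        for line in fh:
            if line.strip():
                records.append(EditingSiteRecord.from_row(line))
    return records


def merge_outputs(
    paths: Sequence[Union[str, os.PathLike]],
    sink: Union[str, os.PathLike],
    min_base_quality: int = 25,
    delete: bool = False,
) -> int:
    """Concatenate per-interval tables into one file with a single header.

    ``paths`` must be ordered by their intervals' genomic order so the
    result is globally sorted. Returns the number of data rows written.
    """
    missing = [str(p) for p in paths if not os.path.exists(p)]
    if missing:
        raise MissingTemporaryError(missing)
    count = 0
    with open(sink, "w") as out:
        out.write(table_header(min_base_quality) + "\n")
        for p in paths:
            with open(p) as fh:
                first = fh.readline()
                if first and not first.startswith("Region\t"):
                    out.write(first)
                    count += 1
                for line in fh:
                    if line.strip():
                        out.write(line)
                        count += 1
    if delete:
        for p in paths:
            os.remove(p)
    return count


def temp_table_name(interval) -> str:
    """Canonical per-interval temporary file name."""
    return f"{interval.chrom}_{interval.start}_{interval.end}.tmp.tsv"
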